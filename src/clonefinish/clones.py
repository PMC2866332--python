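"""Associating final contigs with physical clones via Sanger end reads.

Each clone contributed a 5' and/or 3' Sanger read.  Reads are aligned
to the final contig sequences; alignments shorter than 30 bp or below
90% identity are discarded, conflicts resolve to the best-scoring
match, and a truncated contig end is extended with the unaligned
terminal portion of the Sanger read (contig bases win wherever the two
overlap).  Contigs no Sanger read supports are demoted to a secondary
output to avoid false positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .aligner import Genome, align_to_contigs
from .anchoring import AnchoredContig
from .core import GenomeAlignment, GenomeInterval, Params
from .reads import revcomp

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

_MIN_EXTENSION = 10  # unaligned terminal bases needed to trigger extension
_MAX_EXT_N_RATE = 0.10


@dataclass(frozen=True)
class SangerRead:
    id: str
    clone_id: str
    end: str  # five_prime | three_prime
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CloneAssembly:
    clone_id: str
    status: str  # assembled | not_amplified
    contig_id: str | None = None
    secondary_contig_id: str | None = None
    sequence: str = ""
    chrom: str | None = None
    strand: str | None = None
    exon_chain: list[GenomeInterval] = field(default_factory=list)
    extended_5p: int = 0
    extended_3p: int = 0
    internal_gap: bool = False


def dedupe_sanger(reads: list[SangerRead]) -> list[SangerRead]:
    """One read per (clone, end); the longer read wins, with a warning."""
    best: dict[tuple[str, str], SangerRead] = {}
    for r in reads:
        key = (r.clone_id, r.end)
        if key in best:
            warnings.warn(f"duplicate Sanger read for {key}; keeping the longer")
            if len(r) > len(best[key]):
                best[key] = r
        else:
            best[key] = r
    return list(best.values())


def _passes_filters(aln: GenomeAlignment, params: Params) -> bool:
    return (
        aln.aligned_len >= params.sanger_min_align
        and aln.identity >= params.sanger_min_identity
    )


def extend_with_sanger(
    assembly: CloneAssembly, read: SangerRead, aln: GenomeAlignment
) -> CloneAssembly:
    """Graft the unaligned terminal portion of an end read onto the
    assembly sequence.

    For a 5' read aligned in the sense orientation, read bases hanging
    off the contig start are prepended; for a 3' read (stored reverse
    complemented) bases hanging off the contig end are appended.  Bases
    in the overlap always come from the contig.  Extensions with more
    than 10% ambiguous bases are refused.
    """
    tlen = len(assembly.sequence)
    qlen = aln.query_len
    if read.end == FIVE_PRIME and aln.strand == "+":
        ext = aln.q_start - aln.t_start
        if ext >= _MIN_EXTENSION:
            piece = read.sequence[:ext]
            if piece.count("N") / len(piece) > _MAX_EXT_N_RATE:
                warnings.warn(f"5' extension for {read.clone_id} too ambiguous; skipped")
            else:
                assembly.sequence = piece + assembly.sequence
                assembly.extended_5p = ext
    elif read.end == THREE_PRIME and aln.strand == "-":
        # minus-strand query coordinates are in the reverse-complemented
        # frame, i.e. the frame of the transcript-sense tail
        sense = revcomp(read.sequence)
        ext = (qlen - aln.q_end) - (tlen - aln.t_end)
        if ext >= _MIN_EXTENSION:
            piece = sense[qlen - ext :]
            if piece.count("N") / len(piece) > _MAX_EXT_N_RATE:
                warnings.warn(f"3' extension for {read.clone_id} too ambiguous; skipped")
            else:
                assembly.sequence = assembly.sequence + piece
                assembly.extended_3p = ext
    return assembly


def assign_clones(
    contigs: list[AnchoredContig],
    sanger_reads: list[SangerRead],
    params: Params | None = None,
) -> tuple[list[CloneAssembly], list[AnchoredContig]]:
    """Map clones to contigs and extend truncated ends.

    Returns (one CloneAssembly per clone, contigs left unassigned).
    A clone whose reads all fail the alignment filters has status
    ``not_amplified``; when a clone's two end reads best-match two
    different contigs, the better match is primary and the assembly is
    flagged as carrying an internal gap of unknown size.
    """
    params = params or Params()
    reads = dedupe_sanger(sanger_reads)
    reads.sort(key=lambda r: (r.clone_id, r.end, r.id))
    by_id = {c.id: c for c in contigs}
    space = Genome({c.id: c.sequence for c in contigs})  # forward-genome frame

    per_read: dict[str, tuple[SangerRead, GenomeAlignment]] = {}
    for r in reads:
        if len(r) < params.sanger_min_align:
            continue
        alns = [
            a for a in align_to_contigs(r.sequence, space, params, query_id=r.id)
            if _passes_filters(a, params)
        ]
        if not alns:
            continue
        hit = max(alns, key=lambda a: a.score)
        per_read[r.id] = (r, hit)

    clone_ids = sorted({r.clone_id for r in reads})
    assemblies: list[CloneAssembly] = []
    used_contigs: set[str] = set()
    for cid in clone_ids:
        matches = [
            (r, a) for r, a in per_read.values() if r.clone_id == cid
        ]
        if not matches:
            assemblies.append(CloneAssembly(clone_id=cid, status="not_amplified"))
            continue
        matches.sort(key=lambda ra: (-ra[1].score, ra[0].id))
        best_read, best_aln = matches[0]
        contig = by_id[best_aln.chrom]  # contig id doubles as target name
        # The contig is stored on the forward genome strand; the end
        # reads reveal the transcript orientation: a 5' read aligning
        # forward (or a 3' read aligning reverse) means the transcript
        # runs with the genome.
        sense_fwd = (best_read.end == FIVE_PRIME) == (best_aln.strand == "+")
        strand = "+" if sense_fwd else "-"
        oriented = contig.sequence if sense_fwd else revcomp(contig.sequence)
        asm = CloneAssembly(
            clone_id=cid,
            status="assembled",
            contig_id=contig.id,
            sequence=oriented,
            chrom=contig.chrom,
            strand=strand,
            exon_chain=list(contig.exon_chain),
        )
        used_contigs.add(contig.id)
        others = {a.chrom for _, a in matches[1:]}
        if others - {contig.id}:
            asm.internal_gap = True
            asm.secondary_contig_id = sorted(others - {contig.id})[0]
            used_contigs.add(asm.secondary_contig_id)
        # re-align the clone's reads against the oriented transcript so
        # the extension logic sees 5' reads forward and 3' reads reverse
        oriented_space = Genome({contig.id: oriented})
        for r, a in matches:
            if a.chrom != contig.id:
                continue
            re_alns = [
                x for x in align_to_contigs(r.sequence, oriented_space, params,
                                            query_id=r.id)
                if _passes_filters(x, params)
            ]
            if re_alns:
                extend_with_sanger(asm, r, max(re_alns, key=lambda x: x.score))
        assemblies.append(asm)
    unassigned = [c for c in contigs if c.id not in used_contigs]
    return assemblies, unassigned


__all__ = [
    "SangerRead",
    "CloneAssembly",
    "FIVE_PRIME",
    "THREE_PRIME",
    "dedupe_sanger",
    "assign_clones",
    "extend_with_sanger",
]
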