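"""Anchoring de novo contigs on the reference genome and merging them.

Contigs are placed by spliced alignment; ambiguous placements (score
ties) are discarded as repetitive, erroneous short terminal exons are
pruned, and contigs that overlap — or abut with a zero-base gap — on
the genome are merged into one anchored contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .aligner import Genome, align_contig_spliced, best_hit
from .core import GenomeAlignment, GenomeInterval, Params
from .reads import revcomp

_EXON_JOIN_GAP = 10  # blocks this close on the genome belong to one exon


def prune_terminal_exons(
    aln: GenomeAlignment, L: int = 12, D: int = 5
) -> GenomeAlignment:
    """Drop short, distant initial/terminal blocks, iterating to a fixpoint.

    A terminal block is removed when it is shorter than ``L`` bp and
    more than ``D`` bp away (on the genome) from its neighbour; such
    blocks are usually spurious placements of sequencing errors or
    polymorphisms near an exon boundary.  Interior blocks are never
    touched; removal can expose new removable terminals.  All blocks
    may be pruned away, in which case the caller drops the contig.
    """
    if not aln.blocks:
        raise ValueError("alignment has no blocks")
    blocks = list(aln.blocks)
    ins, dels, openings = aln.insertions, aln.deletions, aln.gap_openings

    def removable(idx_term: int, idx_adj: int) -> bool:
        b, a = blocks[idx_term], blocks[idx_adj]
        gap = a.t.start - b.t.end if idx_term < idx_adj else b.t.start - a.t.end
        return len(b) < L and gap > D

    changed = True
    while changed and len(blocks) > 1:
        changed = False
        if removable(0, 1):
            q_gap = blocks[1].q_start - blocks[0].q_end
            ins -= min(ins, max(0, q_gap))
            openings = max(0, openings - 1)
            blocks.pop(0)
            changed = True
        if len(blocks) > 1 and removable(-1, -2):
            q_gap = blocks[-1].q_start - blocks[-2].q_end
            ins -= min(ins, max(0, q_gap))
            openings = max(0, openings - 1)
            blocks.pop()
            changed = True
    return GenomeAlignment(
        query_id=aln.query_id,
        query_len=aln.query_len,
        strand=aln.strand,
        blocks=blocks,
        matches=sum(b.matches for b in blocks),
        mismatches=sum(b.mismatches for b in blocks),
        insertions=ins,
        deletions=dels,
        gap_openings=openings,
        repetitive=aln.repetitive,
    )


@dataclass
class FillRecord:
    kind: str  # exon | intron
    interval: GenomeInterval
    method: str


@dataclass
class AnchoredContig:
    """A contig placed on the genome: exon chain plus consensus sequence.

    ``sequence`` is on the forward genome strand and is exactly the
    concatenation of the exon interval sequences (contig bases where the
    contig aligned, reference bases across small contig deletions), so
    its length always equals the summed exon lengths.  ``strand`` is the
    transcript strand.
    """

    id: str
    chrom: str
    strand: str
    exon_chain: list[GenomeInterval]
    sequence: str
    score: int = 0
    sources: list[str] = field(default_factory=list)
    fills: list[FillRecord] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exon_chain[0].start

    @property
    def end(self) -> int:
        return self.exon_chain[-1].end

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        for a, b in zip(self.exon_chain, self.exon_chain[1:]):
            if b.start < a.end:
                raise ValueError("exon chain not increasing")
        if len(self.sequence) != sum(len(e) for e in self.exon_chain):
            raise ValueError("sequence length != exon chain length")

    def transcript_sequence(self) -> str:
        return self.sequence if self.strand == "+" else revcomp(self.sequence)

    def base_at(self, pos: int) -> str:
        off = 0
        for e in self.exon_chain:
            if e.start <= pos < e.end:
                return self.sequence[off + pos - e.start]
            off += len(e)
        raise KeyError(pos)


def anchored_from_alignment(
    aln: GenomeAlignment, contig_seq: str, genome: Genome
) -> AnchoredContig:
    """Project an aligned contig onto the genome.

    Blocks within ``_EXON_JOIN_GAP`` bp on the genome join into one exon
    interval; bases the contig deleted inside an exon come from the
    reference, and contig insertions are dropped (they have no genomic
    placement and are handled downstream by the evaluator).
    """
    oriented = contig_seq.upper() if aln.strand == "+" else revcomp(contig_seq.upper())
    groups: list[list] = [[aln.blocks[0]]]
    for b in aln.blocks[1:]:
        if b.t.start - groups[-1][-1].t.end <= _EXON_JOIN_GAP:
            groups[-1].append(b)
        else:
            groups.append([b])
    chain: list[GenomeInterval] = []
    seq_parts: list[str] = []
    for grp in groups:
        start, end = grp[0].t.start, grp[-1].t.end
        buf = list(genome.fetch(aln.chrom, start, end))
        for b in grp:
            for i in range(len(b)):
                buf[b.t.start - start + i] = oriented[b.q_start + i]
        chain.append(GenomeInterval(aln.chrom, start, end, "+"))
        seq_parts.append("".join(buf))
    ac = AnchoredContig(
        id=aln.query_id,
        chrom=aln.chrom,
        strand="+",  # orientation is settled by Sanger reads at assignment
        exon_chain=chain,
        sequence="".join(seq_parts),
        score=aln.score,
        sources=[aln.query_id],
    )
    ac.validate()
    return ac


@dataclass
class AnchoringReport:
    aligned: int = 0
    unaligned: list[str] = field(default_factory=list)
    repetitive: list[str] = field(default_factory=list)
    pruned_away: list[str] = field(default_factory=list)


def anchor_contigs(
    contigs: list[tuple[str, str]],
    genome: Genome,
    params: Params | None = None,
) -> tuple[list[AnchoredContig], AnchoringReport]:
    """Place every contig; keep uniquely best placements only."""
    params = params or Params()
    report = AnchoringReport()
    anchored: list[AnchoredContig] = []
    for cid, seq in contigs:
        alns = align_contig_spliced(seq, genome, params, query_id=cid)
        hit = best_hit(alns)
        if hit is None:
            (report.repetitive if alns else report.unaligned).append(cid)
            continue
        hit = prune_terminal_exons(hit, params.prune_len, params.prune_dist)
        if not hit.blocks:
            report.pruned_away.append(cid)
            continue
        report.aligned += 1
        anchored.append(anchored_from_alignment(hit, seq, genome))
    anchored.sort(key=lambda a: (a.chrom, a.strand, a.start, a.id))
    return anchored, report


def _touch(a: AnchoredContig, b: AnchoredContig) -> bool:
    """Overlap by >= 1 bp on the genome, or a zero-base gap between the
    terminal exon of one and the first exon of the other.

    Alignment strand is ignored: a cDNA contig aligns on whichever
    strand the assembler happened to emit it, so genomic position alone
    decides; transcript orientation is settled later by the Sanger end
    reads.
    """
    if a.chrom != b.chrom:
        return False
    if a.exon_chain[-1].end == b.exon_chain[0].start:
        return True
    if b.exon_chain[-1].end == a.exon_chain[0].start:
        return True
    for ea in a.exon_chain:
        for eb in b.exon_chain:
            if ea.start < eb.end and eb.start < ea.end:
                return True
    return False


def merge_overlapping(anchored: list[AnchoredContig]) -> list[AnchoredContig]:
    """Merge contigs that touch on the genome (transitive closure).

    The merged exon chain is the interval union of the members' exons;
    where sequences overlap, the base comes from the contig with the
    higher alignment score (ties: longer contig, then lexicographic id),
    which prefers the better-supported consensus deterministically.
    """
    items = sorted(anchored, key=lambda a: (a.chrom, a.strand, a.start, a.id))
    n = len(items)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    by_group: dict[str, list[int]] = {}
    for i, a in enumerate(items):
        by_group.setdefault(a.chrom, []).append(i)
    for idxs in by_group.values():
        for ii, i in enumerate(idxs):
            for j in idxs[ii + 1 :]:
                if items[j].start > items[i].end:
                    break
                if _touch(items[i], items[j]):
                    union(i, j)

    groups: dict[int, list[AnchoredContig]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(items[i])
    merged = [
        members[0] if len(members) == 1 else merge_group(members)
        for _, members in sorted(groups.items())
    ]
    merged.sort(key=lambda a: (a.chrom, a.strand, a.start, a.id))
    return merged


def merge_group(members: list[AnchoredContig]) -> AnchoredContig:
    members = sorted(members, key=lambda a: (a.score, len(a), a.id))
    chrom, strand = members[0].chrom, "+"
    bases: dict[int, str] = {}
    for m in members:  # ascending priority: later members overwrite
        off = 0
        for e in m.exon_chain:
            for i in range(len(e)):
                bases[e.start + i] = m.sequence[off + i]
            off += len(e)
    positions = sorted(bases)
    chain: list[GenomeInterval] = []
    seq_parts: list[str] = []
    run_start = positions[0]
    prev = positions[0]
    buf = [bases[prev]]
    for p in positions[1:]:
        if p == prev + 1:
            buf.append(bases[p])
        else:
            chain.append(GenomeInterval(chrom, run_start, prev + 1, "+"))
            seq_parts.append("".join(buf))
            run_start = p
            buf = [bases[p]]
        prev = p
    chain.append(GenomeInterval(chrom, run_start, prev + 1, "+"))
    seq_parts.append("".join(buf))
    out = AnchoredContig(
        id="+".join(sorted(s for m in members for s in [m.id])),
        chrom=chrom,
        strand=strand,
        exon_chain=chain,
        sequence="".join(seq_parts),
        score=max(m.score for m in members),
        sources=sorted({s for m in members for s in m.sources}),
        fills=[f for m in members for f in m.fills],
    )
    out.validate()
    return out


__all__ = [
    "AnchoredContig",
    "AnchoringReport",
    "FillRecord",
    "prune_terminal_exons",
    "anchored_from_alignment",
    "anchor_contigs",
    "merge_overlapping",
    "merge_group",
]
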