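"""Closing inter-contig gaps with raw shotgun reads.

Two gap classes are handled (second reference-assembly stage):

* **exon gaps** — short gaps (<= 1 kb by default) between contigs
  adjacent on the genome, presumed to be exonic sequence the de novo
  assembler missed.  Raw reads are aligned to the gap extended by
  ``ext`` bp on both sides; the gap is filled only when every base of
  the gap proper is covered by at least ``e_min`` uniquely placed reads.
* **intron gaps** — longer gaps presumed to be introns.  Reads are
  split into two parts at every allowed position and the parts are
  aligned, with at most one mismatch each and no indels, to the two
  exon-intron boundary candidate regions (2W bp windows centred on the
  facing contig ends).  A read voting for exactly one junction counts
  as support; junction coordinates are left-aligned so that reads
  observing different registers of a microhomologous junction agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .aligner import Genome, align_read_small_edit, best_hit
from .anchoring import AnchoredContig, FillRecord
from .core import GenomeInterval, Params
from .readstore import ReadStore
from .reads import enumerate_splits, polya_discard, revcomp
from .seedindex import encode


@dataclass
class GapCandidate:
    kind: str  # exon | intron
    left: str  # contig ids
    right: str
    interval: GenomeInterval


@dataclass
class JunctionCall:
    donor_end: int
    acceptor_start: int
    support: int

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValueError("donor must precede acceptor")


@dataclass
class GapOutcome:
    candidate: GapCandidate
    filled: bool
    n_alignments: int = 0
    min_coverage: int = 0
    mean_coverage: float = 0.0
    junction: JunctionCall | None = None


def find_gap_candidates(
    anchored: list[AnchoredContig], params: Params, stage: str | None = None
) -> list[GapCandidate]:
    """Candidate gaps between genome-adjacent contig pairs.

    With ``stage=None`` a gap is classified exon when its length is at
    most ``exon_gap_max``, else intron when inside the intron bounds.
    ``stage="intron"`` classifies by the intron bounds alone, so that
    short gaps left unfilled by exon closing can still be bridged as
    introns (the two ranges overlap by design).
    """
    out: list[GapCandidate] = []
    items = sorted(anchored, key=lambda a: (a.chrom, a.strand, a.start, a.id))
    for a, b in zip(items, items[1:]):
        if a.chrom != b.chrom:
            continue
        gap = b.start - a.end
        if gap <= 0:
            continue
        interval = GenomeInterval(a.chrom, a.end, b.start, "+")
        if stage == "intron":
            if params.intron_min <= gap <= params.intron_max:
                out.append(GapCandidate("intron", a.id, b.id, interval))
        elif gap <= params.exon_gap_max:
            out.append(GapCandidate("exon", a.id, b.id, interval))
        elif params.intron_min <= gap <= params.intron_max:
            out.append(GapCandidate("intron", a.id, b.id, interval))
    return out


# ---------------------------------------------------------------------------
# exon gaps


def exon_gap_coverage(
    gap: GapCandidate, store: ReadStore, genome: Genome, params: Params
) -> tuple[np.ndarray, int]:
    """Unique-alignment coverage over the gap proper.

    Reads are aligned to the gap extended by ``ext`` into both flanks
    (to avoid end effects); only reads with a unique best placement in
    the region contribute.  Returns (per-base coverage, #alignments).
    """
    if store.max_read_len > params.ext - 3:
        raise ValueError(
            f"read length {store.max_read_len} too long for ext={params.ext}; "
            "exon filling requires ext to exceed the read length by >= 3"
        )
    chrom = gap.interval.chrom
    start = max(0, gap.interval.start - params.ext)
    end = min(genome.chrom_len(chrom), gap.interval.end + params.ext)
    region = GenomeInterval(chrom, start, end, "+")
    region_seq = genome.fetch(chrom, start, end)
    cov = np.zeros(len(gap.interval), dtype=np.int64)
    n_aln = 0
    for rid in store.candidate_ids(region_seq):
        read = store.reads[int(rid)]
        alns = align_read_small_edit(
            read.sequence, [(region, region_seq)],
            params.fill_max_discrepancies, read.id,
        )
        hit = best_hit(alns)
        if hit is None:
            continue
        n_aln += 1
        lo = max(hit.t_start, gap.interval.start) - gap.interval.start
        hi = min(hit.t_end, gap.interval.end) - gap.interval.start
        if hi > lo:
            cov[lo:hi] += 1
    return cov, n_aln


def fill_exon_gap(
    gap: GapCandidate,
    left: AnchoredContig,
    right: AnchoredContig,
    store: ReadStore,
    genome: Genome,
    params: Params,
) -> tuple[AnchoredContig | None, GapOutcome]:
    """Merge the flanking contigs when the gap is adequately covered.

    The fill sequence itself comes from the reference genome over the
    gap interval; the reads only certify coverage.
    """
    cov, n_aln = exon_gap_coverage(gap, store, genome, params)
    outcome = GapOutcome(
        gap,
        filled=bool(cov.size and cov.min() >= params.e_min),
        n_alignments=n_aln,
        min_coverage=int(cov.min()) if cov.size else 0,
        mean_coverage=float(cov.mean()) if cov.size else 0.0,
    )
    if not outcome.filled:
        return None, outcome
    bridge = GenomeInterval(
        gap.interval.chrom, left.exon_chain[-1].start, right.exon_chain[0].end, "+"
    )
    chain = left.exon_chain[:-1] + [bridge] + right.exon_chain[1:]
    gap_seq = genome.fetch(gap.interval.chrom, gap.interval.start, gap.interval.end)
    merged = AnchoredContig(
        id=f"{left.id}+{right.id}",
        chrom=left.chrom,
        strand=left.strand,
        exon_chain=chain,
        sequence=left.sequence + gap_seq + right.sequence,
        score=max(left.score, right.score),
        sources=sorted(set(left.sources) | set(right.sources)),
        fills=left.fills + right.fills + [FillRecord("exon", gap.interval, "read_coverage")],
    )
    merged.validate()
    return merged, outcome


def close_exon_gaps(
    anchored: list[AnchoredContig],
    store: ReadStore,
    genome: Genome,
    params: Params,
) -> tuple[list[AnchoredContig], list[GapOutcome]]:
    """Left-to-right sweep attempting to fill every exon gap candidate."""
    items = sorted(anchored, key=lambda a: (a.chrom, a.strand, a.start, a.id))
    out: list[AnchoredContig] = []
    outcomes: list[GapOutcome] = []
    cur: AnchoredContig | None = None
    for nxt in items:
        if cur is None:
            cur = nxt
            continue
        gap = nxt.start - cur.end
        if cur.chrom == nxt.chrom and 0 < gap <= params.exon_gap_max:
            cand = GapCandidate(
                "exon", cur.id, nxt.id,
                GenomeInterval(cur.chrom, cur.end, nxt.start, "+"),
            )
            merged, outcome = fill_exon_gap(cand, cur, nxt, store, genome, params)
            outcomes.append(outcome)
            if merged is not None:
                cur = merged
                continue
        out.append(cur)
        cur = nxt
    if cur is not None:
        out.append(cur)
    return out, outcomes


# ---------------------------------------------------------------------------
# intron gaps


def left_align_junction(genome_seq_at, donor_end: int, acceptor_start: int,
                        limit: int = 50) -> tuple[int, int]:
    """Shift a junction to its leftmost equivalent register.

    Moving the junction one base left leaves the spliced product
    unchanged exactly when the base entering the intron on the left
    equals the base leaving it on the right.
    """
    for _ in range(limit):
        if donor_end <= 0:
            break
        a = genome_seq_at(donor_end - 1)
        b = genome_seq_at(acceptor_start - 1)
        if a != b or a is None:
            break
        donor_end -= 1
        acceptor_start -= 1
    return donor_end, acceptor_start


def _part_occurrences(oriented: np.ndarray, region: np.ndarray, max_mm: int):
    """Cumulative mismatch table of the read against every region offset.

    Returns (offsets x read_len) cumulative mismatch counts, where row o
    compares ``oriented`` with ``region[o:o+len]`` (padded positions
    always mismatch).
    """
    L = oriented.size
    pad = np.full(L, -9, dtype=np.int8)
    padded = np.concatenate([region, pad])
    win = sliding_window_view(padded, L)[: region.size]  # offsets 0..Tr-1
    return np.cumsum(win != oriented, axis=1)


def split_junction_votes(
    read_seq: str,
    left_region: tuple[int, np.ndarray],
    right_region: tuple[int, np.ndarray],
    params: Params,
) -> set[tuple[int, int]]:
    """(donor_end, acceptor_start) -> minimal total mismatches, for one read.

    The read (each orientation) is split at every allowed position; the
    5' part must align in the left boundary region and the 3' part in
    the right one, each with at most ``split_max_mm_per_part``
    mismatches and no indels.  Junctions are reported un-canonicalised,
    with the best mismatch total over all splits that induce them.
    """
    l_start, l_arr = left_region
    r_start, r_arr = right_region
    L = len(read_seq)
    splits = enumerate_splits(L, params.split_min_part)
    if not splits:
        return {}
    pairs: dict[tuple[int, int], int] = {}
    orientations = [encode(read_seq), encode(revcomp(read_seq))]
    max_mm = params.split_max_mm_per_part
    for oriented in orientations:
        cum_l = _part_occurrences(oriented, l_arr, max_mm)
        # suffix alignment against the right region: pad left so that
        # starts of the 3' part before the region window are expressible
        pad = np.full(L, -9, dtype=np.int8)
        padded_r = np.concatenate([pad, r_arr, pad])
        win_r = sliding_window_view(padded_r, L)[: L + r_arr.size]
        cum_r = np.cumsum(win_r != oriented, axis=1)
        total_r = cum_r[:, -1]
        for p in splits:
            occ5 = np.nonzero(
                (cum_l[:, p - 1] <= max_mm)
                & (np.arange(cum_l.shape[0]) + p <= l_arr.size)
            )[0]
            if occ5.size == 0:
                continue
            # row u of cum_r compares read base i with padded_r[u+i];
            # the 3' part (read[p:]) sits at region offset o3 = u + p - L
            suffix_mm = total_r - cum_r[:, p - 1]
            u = np.arange(cum_r.shape[0])
            o3 = u + p - L
            occ3 = np.nonzero(
                (suffix_mm <= max_mm)
                & (o3 >= 0)
                & (o3 + (L - p) <= r_arr.size)
            )[0]
            if occ3.size == 0:
                continue
            for o5 in occ5:
                donor = l_start + int(o5) + p
                mm5 = int(cum_l[o5, p - 1])
                for uu in occ3:
                    acceptor = r_start + int(uu) + p - L
                    if acceptor > donor:
                        mm = mm5 + int(suffix_mm[uu])
                        key = (donor, acceptor)
                        if key not in pairs or mm < pairs[key]:
                            pairs[key] = mm
    return pairs


def splice_fill(
    gap: GapCandidate,
    store: ReadStore,
    genome: Genome,
    params: Params,
) -> tuple[JunctionCall | None, GapOutcome]:
    """Find the splice junction inside an intron gap candidate.

    Per read: poly-A prefilter, split enumeration, part alignment to the
    two boundary regions, junction left-alignment, then the uniqueness
    rule — a read supporting more than one distinct junction is
    discarded.  The junction with most support wins (ties by leftmost
    coordinates), provided support reaches ``min_intron_support``.
    """
    W = params.boundary_halfwidth
    chrom = gap.interval.chrom
    clen = genome.chrom_len(chrom)
    l_start = max(0, gap.interval.start - W)
    l_end = min(clen, gap.interval.start + W)
    r_start = max(0, gap.interval.end - W)
    r_end = min(clen, gap.interval.end + W)
    l_seq = genome.fetch(chrom, l_start, l_end)
    r_seq = genome.fetch(chrom, r_start, r_end)
    l_arr = encode(l_seq)
    r_arr = encode(r_seq)
    chrom_seq = genome.sequences[chrom]

    def base_at(i: int):
        return chrom_seq[i] if 0 <= i < clen else None

    cand = np.union1d(store.candidate_ids(l_seq), store.candidate_ids(r_seq))
    votes: dict[tuple[int, int], int] = {}
    n_reads = 0
    for rid in cand:
        read = store.reads[int(rid)]
        if polya_discard(read.sequence, params.polya_stretch, params.polya_ratio):
            continue
        pairs = split_junction_votes(
            read.sequence, (l_start, l_arr), (r_start, r_arr), params
        )
        valid = {k: mm for k, mm in pairs.items() if k[1] - k[0] >= params.intron_min}
        if not valid:
            continue
        # registers reachable only by spending a mismatch are dominated
        # by any perfect placement the same read supports
        best_mm = min(valid.values())
        canon = {
            left_align_junction(base_at, d, a)
            for (d, a), mm in valid.items()
            if mm == best_mm
        }
        if len(canon) != 1:
            continue
        (d, a) = next(iter(canon))
        votes[(d, a)] = votes.get((d, a), 0) + 1
        n_reads += 1
    outcome = GapOutcome(gap, filled=False, n_alignments=n_reads)
    if not votes:
        return None, outcome
    (d, a), support = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    if support < params.min_intron_support:
        return None, outcome
    call = JunctionCall(d, a, support)
    outcome.filled = True
    outcome.junction = call
    return call, outcome


def link_intron(
    left: AnchoredContig,
    right: AnchoredContig,
    call: JunctionCall,
    genome: Genome,
) -> AnchoredContig:
    """Join two contigs across a recovered intron.

    The facing exon boundaries are moved to the called junction: the
    left contig's last exon ends at the donor site and the right
    contig's first exon starts at the acceptor, extending with reference
    bases or trimming contig bases as needed.  No intronic sequence is
    inserted.
    """
    d, a = call.donor_end, call.acceptor_start
    llast = left.exon_chain[-1]
    rfirst = right.exon_chain[0]
    d = max(d, llast.start + 1)
    a = min(a, rfirst.end - 1)
    lseq = left.sequence
    if d >= llast.end:
        lseq = lseq + genome.fetch(left.chrom, llast.end, d)
    else:
        lseq = lseq[: len(lseq) - (llast.end - d)]
    rseq = right.sequence
    if a <= rfirst.start:
        rseq = genome.fetch(right.chrom, a, rfirst.start) + rseq
    else:
        rseq = rseq[a - rfirst.start :]
    chain = (
        left.exon_chain[:-1]
        + [GenomeInterval(left.chrom, llast.start, d, "+")]
        + [GenomeInterval(right.chrom, a, rfirst.end, "+")]
        + right.exon_chain[1:]
    )
    merged = AnchoredContig(
        id=f"{left.id}+{right.id}",
        chrom=left.chrom,
        strand=left.strand,
        exon_chain=chain,
        sequence=lseq + rseq,
        score=max(left.score, right.score),
        sources=sorted(set(left.sources) | set(right.sources)),
        fills=left.fills + right.fills + [
            FillRecord("intron", GenomeInterval(left.chrom, d, a, "+"), "split_read")
        ],
    )
    merged.validate()
    return merged


def close_intron_gaps(
    anchored: list[AnchoredContig],
    store: ReadStore,
    genome: Genome,
    params: Params,
) -> tuple[list[AnchoredContig], list[GapOutcome]]:
    items = sorted(anchored, key=lambda a: (a.chrom, a.strand, a.start, a.id))
    out: list[AnchoredContig] = []
    outcomes: list[GapOutcome] = []
    cur: AnchoredContig | None = None
    for nxt in items:
        if cur is None:
            cur = nxt
            continue
        gap = nxt.start - cur.end
        if (
            cur.chrom == nxt.chrom
            and params.intron_min <= gap <= params.intron_max
        ):
            cand = GapCandidate(
                "intron", cur.id, nxt.id,
                GenomeInterval(cur.chrom, cur.end, nxt.start, "+"),
            )
            call, outcome = splice_fill(cand, store, genome, params)
            outcomes.append(outcome)
            if call is not None:
                cur = link_intron(cur, nxt, call, genome)
                continue
        out.append(cur)
        cur = nxt
    if cur is not None:
        out.append(cur)
    return out, outcomes


__all__ = [
    "GapCandidate",
    "JunctionCall",
    "GapOutcome",
    "find_gap_candidates",
    "exon_gap_coverage",
    "fill_exon_gap",
    "close_exon_gaps",
    "split_junction_votes",
    "splice_fill",
    "link_intron",
    "close_intron_gaps",
    "left_align_junction",
]
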