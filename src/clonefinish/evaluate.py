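"""Accuracy evaluation of reconstructed clones.

The central metric is CDS-structure consistency: a reconstruction is
consistent when the genomic exon-intron structure of the reference
coding sequence is completely contained in the reconstructed structure
— every CDS exon inside a reconstructed exon, with identical intron
junctions between internal CDS exons.  Inconsistencies are classified
as wrong exon boundaries, a sequence gap inside an exon, a missing
clone end, or a missing link (intron) between exons.

Base-level accuracy is measured by global alignment of the output
sequence against the finished reference sequence, and the relationship
between per-clone shotgun coverage and consistency is summarised in
10-fold coverage bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .core import GenomeAlignment, GenomeInterval, per_clone_coverage
from .aligner import parse_cigar
from .reads import ShortRead, revcomp
from .seedindex import encode

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
EXON_BOUNDARY = "exon_boundary"
INTERNAL_GAP = "internal_gap"
END_MISSING = "end_missing"
MISSING_LINK = "missing_link"

_FAILURE_ORDER = (EXON_BOUNDARY, INTERNAL_GAP, END_MISSING, MISSING_LINK)


@dataclass
class CdsStructure:
    clone_id: str
    exons: list[GenomeInterval]

    def __post_init__(self) -> None:
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end or a.chrom != b.chrom or a.strand != b.strand:
                raise ValueError("CDS exons must be increasing on one chrom/strand")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand


@dataclass
class ConsistencyResult:
    clone_id: str
    verdict: str
    failure: str = "none"


@dataclass
class BaseAccuracy:
    ref_len: int
    aligned_len: int
    matches: int
    mismatches: int
    insertions: int
    deletions: int

    @property
    def match_ratio(self) -> float:
        return self.matches / self.aligned_len if self.aligned_len else 0.0


def classify_consistency(
    reconstructed: list[GenomeInterval] | list[list[GenomeInterval]],
    cds: CdsStructure,
) -> ConsistencyResult:
    """Compare a reconstructed exon structure with the reference CDS.

    ``reconstructed`` is one exon chain or several (a clone whose two
    halves were never linked contributes two chains).  Failure classes
    are reported with precedence exon_boundary > internal_gap >
    end_missing > missing_link.
    """
    chains: list[list[GenomeInterval]]
    if reconstructed and isinstance(reconstructed[0], GenomeInterval):
        chains = [list(reconstructed)]  # type: ignore[list-item]
    else:
        chains = [list(c) for c in reconstructed]  # type: ignore[union-attr]
    chains = [
        c for c in chains
        if c and c[0].chrom == cds.chrom
    ]
    if not chains:
        return ConsistencyResult(cds.clone_id, INCONSISTENT, EXON_BOUNDARY)

    failures: set[str] = set()
    exons: list[tuple[GenomeInterval, int]] = []  # (exon, chain index)
    for ci, c in enumerate(chains):
        for e in c:
            exons.append((e, ci))
    exons.sort(key=lambda ei: (ei[0].start, ei[0].end))
    last = len(cds.exons) - 1
    containing: dict[int, tuple[GenomeInterval, int]] = {}

    for k, c in enumerate(cds.exons):
        over = [(e, ci) for e, ci in exons if e.start < c.end and c.start < e.end]
        covered = 0
        touch_start = touch_end = False
        for e, _ in over:
            covered += min(e.end, c.end) - max(e.start, c.start)
            touch_start |= e.start <= c.start
            touch_end |= e.end >= c.end
        if covered < len(c):
            if k == 0 and not touch_start:
                failures.add(END_MISSING)
            elif k == last and not touch_end:
                failures.add(END_MISSING)
            elif not over:
                failures.add(MISSING_LINK if 0 < k < last else END_MISSING)
            else:
                failures.add(INTERNAL_GAP)
            continue
        cont = [(e, ci) for e, ci in over if e.start <= c.start and c.end <= e.end]
        if not cont:
            # fully covered yet split: a junction or chain break inside
            same_chain = len({ci for _, ci in over}) == 1
            failures.add(EXON_BOUNDARY if same_chain else INTERNAL_GAP)
            continue
        e, ci = cont[0]
        containing[k] = (e, ci)
        if 0 < k and e.start != c.start:
            failures.add(EXON_BOUNDARY)
        if k < last and e.end != c.end:
            failures.add(EXON_BOUNDARY)

    for k in range(last):
        if k not in containing or (k + 1) not in containing:
            continue
        (e1, c1), (e2, c2) = containing[k], containing[k + 1]
        if c1 != c2:
            failures.add(MISSING_LINK)
            continue
        if e1 == e2:
            failures.add(EXON_BOUNDARY)  # intron absent from reconstruction
            continue
        chain = chains[c1]
        i1, i2 = chain.index(e1), chain.index(e2)
        if i2 != i1 + 1:
            failures.add(EXON_BOUNDARY)

    if not failures:
        return ConsistencyResult(cds.clone_id, CONSISTENT)
    for f in _FAILURE_ORDER:
        if f in failures:
            return ConsistencyResult(cds.clone_id, INCONSISTENT, f)
    raise AssertionError("unreachable")


def base_accuracy(output_seq: str, reference_seq: str) -> BaseAccuracy:
    """Global-alignment base accuracy of an output sequence against the
    finished reference; insertions are output-only bases, deletions are
    reference-only bases."""
    if not output_seq or not reference_seq:
        raise ValueError("base_accuracy requires non-empty sequences")
    res = edlib.align(output_seq.upper(), reference_seq.upper(), mode="NW", task="path")
    matches = mismatches = ins = dels = 0
    for op, n in parse_cigar(res["cigar"]):
        if op == "=":
            matches += n
        elif op in ("X", "M"):
            mismatches += n
        elif op == "I":
            ins += n
        elif op == "D":
            dels += n
    return BaseAccuracy(
        ref_len=len(reference_seq),
        aligned_len=len(output_seq),
        matches=matches,
        mismatches=mismatches,
        insertions=ins,
        deletions=dels,
    )


def map_transcript_range(
    aln: GenomeAlignment, t_start: int, t_end: int, join_gap: int = 10
) -> list[GenomeInterval]:
    """Project a transcript-coordinate interval through a spliced
    alignment onto the genome.

    For a minus-strand alignment the query frame is the reverse
    complement, so the transcript interval is mirrored first.  Genomic
    pieces closer than ``join_gap`` (small indel scars) are merged.
    """
    L = aln.query_len
    if aln.strand == "-":
        t_start, t_end = L - t_end, L - t_start
    pieces: list[GenomeInterval] = []
    for b in aln.blocks:
        a = max(b.q_start, t_start)
        z = min(b.q_end, t_end)
        if z > a:
            pieces.append(
                GenomeInterval(
                    b.t.chrom,
                    b.t.start + (a - b.q_start),
                    b.t.start + (z - b.q_start),
                    aln.strand,
                )
            )
    pieces.sort(key=lambda e: e.start)
    merged: list[GenomeInterval] = []
    for p in pieces:
        if merged and p.start - merged[-1].end <= join_gap:
            merged[-1] = GenomeInterval(
                p.chrom, merged[-1].start, max(p.end, merged[-1].end), p.strand
            )
        else:
            merged.append(p)
    return merged


def transcript_cds_range(
    exon_chain: list[GenomeInterval],
    cds_exons: list[GenomeInterval],
    strand: str,
) -> tuple[int, int]:
    """Invert the genomic CDS projection: transcript-coordinate CDS
    range of an annotated gene, given its (genomically sorted) exon
    chain and CDS exon intervals."""
    if not cds_exons:
        raise ValueError("no CDS exons")
    L = sum(len(e) for e in exon_chain)
    lo = cds_exons[0].start
    hi = cds_exons[-1].end
    a = b = None
    off = 0
    for e in exon_chain:
        if a is None and e.start <= lo < e.end:
            a = off + (lo - e.start)
        if e.start < hi <= e.end:
            b = off + (hi - e.start)
        off += len(e)
    if a is None or b is None:
        raise ValueError("CDS exons fall outside the exon chain")
    if strand == "-":
        a, b = L - b, L - a
    return a, b


def coverage_bins(
    coverages: list[float], verdicts: list[str], bin_width: float = 10.0
) -> pd.DataFrame:
    """Bin clones by per-clone fold coverage (10-fold bins by default)
    and tabulate the fraction classified consistent per bin."""
    if len(coverages) != len(verdicts):
        raise ValueError("coverages and verdicts must be parallel")
    rows: dict[int, list[int]] = {}
    for cov, v in zip(coverages, verdicts):
        if cov < 0:
            raise ValueError("negative coverage")
        b = int(cov // bin_width)
        n, k = rows.get(b, (0, 0))
        rows[b] = [n + 1, k + (1 if v == CONSISTENT else 0)]
    out = pd.DataFrame(
        [
            {
                "bin_lo": b * bin_width,
                "bin_hi": (b + 1) * bin_width,
                "n": n,
                "n_consistent": k,
                "pct_consistent": 100.0 * k / n,
            }
            for b, (n, k) in sorted(rows.items())
        ]
    )
    return out


def downsample_reads(
    reads: list[ShortRead], fraction: float, seed: int
) -> list[ShortRead]:
    """Uniform sample without replacement of round(fraction * N) reads,
    reproducible under the seed; input order preserved."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = int(round(fraction * len(reads)))
    if n >= len(reads):
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    idx.sort()
    return [reads[i] for i in idx]


def count_reads_per_clone(
    reads: list[ShortRead],
    clone_seqs: dict[str, str],
    max_mm: int = 3,
    seed_k: int = 12,
) -> dict[str, int]:
    """Reads aligned per clone, allowing up to ``max_mm`` mismatches.

    Seed-verified exact counting: each read is anchored by exact
    ``seed_k``-mers at non-overlapping offsets (a read with at most two
    errors always retains one) and verified by Hamming distance at the
    implied offset, in both orientations.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    arrs: dict[str, np.ndarray] = {}
    for cid, seq in clone_seqs.items():
        arrs[cid] = encode(seq)
        for i in range(0, len(seq) - seed_k + 1):
            index.setdefault(seq[i : i + seed_k], []).append((cid, i))
    counts = {cid: 0 for cid in clone_seqs}
    for read in reads:
        L = len(read.sequence)
        hit_clones: set[str] = set()
        for oriented in (read.sequence, revcomp(read.sequence)):
            oarr = encode(oriented)
            for off in range(0, L - seed_k + 1, seed_k):
                for cid, pos in index.get(oriented[off : off + seed_k], ()):
                    if cid in hit_clones:
                        continue
                    s = pos - off
                    if s < 0 or s + L > arrs[cid].size:
                        continue
                    if int(np.count_nonzero(arrs[cid][s : s + L] != oarr)) <= max_mm:
                        hit_clones.add(cid)
        for cid in hit_clones:
            counts[cid] += 1
    return counts


def clone_coverages(
    reads: list[ShortRead], clone_seqs: dict[str, str], read_len: int = 36
) -> dict[str, float]:
    counts = count_reads_per_clone(reads, clone_seqs)
    return {
        cid: per_clone_coverage(counts[cid], read_len, len(seq))
        for cid, seq in clone_seqs.items()
    }


# ---------------------------------------------------------------------------
# consumables cost model


def cost_per_clone(
    run_cost: float,
    usable_lanes: float,
    clones_per_lane: float,
    pcr_eff: float,
    accuracy: float,
    sanger_cost: float,
) -> float:
    """Per-clone consumables cost of multiclone shotgun sequencing on a
    short-read instrument: the run cost is spread over usable lanes and
    clones per lane, discounted by PCR success and assembly accuracy,
    plus the one-pass Sanger end reads.  Rounded to cents."""
    for name, v in (
        ("run_cost", run_cost), ("usable_lanes", usable_lanes),
        ("clones_per_lane", clones_per_lane), ("sanger_cost", sanger_cost),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if not (0 < pcr_eff <= 1 and 0 < accuracy <= 1):
        raise ValueError("pcr_eff and accuracy must be in (0, 1]")
    cost = run_cost / usable_lanes / clones_per_lane / pcr_eff / accuracy + sanger_cost
    return round(cost, 2)


def cost_multiclone_sanger(
    clone_len_kb: float,
    coverage: float,
    read_len_bp: float,
    read_cost: float,
    primers_per_kb: float,
    primer_cost: float,
) -> float:
    """Per-clone cost of the older Sanger-based multiclone shotgun:
    shotgun reads to the target coverage plus custom finishing primers.
    Rounded to cents."""
    if min(clone_len_kb, coverage, read_len_bp, read_cost) <= 0:
        raise ValueError("inputs must be positive")
    reads_cost = clone_len_kb * 1000.0 * coverage / read_len_bp * read_cost
    primer_total = clone_len_kb * primers_per_kb * primer_cost
    return round(reads_cost + primer_total, 2)


_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf(seq: str) -> tuple[int, int, str]:
    """Longest stop-to-stop open stretch over three frames on both
    strands (standard code).  Returns (start, end, strand) in the
    coordinates of ``seq``.  A convenience for species without CDS
    annotation; not a gene finder."""
    seq = seq.upper()
    L = len(seq)
    best = (0, 0, "+")
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            start = frame
            i = frame
            while i + 3 <= len(s):
                if s[i : i + 3] in _STOPS:
                    if i - start > best[1] - best[0]:
                        best = (start, i, strand) if strand == "+" else (
                            L - i, L - start, strand
                        )
                    start = i + 3
                i += 3
            if i - start > best[1] - best[0]:
                best = (start, i, strand) if strand == "+" else (L - i, L - start, strand)
    return best


__all__ = [
    "CdsStructure",
    "ConsistencyResult",
    "BaseAccuracy",
    "classify_consistency",
    "base_accuracy",
    "map_transcript_range",
    "coverage_bins",
    "downsample_reads",
    "count_reads_per_clone",
    "clone_coverages",
    "cost_per_clone",
    "cost_multiclone_sanger",
    "longest_orf",
    "CONSISTENT",
    "INCONSISTENT",
    "EXON_BOUNDARY",
    "INTERNAL_GAP",
    "END_MISSING",
    "MISSING_LINK",
]
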