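"""Core record types, coordinate conventions and assembly statistics.

All coordinates are 0-based half-open on the forward genome strand.
Alignments of minus-strand queries store query coordinates in the
reverse-complemented frame (the orientation that actually aligned), the
same convention PSL uses, so that blocks are strictly increasing in both
query and target regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A genomic interval: 0-based inclusive start, exclusive end."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Block:
    """One ungapped piece of an alignment (an exon block).

    ``q_start``/``q_end`` are query coordinates in the aligned
    orientation; ``t`` is the matching genome interval of equal length.
    """

    q_start: int
    q_end: int
    t: GenomeInterval
    matches: int = 0
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.q_end - self.q_start != len(self.t):
            raise ValueError("block query and target lengths differ")

    def __len__(self) -> int:
        return self.q_end - self.q_start


@dataclass
class GenomeAlignment:
    """A query placed on the genome as an ordered chain of blocks."""

    query_id: str
    query_len: int
    strand: str
    blocks: list[Block]
    matches: int = 0
    mismatches: int = 0
    insertions: int = 0  # query bases absent from the target
    deletions: int = 0  # target bases absent from the query
    gap_openings: int = 0
    repetitive: bool = False

    @property
    def score(self) -> int:
        """matches - mismatches - one point per gap opening."""
        return self.matches - self.mismatches - self.gap_openings

    @property
    def chrom(self) -> str:
        return self.blocks[0].t.chrom

    @property
    def t_start(self) -> int:
        return self.blocks[0].t.start

    @property
    def t_end(self) -> int:
        return self.blocks[-1].t.end

    @property
    def q_start(self) -> int:
        return self.blocks[0].q_start

    @property
    def q_end(self) -> int:
        return self.blocks[-1].q_end

    @property
    def aligned_len(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def identity(self) -> float:
        """matches / (matches + mismatches + gapped bases) in the aligned span."""
        denom = self.matches + self.mismatches + self.insertions + self.deletions
        return self.matches / denom if denom else 0.0

    def validate(self) -> None:
        if sum(len(b) for b in self.blocks) != self.matches + self.mismatches:
            raise ValueError("block lengths inconsistent with match counts")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if not (a.q_end <= b.q_start and a.t.end <= b.t.start):
                raise ValueError("blocks not increasing in query and target")
            if a.t.chrom != b.t.chrom or a.t.strand != b.t.strand:
                raise ValueError("blocks span chromosomes/strands")


@dataclass
class Params:
    """Every tunable threshold of the pipeline, with defaults.

    Units are base pairs unless noted.  ``e_min`` is the minimum number
    of unique read alignments per base required to accept an exon-gap
    fill (empirical default 2; raise it for very deep runs).  The intron
    length bounds are open pipeline choices, not literature constants.
    """

    exon_gap_max: int = 1000
    e_min: int = 2
    ext: int = 50
    boundary_halfwidth: int = 50  # W: boundary candidate region is 2W bp
    prune_len: int = 12  # L
    prune_dist: int = 5  # D
    intron_min: int = 40
    intron_max: int = 500_000
    split_min_part: int = 13
    split_max_mm_per_part: int = 1
    polya_stretch: int = 12
    polya_ratio: float = 0.5
    fill_max_discrepancies: int = 3
    sanger_min_align: int = 30
    sanger_min_identity: float = 0.90
    min_intron_support: int = 1

    def __post_init__(self) -> None:
        for name in (
            "exon_gap_max", "e_min", "ext", "boundary_halfwidth", "prune_len",
            "prune_dist", "intron_min", "intron_max", "split_min_part",
            "split_max_mm_per_part", "polya_stretch", "fill_max_discrepancies",
            "sanger_min_align", "min_intron_support",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.polya_ratio <= 1 and 0 < self.sanger_min_identity <= 1):
            raise ValueError("ratio parameters must be in (0, 1]")
        if self.intron_min >= self.intron_max:
            raise ValueError("intron_min must be < intron_max")

    def check_read_len(self, read_len: int) -> None:
        """Exon filling needs the target extension to exceed the read length
        by at least three bases, or end effects bias the coverage test."""
        if read_len > self.ext - 3:
            raise ValueError(
                f"read length {read_len} requires ext > {read_len + 3}; "
                f"increase Params.ext (currently {self.ext})"
            )

    def check_split(self, read_len: int) -> None:
        if 2 * self.split_min_part > read_len:
            raise ValueError(
                f"2*split_min_part={2 * self.split_min_part} exceeds read length {read_len}"
            )


def n50(lengths: list[int]) -> int:
    """N50: the length L such that pieces of length >= L hold at least
    half of the total bases."""
    if not lengths:
        raise ValueError("n50 of an empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    raise AssertionError("unreachable")


def select_best_assembly(candidates: list[list[int]] | list) -> object:
    """Pick the candidate contig set with the largest N50.

    Candidates may be lists of lengths or objects with a ``lengths``
    attribute.  Ties go to the larger total length, then input order.
    """
    if not candidates:
        raise ValueError("no candidate assemblies")

    def lengths_of(c):
        return c if isinstance(c, (list, tuple)) else c.lengths

    best = None
    best_key = None
    for i, cand in enumerate(candidates):
        ls = list(lengths_of(cand))
        key = (n50(ls), sum(ls), -i)
        if best_key is None or key > best_key:
            best, best_key = cand, key
    return best


def per_clone_coverage(n_aligned: int, read_len: int, clone_len: int) -> float:
    """Fold coverage of one clone: reads aligned x read length / clone length."""
    if clone_len <= 0:
        raise ValueError("clone_len must be positive")
    return n_aligned * read_len / clone_len


__all__ = [
    "GenomeInterval",
    "Block",
    "GenomeAlignment",
    "Params",
    "n50",
    "select_best_assembly",
    "per_clone_coverage",
    "replace",
]
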