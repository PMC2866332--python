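"""Read preprocessing and the read-splitting primitive for spliced alignment."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase and map U to T; other symbols pass through."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class ShortRead:
    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def drop_ambiguous(reads: Iterable[ShortRead]) -> list[ShortRead]:
    """Remove reads containing any ambiguous base (N); order preserved."""
    return [r for r in reads if "N" not in r.sequence]


def _max_run(seq: str, base: str) -> int:
    best = cur = 0
    for c in seq:
        cur = cur + 1 if c == base else 0
        best = max(best, cur)
    return best


def polya_discard(
    seq: str, polya_stretch: int = 12, polya_ratio: float = 0.5
) -> bool:
    """True when a read should be discarded by the poly-A filter.

    A read is discarded when it or its reverse complement contains a run
    of A strictly longer than ``polya_stretch``, or when the fraction of
    A in either orientation strictly exceeds ``polya_ratio``.  A run of
    A in the reverse complement is a run of T in the read, and the A
    fraction of the reverse complement is the T fraction of the read, so
    the test is symmetric under reverse complement by construction.
    """
    seq = normalize(seq)
    n = len(seq)
    if n == 0:
        return False
    if _max_run(seq, "A") > polya_stretch or _max_run(seq, "T") > polya_stretch:
        return True
    if seq.count("A") / n > polya_ratio or seq.count("T") / n > polya_ratio:
        return True
    return False


def enumerate_splits(read_len: int, min_part: int = 1) -> list[int]:
    """Positions at which a read can be cut into a 5' and a 3' part.

    Position p means parts ``read[:p]`` and ``read[p:]``.  Only splits
    where both parts are at least ``min_part`` long are returned; a
    36-bp read has 35 internal positions in total and 11 once parts
    shorter than 13 bp are excluded.
    """
    if read_len < 2:
        raise ValueError("read_len must be >= 2")
    if min_part < 1:
        raise ValueError("min_part must be >= 1")
    return list(range(min_part, read_len - min_part + 1))


@dataclass
class FilterReport:
    reads_in: int = 0
    dropped_n: int = 0
    dropped_polya: int = 0

    @property
    def reads_out(self) -> int:
        return self.reads_in - self.dropped_n - self.dropped_polya


def preprocess_reads(
    reads: Iterable[ShortRead], apply_polya: bool = False,
    polya_stretch: int = 12, polya_ratio: float = 0.5,
) -> tuple[list[ShortRead], FilterReport]:
    """Drop ambiguous reads (and optionally poly-A reads) with accounting.

    The poly-A filter belongs to the intron-closing stage and is off by
    default here; upstream base-caller purity filtering is treated as a
    pass-through (pre-filtered read sets are accepted as-is).
    """
    report = FilterReport()
    kept: list[ShortRead] = []
    for r in reads:
        report.reads_in += 1
        if "N" in r.sequence:
            report.dropped_n += 1
            continue
        if apply_polya and polya_discard(r.sequence, polya_stretch, polya_ratio):
            report.dropped_polya += 1
            continue
        kept.append(r)
    return kept, report


__all__ = [
    "ShortRead",
    "revcomp",
    "normalize",
    "drop_ambiguous",
    "polya_discard",
    "enumerate_splits",
    "preprocess_reads",
    "FilterReport",
]
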