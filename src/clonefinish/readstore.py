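"""A searchable pool of short reads.

Gap closing aligns raw reads against genomic regions that are orders of
magnitude shorter than the genome, so the store inverts the problem: it
indexes every k-mer of every read once, and a region query returns the
read ids sharing at least one exact k-mer with the region (either
orientation).  Full alignment then runs only on those candidates.

A read whose every seed k-mer is disrupted by errors can escape the
prefilter; with the default k=12 a 36-bp read is recalled whenever it
carries at most two errors, which at percent-scale error rates loses a
negligible fraction of coverage.
"""

from __future__ import annotations

import numpy as np

from .reads import ShortRead, revcomp
from .seedindex import kmer_codes


class ReadStore:
    def __init__(self, reads: list[ShortRead], k: int = 12):
        self.reads = list(reads)
        self.k = k
        codes_list = []
        ids_list = []
        for i, r in enumerate(self.reads):
            c = kmer_codes(r.sequence, k)
            c = c[c >= 0]
            if c.size:
                codes_list.append(np.unique(c))
                ids_list.append(np.full(codes_list[-1].size, i, dtype=np.int64))
        if codes_list:
            codes = np.concatenate(codes_list)
            ids = np.concatenate(ids_list)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._ids = ids[order]
        else:
            self._codes = np.empty(0, dtype=np.int64)
            self._ids = np.empty(0, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def max_read_len(self) -> int:
        return max((len(r) for r in self.reads), default=0)

    def candidate_ids(self, region_seq: str) -> np.ndarray:
        """Indices of reads sharing an exact k-mer with the region on
        either strand, in ascending order."""
        if self._codes.size == 0:
            return np.empty(0, dtype=np.int64)
        qcodes = np.concatenate(
            [kmer_codes(region_seq, self.k), kmer_codes(revcomp(region_seq), self.k)]
        )
        qcodes = np.unique(qcodes[qcodes >= 0])
        hits = []
        lo = np.searchsorted(self._codes, qcodes, side="left")
        hi = np.searchsorted(self._codes, qcodes, side="right")
        for a, b in zip(lo, hi):
            if b > a:
                hits.append(self._ids[a:b])
        if not hits:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(hits))


__all__ = ["ReadStore"]
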