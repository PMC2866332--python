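"""Synthetic study material: genomes, multi-exon clones, shotgun reads.

The generator emulates the experimental input of a multiclone shotgun
run: a set of full-length cDNA clones, none sharing genomic regions,
amplified per clone with variable efficiency (lognormal spread, with
outright PCR failure at a configurable rate), nebulised and sequenced
as short single-end reads whose start density ramps down towards the
clone ends (fragmentation is inefficient near molecule ends), with
i.i.d. substitution errors.  A configurable fraction of clones carries
at least one exon shorter than the read length — the case that defeats
pure reference assembly of short reads.

Everything is deterministic under the config seed; independent streams
are derived for the world, the shotgun reads and the Sanger reads so
that regenerating one does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clones import FIVE_PRIME, THREE_PRIME, SangerRead
from .core import GenomeInterval
from .reads import ShortRead, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 0
    n_clones: int = 100
    genome_len: int = 2_000_000
    exons_per_gene: tuple[int, int] = (2, 8)
    exon_len: tuple[int, int] = (45, 600)
    short_exon_len: tuple[int, int] = (15, 35)
    short_exon_clone_fraction: float = 0.14
    intron_len: tuple[int, int] = (100, 2000)
    clone_len: tuple[int, int] = (1200, 2900)  # mean ~2 kb
    utr_len: tuple[int, int] = (60, 250)
    pcr_success: float = 0.79
    mean_coverage: float = 50.0
    amplification_sigma: float = 0.6  # lognormal sigma of per-clone yield
    end_depletion_bp: int = 150
    subst_error: float = 0.005
    read_len: int = 36
    sanger_len: tuple[int, int] = (400, 800)
    sanger_error: float = 1e-3
    gene_spacer: tuple[int, int] = (300, 800)

    def __post_init__(self) -> None:
        for r in (0.0, self.short_exon_clone_fraction, self.pcr_success,
                  self.subst_error, self.sanger_error):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0, 1]")
        for lo, hi in (self.exons_per_gene, self.exon_len, self.intron_len,
                       self.clone_len, self.sanger_len):
            if lo > hi or lo <= 0:
                raise ValueError("ranges must be non-degenerate and positive")


@dataclass
class CloneTruth:
    clone_id: str
    chrom: str
    strand: str
    exon_chain: list[GenomeInterval]  # genomic order
    cds_start: int  # transcript coordinates
    cds_end: int
    sequence: str  # transcript orientation (mRNA sense)
    has_short_exon: bool = False

    def cds_genomic(self) -> list[GenomeInterval]:
        """CDS exon intervals on the genome, in genomic order.

        Transcript coordinates run 5'->3'; on the minus strand that is
        right-to-left on the genome, so the range is mirrored through
        the spliced length first.
        """
        L = len(self.sequence)
        a, b = self.cds_start, self.cds_end
        if self.strand == "-":
            a, b = L - self.cds_end, L - self.cds_start
        out: list[GenomeInterval] = []
        off = 0
        for e in self.exon_chain:
            lo = max(off, a)
            hi = min(off + len(e), b)
            if hi > lo:
                out.append(
                    GenomeInterval(e.chrom, e.start + (lo - off), e.start + (hi - off),
                                   self.strand)
                )
            off += len(e)
        return out


@dataclass
class World:
    config: SimConfig
    genome: dict[str, str]
    clones: list[CloneTruth] = field(default_factory=list)

    def clone_seqs(self) -> dict[str, str]:
        return {c.clone_id: c.sequence for c in self.clones}


def _partition(rng: np.random.Generator, total: int, n: int, min_len: int) -> list[int]:
    """Random composition of ``total`` into ``n`` parts, each >= min_len."""
    extra = total - n * min_len
    if extra < 0:
        raise ValueError("total too small for the requested parts")
    cuts = np.sort(rng.integers(0, extra + 1, size=n - 1))
    parts = np.diff(np.concatenate([[0], cuts, [extra]]))
    return [int(p) + min_len for p in parts]


def generate_world(config: SimConfig) -> World:
    """Lay out non-overlapping multi-exon genes on a random genome.

    The clone sequence is the spliced genomic sequence (no polymorphism
    between clones and reference is simulated).  The truth table keeps
    the genomic exon chain and the CDS range in transcript coordinates.
    """
    rng = np.random.default_rng([config.seed, 0])
    chrom = "chr1"
    genome_digits = rng.integers(0, 4, size=config.genome_len, dtype=np.int8)
    genome_seq = "".join(_BASES[genome_digits])
    clones: list[CloneTruth] = []
    cursor = int(rng.integers(*config.gene_spacer))
    short_flags = rng.random(config.n_clones) < config.short_exon_clone_fraction
    for i in range(config.n_clones):
        clone_len = int(rng.integers(config.clone_len[0], config.clone_len[1] + 1))
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        short = bool(short_flags[i])
        if short:
            s_len = int(rng.integers(config.short_exon_len[0], config.short_exon_len[1] + 1))
            s_idx = int(rng.integers(0, n_exons))
            rest = _partition(rng, clone_len - s_len, n_exons - 1, config.exon_len[0]) \
                if n_exons > 1 else []
            exon_lens = rest[:s_idx] + [s_len] + rest[s_idx:]
        else:
            exon_lens = _partition(rng, clone_len, n_exons, config.exon_len[0])
        intron_lens = [
            int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            for _ in range(n_exons - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        span = sum(exon_lens) + sum(intron_lens)
        if cursor + span > config.genome_len:
            raise ValueError(
                f"genome of {config.genome_len} bp too small for {config.n_clones} genes"
            )
        chain: list[GenomeInterval] = []
        pos = cursor
        for j, el in enumerate(exon_lens):
            chain.append(GenomeInterval(chrom, pos, pos + el, "+"))
            pos += el
            if j < n_exons - 1:
                pos += intron_lens[j]
        spliced = "".join(genome_seq[e.start : e.end] for e in chain)
        sequence = spliced if strand == "+" else revcomp(spliced)
        utr5 = int(rng.integers(config.utr_len[0], config.utr_len[1] + 1))
        utr3 = int(rng.integers(config.utr_len[0], config.utr_len[1] + 1))
        cds_start = min(utr5, max(0, clone_len - 300))
        cds_end = max(cds_start + 150, clone_len - utr3)
        cds_end = min(clone_len, cds_end)
        cds_end -= (cds_end - cds_start) % 3
        clones.append(
            CloneTruth(
                clone_id=f"clone{i:04d}",
                chrom=chrom,
                strand=strand,
                exon_chain=chain,
                cds_start=cds_start,
                cds_end=cds_end,
                sequence=sequence,
                has_short_exon=short,
            )
        )
        cursor = pos + int(rng.integers(*config.gene_spacer))
    return World(config=config, genome={chrom: genome_seq}, clones=clones)


def shotgun_reads(world: World, config: SimConfig | None = None) -> list[ShortRead]:
    """Simulate the pooled shotgun lane.

    Per clone: a Bernoulli PCR-success draw, a lognormal amplification
    factor, read starts sampled with a linear density ramp from zero
    over ``end_depletion_bp`` at both molecule ends, random strand, and
    i.i.d. substitution errors.
    """
    config = config or world.config
    rng = np.random.default_rng([config.seed, 1])
    rl = config.read_len
    dep = max(config.end_depletion_bp, 1)
    out: list[ShortRead] = []
    for clone in world.clones:
        seq = clone.sequence
        L = len(seq)
        amplified = rng.random() < config.pcr_success
        amp = float(rng.lognormal(0.0, config.amplification_sigma))
        if not amplified or L < rl:
            continue
        n_reads = int(round(config.mean_coverage * amp * L / rl))
        if n_reads == 0:
            continue
        n_pos = L - rl + 1
        s = np.arange(n_pos)
        w = np.minimum(1.0, (s + 1) / dep) * np.minimum(
            1.0, (L - rl - s + 1) / dep
        )
        w = np.clip(w, 0.0, None)
        if w.sum() == 0:
            w[:] = 1.0
        starts = rng.choice(n_pos, size=n_reads, p=w / w.sum())
        flips = rng.random(n_reads) < 0.5
        err = rng.random((n_reads, rl)) < config.subst_error
        shifts = rng.integers(1, 4, size=(n_reads, rl))
        digits = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.int8)
        for bi, b in enumerate("ACGT"):
            lut[ord(b)] = bi
        enc = lut[digits]
        for ri in range(n_reads):
            st = int(starts[ri])
            d = enc[st : st + rl].copy()
            d[err[ri]] = (d[err[ri]] + shifts[ri][err[ri]]) % 4
            rseq = "".join(_BASES[d])
            if flips[ri]:
                rseq = revcomp(rseq)
            out.append(ShortRead(f"{clone.clone_id}_r{ri:06d}", rseq))
    return out


def _with_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    lut = np.zeros(256, dtype=np.int8)
    for bi, b in enumerate("ACGT"):
        lut[ord(b)] = bi
    d = lut[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()
    err = rng.random(d.size) < rate
    d[err] = (d[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
    return "".join(_BASES[d])


def sanger_ends(world: World, config: SimConfig | None = None) -> list[SangerRead]:
    """One 5' and one 3' Sanger end read per clone; the 3' read is
    reverse complemented (as sequenced from the other end)."""
    config = config or world.config
    rng = np.random.default_rng([config.seed, 2])
    out: list[SangerRead] = []
    for clone in world.clones:
        L = len(clone.sequence)
        l5 = min(int(rng.integers(config.sanger_len[0], config.sanger_len[1] + 1)), L)
        l3 = min(int(rng.integers(config.sanger_len[0], config.sanger_len[1] + 1)), L)
        r5 = _with_errors(rng, clone.sequence[:l5], config.sanger_error)
        r3 = _with_errors(rng, revcomp(clone.sequence[L - l3 :]), config.sanger_error)
        out.append(SangerRead(f"{clone.clone_id}_5p", clone.clone_id, FIVE_PRIME, r5))
        out.append(SangerRead(f"{clone.clone_id}_3p", clone.clone_id, THREE_PRIME, r3))
    return out


# ---------------------------------------------------------------------------
# de novo contig emulation


def _rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        out = (out << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return out


def debruijn_contigs(
    reads: list[ShortRead],
    k: int = 25,
    min_count: int = 2,
    min_len: int = 100,
) -> list[tuple[str, str]]:
    """A deliberately simple de Bruijn unitig assembler.

    Canonical k-mers seen fewer than ``min_count`` times are discarded
    (the classic error filter), and maximal non-branching paths are
    emitted as contigs, dropping those shorter than ``min_len`` the way
    production assemblers discard dust.  It stands in for an external
    de novo assembler at desk scale: fragmentation emerges naturally
    where k-mer coverage dips, which is exactly what the downstream
    reference-guided stages are meant to repair.
    """
    lut = np.zeros(256, dtype=np.int64)
    for bi, b in enumerate("ACGT"):
        lut[ord(b)] = bi
    chunks = []
    for r in reads:
        s = r.sequence
        if len(s) < k or "N" in s:
            continue
        d = lut[np.frombuffer(s.encode(), dtype=np.uint8)]
        n = d.size - k + 1
        codes = np.zeros(n, dtype=np.int64)
        for i in range(k):
            codes = (codes << 2) | d[i : i + n]
        chunks.append(codes)
    if not chunks:
        return []
    fwd = np.concatenate(chunks)
    canon = np.minimum(fwd, _rc_codes(fwd, k))
    uniq, counts = np.unique(canon, return_counts=True)
    kept_canon = uniq[counts >= min_count]
    kept = set(kept_canon.tolist()) | set(_rc_codes(kept_canon, k).tolist())

    mask = (1 << (2 * (k - 1))) - 1
    shift_hi = 2 * (k - 1)

    def right_exts(c: int) -> list[int]:
        base = (c & mask) << 2
        return [b for b in range(4) if (base | b) in kept]

    def left_exts(c: int) -> list[int]:
        base = c >> 2
        return [a for a in range(4) if ((a << shift_hi) | base) in kept]

    def rc_one(c: int) -> int:
        out = 0
        for _ in range(k):
            out = (out << 2) | (3 - (c & 3))
            c >>= 2
        return out

    def decode(c: int) -> str:
        s = []
        for _ in range(k):
            s.append("ACGT"[c & 3])
            c >>= 2
        return "".join(reversed(s))

    visited: set[int] = set()
    contigs: list[tuple[str, str]] = []
    idx = 0
    for start in sorted(kept_canon.tolist()):
        if start in visited:
            continue
        path = [start]
        # extend right
        cur = start
        while True:
            exts = right_exts(cur)
            if len(exts) != 1:
                break
            nxt = ((cur & mask) << 2) | exts[0]
            if nxt in visited or nxt == start or len(left_exts(nxt)) != 1:
                break
            path.append(nxt)
            visited.add(nxt)
            visited.add(rc_one(nxt))
            cur = nxt
        # extend left
        cur = start
        while True:
            exts = left_exts(cur)
            if len(exts) != 1:
                break
            prv = (exts[0] << shift_hi) | (cur >> 2)
            if prv in visited or prv == start or len(right_exts(prv)) != 1:
                break
            path.insert(0, prv)
            visited.add(prv)
            visited.add(rc_one(prv))
            cur = prv
        visited.add(start)
        visited.add(rc_one(start))
        seq = decode(path[0]) + "".join("ACGT"[c & 3] for c in path[1:])
        if len(seq) >= min_len:
            contigs.append((f"ctg{idx:05d}", seq))
            idx += 1
    return contigs


def slice_contigs(
    world: World,
    seed: int = 0,
    frag_len: tuple[int, int] = (300, 900),
    overlap: int = 50,
    dropout: float = 0.1,
) -> list[tuple[str, str]]:
    """The other contig emulator: cut each true transcript into
    overlapping fragments and drop some — handy for tests that need
    controlled fragmentation independent of the read set."""
    rng = np.random.default_rng([seed, 3])
    out: list[tuple[str, str]] = []
    idx = 0
    for clone in world.clones:
        seq = clone.sequence
        pos = 0
        while pos < len(seq):
            ln = int(rng.integers(frag_len[0], frag_len[1] + 1))
            piece = seq[pos : pos + ln]
            keep = rng.random() >= dropout
            if keep and len(piece) >= 60:
                out.append((f"frag{idx:05d}", piece))
                idx += 1
            pos += max(1, ln - overlap)
    return out


__all__ = [
    "SimConfig",
    "CloneTruth",
    "World",
    "generate_world",
    "shotgun_reads",
    "sanger_ends",
    "debruijn_contigs",
    "slice_contigs",
]
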