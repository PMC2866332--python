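"""Internal seeded aligner.

Three modes back the pipeline:

* ``align_read_small_edit`` — guaranteed-complete placement of a short
  read against small target regions at bounded edit distance.  The
  guarantee is by pigeonhole seeding: the read is cut into
  ``max_d + 1`` equal parts, one of which must match exactly in any
  placement with at most ``max_d`` unit-cost edits; every candidate
  offset implied by an exact part hit (plus/minus ``max_d``) is then
  scored by banded edit distance.
* ``align_contig_spliced`` — seed-and-chain spliced alignment of a
  contig (or any long query) against a genome, allowing intron-sized
  target gaps between co-linear blocks.
* the same chainer with a small gap cap serves as an unspliced
  free-overlap aligner for Sanger reads against contigs.

Scores are ``matches - mismatches - gap openings`` (one point per gap
opening, introns included), which is only required to induce a total
order: the best alignment per query is kept, and exact score ties are
discarded as repetitive placements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from .core import Block, GenomeAlignment, GenomeInterval, Params
from .reads import revcomp
from .seedindex import KmerIndex, kmer_codes

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

SEED_K = 12  # seed size for contig/genome chaining


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


class Genome:
    """Named sequences plus a lazily built k-mer index.

    Chromosome sequences are concatenated with runs of N so that no
    k-mer window spans two sequences; index positions map back to
    (chrom, offset).
    """

    def __init__(self, sequences: dict[str, str], k: int = SEED_K, max_hits: int = 128):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.k = k
        self.max_hits = max_hits
        self._names: list[str] = []
        self._offsets: list[int] = []
        parts = []
        off = 0
        for name, seq in self.sequences.items():
            self._names.append(name)
            self._offsets.append(off)
            parts.append(seq)
            off += len(seq) + k
        self._concat = ("N" * k).join(parts)
        self._offsets_arr = np.array(self._offsets, dtype=np.int64)
        self._index: KmerIndex | None = None

    @property
    def index(self) -> KmerIndex:
        if self._index is None:
            self._index = KmerIndex(self._concat, self.k, self.max_hits)
        return self._index

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        return seq[max(0, start) : min(len(seq), end)]

    def chrom_len(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def locate(self, concat_pos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._offsets_arr, concat_pos, side="right")) - 1
        return self._names[i], concat_pos - self._offsets[i]


# ---------------------------------------------------------------------------
# small-edit read alignment


def _alignment_from_cigar(
    query_id: str,
    query_len: int,
    strand: str,
    chrom: str,
    q_off: int,
    t_off: int,
    cigar: str,
) -> GenomeAlignment:
    """Build a block-chain record from an edlib extended cigar.

    ``I`` consumes query only, ``D`` consumes target only; runs of
    ``=``/``X`` form ungapped blocks.
    """
    blocks: list[Block] = []
    q = q_off
    t = t_off
    bq = q
    bt = t
    bm = bx = 0
    matches = mismatches = ins = dels = openings = 0

    def flush():
        nonlocal bm, bx
        if q > bq:
            blocks.append(
                Block(bq, q, GenomeInterval(chrom, bt, bt + (q - bq), "+"),
                      matches=bm, mismatches=bx)
            )
        bm = bx = 0

    for op, n in parse_cigar(cigar):
        if op == "=":
            q += n
            t += n
            matches += n
            bm += n
        elif op in ("X", "M"):
            q += n
            t += n
            mismatches += n
            bx += n
        elif op == "I":
            flush()
            q += n
            bq, bt = q, t
            ins += n
            openings += 1
        elif op == "D":
            flush()
            t += n
            bq, bt = q, t
            dels += n
            openings += 1
    flush()
    return GenomeAlignment(
        query_id=query_id,
        query_len=query_len,
        strand=strand,
        blocks=blocks,
        matches=matches,
        mismatches=mismatches,
        insertions=ins,
        deletions=dels,
        gap_openings=openings,
    )


def align_read_small_edit(
    read_seq: str,
    targets: list[tuple[GenomeInterval, str]],
    max_d: int,
    query_id: str = "read",
) -> list[GenomeAlignment]:
    """All placements of a read in the targets within ``max_d`` edits.

    A placement is identified by (target, strand, start offset); for
    each start offset the best prefix alignment of the read into the
    window starting there is scored, and reported when its unit-cost
    edit distance is at most ``max_d``.  Both strands are searched; the
    output is complete (no placement within ``max_d`` edits is missed).
    """
    if not targets:
        raise ValueError("align_read_small_edit requires at least one target")
    if max_d < 0:
        raise ValueError("max_d must be >= 0")
    read_seq = read_seq.upper()
    L = len(read_seq)
    k = max(1, L // (max_d + 1))
    out: list[GenomeAlignment] = []
    for ti, (interval, tseq) in enumerate(targets):
        tseq = tseq.upper()
        tlen = len(tseq)
        max_start = tlen - (L - max_d)
        if max_start < 0:
            continue
        for strand, oriented in (("+", read_seq), ("-", revcomp(read_seq))):
            cand: set[int] = set()
            for j in range(max_d + 1):
                part = oriented[j * k : (j + 1) * k]
                if len(part) < k:
                    break
                p = tseq.find(part)
                while p != -1:
                    implied = p - j * k
                    for d in range(-max_d, max_d + 1):
                        s = implied + d
                        if 0 <= s <= max_start:
                            cand.add(s)
                    p = tseq.find(part, p + 1)
            seen: set[tuple] = set()
            for s in sorted(cand):
                window = tseq[s : s + L + max_d]
                res = edlib.align(oriented, window, mode="SHW", task="path")
                if res["editDistance"] < 0 or res["editDistance"] > max_d:
                    continue
                cigar, s_norm = _strip_leading_deletion(res["cigar"], s)
                aln = _alignment_from_cigar(
                    query_id, L, strand, interval.chrom,
                    0, interval.start + s_norm, cigar,
                )
                key = (ti, strand, tuple((b.q_start, b.q_end, b.t.start) for b in aln.blocks))
                if key in seen:
                    continue
                seen.add(key)
                out.append(aln)
    out.sort(key=lambda a: (a.chrom, a.t_start, a.strand))
    return out


def _strip_leading_deletion(cigar: str, offset: int) -> tuple[str, int]:
    """A leading run of target-only bases is not part of the placement;
    drop it and advance the start offset so equivalent placements found
    from neighbouring seed offsets collapse to one record."""
    ops = parse_cigar(cigar)
    if ops and ops[0][0] == "D":
        n = ops[0][1]
        return "".join(f"{ln}{op}" for op, ln in ops[1:]), offset + n
    return cigar, offset


def best_hit(alignments: list[GenomeAlignment]) -> GenomeAlignment | None:
    """Keep the single best-scoring alignment of one query.

    A unique maximum wins; an exact score tie means the query is
    repetitive and nothing is returned (the caller may flag it).
    """
    if not alignments:
        return None
    ids = {a.query_id for a in alignments}
    if len(ids) > 1:
        raise ValueError(f"best_hit over mixed queries: {sorted(ids)}")
    best_score = max(a.score for a in alignments)
    top = [a for a in alignments if a.score == best_score]
    if len(top) > 1:
        for a in alignments:
            a.repetitive = True
        return None
    return top[0]


# ---------------------------------------------------------------------------
# spliced seed-and-chain alignment


@dataclass
class _Run:
    q0: int
    t0: int  # concatenated-genome coordinate
    ln: int

    @property
    def q_end(self) -> int:
        return self.q0 + self.ln

    @property
    def t_end(self) -> int:
        return self.t0 + self.ln


def _collect_runs(oriented: str, genome: Genome) -> list[_Run]:
    codes = kmer_codes(oriented, genome.k)
    hits: list[tuple[int, int]] = []
    index = genome.index
    for q, code in enumerate(codes):
        for t in index.lookup(int(code)):
            hits.append((int(t) - q, q))  # (diagonal, query pos)
    if not hits:
        return []
    hits.sort()
    runs: list[_Run] = []
    k = genome.k
    diag0, q0 = hits[0]
    prev_q = q0
    for diag, q in hits[1:]:
        if diag == diag0 and q == prev_q + 1:
            prev_q = q
            continue
        runs.append(_Run(q0, diag0 + q0, prev_q - q0 + k))
        diag0, q0, prev_q = diag, q, q
    runs.append(_Run(q0, diag0 + q0, prev_q - q0 + k))
    return runs


_MAX_Q_GAP = 60  # unaligned query bases tolerated at a join
_MAX_OVERLAP = 15  # microhomology slack at junctions
_JOIN_PENALTY = 1
_INTRON_PENALTY = 8
_MIN_INTRON_FLANK = 15  # runs shorter than this cannot open an intron
_MIN_MEAN_EXON = 25  # chains of scattered seed-length exons are noise


def _chain(
    runs: list[tuple[str, _Run]], max_t_gap: int, intron_min: int
) -> tuple[list[_Run], int]:
    """Best co-linear chain through the runs (quadratic DP).

    Runs carry their chromosome name; joins never cross chromosomes.
    """
    runs = sorted(runs, key=lambda cr: (cr[0], cr[1].t0, cr[1].q0))
    n = len(runs)
    score = [r.ln for _, r in runs]
    prev = [-1] * n
    for i in range(n):
        ci, ri = runs[i]
        for j in range(i):
            cj, rj = runs[j]
            if ci != cj:
                continue
            if not (ri.t0 > rj.t0 and ri.t_end > rj.t_end
                    and ri.q0 > rj.q0 and ri.q_end > rj.q_end):
                continue
            if ri.q0 < rj.q_end - _MAX_OVERLAP or ri.t0 < rj.t_end - _MAX_OVERLAP:
                continue
            t_gap = ri.t0 - rj.t_end
            q_gap = ri.q0 - rj.q_end
            if t_gap > max_t_gap or q_gap > _MAX_Q_GAP:
                continue
            if (t_gap - q_gap) >= intron_min:
                # an intron join must be supported by solid exact runs on
                # both sides, or stray seed hits chain genome-wide
                if ri.ln < _MIN_INTRON_FLANK or rj.ln < _MIN_INTRON_FLANK:
                    continue
                pen = _INTRON_PENALTY
            else:
                pen = _JOIN_PENALTY
            s = score[j] + ri.ln - pen
            if s > score[i]:
                score[i] = s
                prev[i] = j
    best = int(np.argmax(score)) if n else -1
    chain = []
    i = best
    while i != -1:
        chain.append(runs[i][1])
        i = prev[i]
    chain.reverse()
    return chain, (score[best] if n else 0)


def _trim_overlaps(chain: list[_Run]) -> list[_Run]:
    """Resolve query/target overlaps between consecutive runs by trimming
    the tail of the left run — junction ambiguity resolves to the
    leftmost donor placement."""
    out: list[_Run] = []
    for run in chain:
        run = _Run(run.q0, run.t0, run.ln)
        while out:
            cur = out[-1]
            h = max(cur.q_end - run.q0, cur.t_end - run.t0, 0)
            if h == 0:
                break
            cur.ln -= h
            if cur.ln <= 0:
                out.pop()
                continue
            break
        out.append(run)
    return [r for r in out if r.ln > 0]


def _segments(chain: list[_Run], intron_min: int) -> list[list[_Run]]:
    segs: list[list[_Run]] = [[chain[0]]]
    for run in chain[1:]:
        prevr = segs[-1][-1]
        t_gap = run.t0 - prevr.t_end
        q_gap = run.q0 - prevr.q_end
        if (t_gap - q_gap) >= intron_min:
            segs.append([run])
        else:
            segs[-1].append(run)
    return segs


_TERMINAL_EXT = 30  # extend alignment to query ends over at most this many bases


def _terminal_extension(qext: str, text: str) -> int:
    """How far to extend an alignment past its last seed towards the
    query end (both strings run outward from the alignment edge).

    Greedy score-maximising extension (+1 match, -2 mismatch): stray
    query bases that do not belong at this locus — e.g. the first bases
    of the next exon on a contig that ends just past a junction — score
    negative and stay unaligned, matching the policy of discarding
    unaligned contig parts rather than forcing them onto the genome.
    """
    n = min(len(qext), len(text))
    best_len = 0
    best_score = 0
    score = 0
    for i in range(n):
        score += 1 if qext[i] == text[i] else -2
        if score > best_score:
            best_score = score
            best_len = i + 1
    return best_len


def align_contig_spliced(
    contig_seq: str,
    genome: Genome,
    params: Params | None = None,
    query_id: str = "contig",
    max_t_gap: int | None = None,
    max_loci: int = 8,
    min_aligned: int = 20,
) -> list[GenomeAlignment]:
    """Spliced alignments of a contig against the genome, best first.

    Multiple loci are reported (up to ``max_loci``) so the caller can
    apply the best-hit/tie-discard rule; chains scoring below half the
    best chain are not pursued.
    """
    params = params or Params()
    if max_t_gap is None:
        max_t_gap = params.intron_max
    contig_seq = contig_seq.upper()
    L = len(contig_seq)
    if L < genome.k:
        return []
    results: list[GenomeAlignment] = []
    best_chain_score = None
    for strand in ("+", "-"):
        oriented = contig_seq if strand == "+" else revcomp(contig_seq)
        runs = [(genome.locate(r.t0)[0], r) for r in _collect_runs(oriented, genome)]
        while runs and len(results) < max_loci:
            chain, chain_score = _chain(runs, max_t_gap, params.intron_min)
            if not chain:
                break
            if best_chain_score is None or chain_score > best_chain_score:
                best_chain_score = chain_score
            if chain_score < max(min_aligned, 0.5 * best_chain_score):
                break
            used = {(r.q0, r.t0) for r in chain}
            runs = [(c, r) for c, r in runs if (r.q0, r.t0) not in used]
            aln = _build_alignment(oriented, chain, genome, params, query_id, strand)
            if aln is not None and aln.aligned_len >= min_aligned and _plausible(aln, params):
                results.append(aln)
    results.sort(key=lambda a: (-a.score, a.chrom, a.t_start, a.strand))
    return results


def _plausible(aln: GenomeAlignment, params: Params) -> bool:
    """Reject chains that are collections of isolated seed hits: the
    mean exon length of a genuine cDNA alignment far exceeds the seed
    size even when individual exons are short."""
    n_exons = 1
    for a, b in zip(aln.blocks, aln.blocks[1:]):
        if b.t.start - a.t.end >= params.intron_min:
            n_exons += 1
    return aln.aligned_len / n_exons >= _MIN_MEAN_EXON


def _build_alignment(
    oriented: str,
    chain: list[_Run],
    genome: Genome,
    params: Params,
    query_id: str,
    strand: str,
) -> GenomeAlignment | None:
    chain = _trim_overlaps(chain)
    if not chain:
        return None
    chrom, _ = genome.locate(chain[0].t0)
    chrom_off = chain[0].t0 - genome.locate(chain[0].t0)[1]
    clen = genome.chrom_len(chrom)
    segs = _segments(chain, params.intron_min)
    L = len(oriented)

    blocks: list[Block] = []
    matches = mismatches = ins = dels = openings = 0
    prev_q_end = None
    for si, seg in enumerate(segs):
        q0, q1 = seg[0].q0, seg[-1].q_end
        t0, t1 = seg[0].t0 - chrom_off, seg[-1].t_end - chrom_off
        if si == 0 and 0 < q0 <= _TERMINAL_EXT:
            shift = _terminal_extension(
                oriented[:q0][::-1], genome.fetch(chrom, max(0, t0 - q0), t0)[::-1]
            )
            q0 -= shift
            t0 -= shift
        if si == len(segs) - 1 and 0 < L - q1 <= _TERMINAL_EXT:
            shift = _terminal_extension(
                oriented[q1:], genome.fetch(chrom, t1, t1 + (L - q1))
            )
            q1 += shift
            t1 += shift
        qseg = oriented[q0:q1]
        tseg = genome.fetch(chrom, t0, t1)
        res = edlib.align(qseg, tseg, mode="NW", task="path")
        part = _alignment_from_cigar(query_id, L, strand, chrom, q0, t0, res["cigar"])
        if prev_q_end is not None:
            openings += 1  # the intron join
            gap_q = q0 - prev_q_end
            if gap_q > 0:
                ins += gap_q  # query bases stranded at the junction
        blocks.extend(part.blocks)
        matches += part.matches
        mismatches += part.mismatches
        ins += part.insertions
        dels += part.deletions
        openings += part.gap_openings
        prev_q_end = q1
    aln = GenomeAlignment(
        query_id=query_id,
        query_len=L,
        strand=strand,
        blocks=blocks,
        matches=matches,
        mismatches=mismatches,
        insertions=ins,
        deletions=dels,
        gap_openings=openings,
    )
    try:
        aln.validate()
    except ValueError:
        return None
    return aln


def align_to_contigs(
    query_seq: str,
    contigs: Genome,
    params: Params | None = None,
    query_id: str = "query",
    max_join_gap: int = 50,
) -> list[GenomeAlignment]:
    """Unspliced (small-gap) overlap alignment of a long read against a
    set of contig sequences, used for Sanger clone assignment."""
    return align_contig_spliced(
        query_seq, contigs, params, query_id,
        max_t_gap=max_join_gap, max_loci=16,
    )


__all__ = [
    "Genome",
    "align_read_small_edit",
    "align_contig_spliced",
    "align_to_contigs",
    "best_hit",
    "parse_cigar",
]
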