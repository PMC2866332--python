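import numpy as np
import pytest

from clonefinish.aligner import Genome
from clonefinish.anchoring import AnchoredContig
from clonefinish.core import GenomeInterval, Params
from clonefinish.gapfill import (
    GapCandidate,
    close_exon_gaps,
    close_intron_gaps,
    exon_gap_coverage,
    fill_exon_gap,
    find_gap_candidates,
    left_align_junction,
    splice_fill,
    split_junction_votes,
)
from clonefinish.readstore import ReadStore
from clonefinish.reads import ShortRead
from tests.conftest import random_seq


def contig(cid, chrom, exons, genome_seq):
    seq = "".join(genome_seq[s:e] for s, e in exons)
    return AnchoredContig(
        id=cid, chrom=chrom, strand="+",
        exon_chain=[GenomeInterval(chrom, s, e) for s, e in exons],
        sequence=seq,
    )


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(17)
    g = random_seq(rng, 20_000)
    return g, Genome({"chr1": g})


def tiling_reads(g, start, end, step=4, read_len=36):
    return [
        ShortRead(f"t{p}", g[p : p + read_len])
        for p in range(start, end - read_len + 1, step)
    ]


class TestGapCandidates:
    def _pair(self, gap):
        return [
            contig("a", "chr1", [(1000, 2000)], "A" * 3000 + "C" * 10_000),
            contig("b", "chr1", [(2000 + gap, 2500 + gap)], "A" * 3000 + "C" * 10_000),
        ]

    def test_short_gap_is_exon_candidate(self):
        cands = find_gap_candidates(self._pair(400), Params())
        assert [c.kind for c in cands] == ["exon"]
        assert (cands[0].interval.start, cands[0].interval.end) == (2000, 2400)

    def test_long_gap_is_intron_candidate(self):
        cands = find_gap_candidates(self._pair(5000), Params())
        assert [c.kind for c in cands] == ["intron"]

    def test_different_chromosomes_yield_nothing(self):
        a = contig("a", "chr1", [(1000, 2000)], "A" * 13_000)
        b = contig("b", "chr2", [(2400, 2900)], "A" * 13_000)
        assert find_gap_candidates([a, b], Params()) == []

    def test_intron_stage_reclassifies_short_unfilled_gaps(self):
        cands = find_gap_candidates(self._pair(400), Params(), stage="intron")
        assert [c.kind for c in cands] == ["intron"]

    def test_gap_outside_both_ranges_yields_nothing(self):
        cands = find_gap_candidates(self._pair(600_000), Params())
        assert cands == []


class TestExonFill:
    def test_well_covered_gap_fills_and_merges(self, planted):
        g, genome = planted
        left = contig("L", "chr1", [(4000, 5000)], g)
        right = contig("R", "chr1", [(5040, 5600)], g)
        reads = tiling_reads(g, 4900, 5200, step=4)
        store = ReadStore(reads)
        gap = GapCandidate("exon", "L", "R", GenomeInterval("chr1", 5000, 5040))
        merged, outcome = fill_exon_gap(gap, left, right, store, genome, Params())
        assert outcome.filled and merged is not None
        assert [(e.start, e.end) for e in merged.exon_chain] == [(4000, 5600)]
        assert merged.sequence == g[4000:5600]

    def test_uncovered_base_blocks_fill(self, planted):
        g, genome = planted
        left = contig("L", "chr1", [(4000, 5000)], g)
        right = contig("R", "chr1", [(5040, 5600)], g)
        # reads cover only the left half of the gap
        reads = tiling_reads(g, 4900, 5020, step=2)
        store = ReadStore(reads)
        gap = GapCandidate("exon", "L", "R", GenomeInterval("chr1", 5000, 5040))
        merged, outcome = fill_exon_gap(gap, left, right, store, genome, Params())
        assert merged is None and not outcome.filled

    def test_coverage_one_below_e_min_blocks_fill(self, planted):
        g, genome = planted
        left = contig("L", "chr1", [(4000, 5000)], g)
        right = contig("R", "chr1", [(5040, 5600)], g)
        reads = tiling_reads(g, 4950, 5120, step=36)  # depth 1
        store = ReadStore(reads)
        gap = GapCandidate("exon", "L", "R", GenomeInterval("chr1", 5000, 5040))
        cov, _ = exon_gap_coverage(gap, store, genome, Params())
        assert cov.min() >= 1
        merged, outcome = fill_exon_gap(gap, left, right, store, genome, Params())
        assert merged is None and outcome.min_coverage < 2

    def test_adding_reads_never_unfills(self, planted):
        g, genome = planted
        gap = GapCandidate("exon", "L", "R", GenomeInterval("chr1", 5000, 5040))
        base = tiling_reads(g, 4900, 5200, step=4)
        extra = tiling_reads(g, 4900, 5200, step=7)
        cov1, _ = exon_gap_coverage(gap, ReadStore(base), genome, Params())
        cov2, _ = exon_gap_coverage(gap, ReadStore(base + extra), genome, Params())
        assert (cov2 >= cov1).all()

    def test_read_longer_than_ext_budget_is_config_error(self, planted):
        g, genome = planted
        gap = GapCandidate("exon", "L", "R", GenomeInterval("chr1", 5000, 5040))
        store = ReadStore([ShortRead("big", g[4000:4060])])  # 60 bp > ext-3
        with pytest.raises(ValueError, match="ext"):
            exon_gap_coverage(gap, store, genome, Params())


class TestSpliceFill:
    def _junction_world(self, rng_seed=21, homology=0):
        rng = np.random.default_rng(rng_seed)
        g = random_seq(rng, 12_000)
        donor, acceptor = 5_000, 6_000
        if homology:
            # make intron start mirror the acceptor bases
            g = g[:donor] + g[acceptor : acceptor + homology] + g[donor + homology :]
            g = g[:12_000]
        tx = g[donor - 200 : donor] + g[acceptor : acceptor + 200]
        reads = [ShortRead(f"s{i}", tx[i : i + 36]) for i in range(164, 201)]
        return g, Genome({"chr1": g}), donor, acceptor, reads

    def test_planted_junction_recovered_exactly(self):
        g, genome, donor, acceptor, reads = self._junction_world()
        gap = GapCandidate("intron", "L", "R", GenomeInterval("chr1", donor, acceptor))
        call, outcome = splice_fill(gap, ReadStore(reads), genome, Params())
        assert call is not None
        assert (call.donor_end, call.acceptor_start) == (donor, acceptor)
        assert call.support >= 1

    def test_single_error_free_spanning_read_suffices(self):
        g, genome, donor, acceptor, _ = self._junction_world()
        tx = g[donor - 18 : donor] + g[acceptor : acceptor + 18]
        gap = GapCandidate("intron", "L", "R", GenomeInterval("chr1", donor, acceptor))
        call, _ = splice_fill(gap, ReadStore([ShortRead("one", tx)]), genome, Params())
        assert call is not None and call.support == 1
        assert (call.donor_end, call.acceptor_start) == (donor, acceptor)

    def test_polya_junction_reads_discarded_before_splitting(self):
        from clonefinish.reads import polya_discard

        rng = np.random.default_rng(23)
        g = random_seq(rng, 12_000)
        donor, acceptor = 5_000, 6_000
        # a 13-A stretch straddles the junction (6 A end the donor exon,
        # 7 A begin the acceptor exon): the true spanning read triggers
        # the poly-A prefilter and contributes no votes
        g = g[: donor - 6] + "A" * 6 + g[donor:acceptor] + "A" * 7 + g[acceptor + 7 :]
        genome = Genome({"chr1": g})
        tx = g[donor - 18 : donor] + g[acceptor : acceptor + 18]
        assert polya_discard(tx)
        gap = GapCandidate("intron", "L", "R", GenomeInterval("chr1", donor, acceptor))
        call, _ = splice_fill(gap, ReadStore([ShortRead("pa", tx)]), genome, Params())
        assert call is None

    def test_read_with_two_valid_pairs_discarded(self):
        rng = np.random.default_rng(29)
        g = random_seq(rng, 12_000)
        donor, acceptor = 5_000, 6_000
        # duplicate the acceptor-side 40-mer inside the right boundary
        # region so the 3' part aligns twice -> two valid pairs
        dup = g[acceptor : acceptor + 23]
        g = g[:acceptor - 23] + dup + g[acceptor:]
        g = g[:12_000]
        genome = Genome({"chr1": g})
        tx = g[donor - 18 : donor] + g[acceptor : acceptor + 18]
        gap = GapCandidate("intron", "L", "R", GenomeInterval("chr1", donor, acceptor))
        call, _ = splice_fill(gap, ReadStore([ShortRead("amb", tx)]), genome, Params())
        assert call is None

    def test_microhomology_registers_collapse_to_leftmost(self):
        g, genome, donor, acceptor, reads = self._junction_world(homology=3)
        gap = GapCandidate("intron", "L", "R", GenomeInterval("chr1", donor, acceptor))
        call, _ = splice_fill(gap, ReadStore(reads), genome, Params())
        assert call is not None
        # all reads agree on one canonical register
        d, a = call.donor_end, call.acceptor_start
        assert a - d == acceptor - donor
        assert g[d - 1] != g[a - 1] or d == 0  # truly left-aligned


def test_left_align_junction_shifts_through_homology():
    # splicing GGGGAT|CCCCCAT|GGGG at (6,13) equals splicing at (4,11):
    # the AT repeat makes the register ambiguous; canonical is leftmost
    seq = "GGGGATCCCCCATGGGG"

    def at(i):
        return seq[i] if 0 <= i < len(seq) else None

    assert left_align_junction(at, 6, 13) == (4, 11)
    # no homology: the junction stays put
    seq2 = "AACGTCCCCCGAAA"

    def at2(i):
        return seq2[i] if 0 <= i < len(seq2) else None

    assert seq2[4] != seq2[11]
    assert left_align_junction(at2, 5, 12) == (5, 12)


class TestCloseGaps:
    def test_contig_count_non_increasing(self, planted):
        g, genome = planted
        contigs = [
            contig("a", "chr1", [(1000, 2000)], g),
            contig("b", "chr1", [(2040, 2600)], g),
            contig("c", "chr1", [(9000, 9500)], g),
        ]
        reads = tiling_reads(g, 1900, 2700, step=3)
        store = ReadStore(reads)
        params = Params()
        after_exon, _ = close_exon_gaps(contigs, store, genome, params)
        assert len(after_exon) <= len(contigs)
        after_intron, _ = close_intron_gaps(after_exon, store, genome, params)
        assert len(after_intron) <= len(after_exon)

    def test_contig_interiors_untouched(self, planted):
        g, genome = planted
        left = contig("L", "chr1", [(4000, 5000)], g)
        right = contig("R", "chr1", [(5040, 5600)], g)
        reads = tiling_reads(g, 4900, 5200, step=4)
        merged, _ = fill_exon_gap(
            GapCandidate("exon", "L", "R", GenomeInterval("chr1", 5000, 5040)),
            left, right, ReadStore(reads), genome, Params(),
        )
        assert merged.sequence[:1000] == left.sequence
        assert merged.sequence[-560:] == right.sequence
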