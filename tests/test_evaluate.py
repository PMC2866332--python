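import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonefinish.core import GenomeInterval
from clonefinish.evaluate import (
    CONSISTENT,
    END_MISSING,
    EXON_BOUNDARY,
    INCONSISTENT,
    INTERNAL_GAP,
    MISSING_LINK,
    CdsStructure,
    base_accuracy,
    classify_consistency,
    cost_multiclone_sanger,
    cost_per_clone,
    coverage_bins,
    downsample_reads,
    longest_orf,
    transcript_cds_range,
)
from clonefinish.reads import ShortRead
from tests.conftest import random_seq


def iv(s, e, chrom="chr1", strand="+"):
    return GenomeInterval(chrom, s, e, strand)


CDS = CdsStructure("k", [iv(100, 200), iv(300, 400), iv(500, 600)])


class TestClassifyConsistency:
    def test_identical_chain_is_consistent(self):
        res = classify_consistency([iv(100, 200), iv(300, 400), iv(500, 600)], CDS)
        assert res.verdict == CONSISTENT and res.failure == "none"

    def test_extra_utr_exons_still_consistent(self):
        chain = [iv(10, 40), iv(80, 200), iv(300, 400), iv(500, 650), iv(700, 750)]
        res = classify_consistency(chain, CDS)
        assert res.verdict == CONSISTENT

    def test_missing_link_between_chains(self):
        chains = [[iv(80, 200), iv(300, 400)], [iv(500, 650)]]
        res = classify_consistency(chains, CDS)
        assert (res.verdict, res.failure) == (INCONSISTENT, MISSING_LINK)

    def test_wrong_internal_junction_is_exon_boundary(self):
        chain = [iv(80, 200), iv(295, 400), iv(500, 650)]  # acceptor off by 5
        res = classify_consistency(chain, CDS)
        assert (res.verdict, res.failure) == (INCONSISTENT, EXON_BOUNDARY)

    def test_junction_inside_cds_exon_is_exon_boundary(self):
        chain = [iv(80, 150), iv(160, 400), iv(500, 650)]  # intron splits exon 1
        res = classify_consistency(chain, CDS)
        assert (res.verdict, res.failure) == (INCONSISTENT, EXON_BOUNDARY)

    def test_uncovered_interior_is_internal_gap(self):
        # two unlinked halves whose break falls inside the middle exon
        chains = [
            [iv(80, 200), iv(300, 340)],
            [iv(360, 400), iv(500, 650)],
        ]
        res = classify_consistency(chains, CDS)
        assert (res.verdict, res.failure) == (INCONSISTENT, INTERNAL_GAP)

    def test_truncated_first_exon_is_end_missing(self):
        chain = [iv(150, 200), iv(300, 400), iv(500, 650)]
        res = classify_consistency(chain, CDS)
        assert (res.verdict, res.failure) == (INCONSISTENT, END_MISSING)

    def test_absent_terminal_exon_is_end_missing(self):
        chain = [iv(80, 200), iv(300, 400)]
        res = classify_consistency(chain, CDS)
        assert (res.verdict, res.failure) == (INCONSISTENT, END_MISSING)

    def test_retained_intron_is_exon_boundary(self):
        chain = [iv(80, 430), iv(500, 650)]  # exons 1+2 fused
        res = classify_consistency(chain, CDS)
        assert (res.verdict, res.failure) == (INCONSISTENT, EXON_BOUNDARY)

    def test_wrong_chromosome_is_exon_boundary(self):
        chain = [iv(100, 200, chrom="chr2"), iv(300, 400, chrom="chr2")]
        res = classify_consistency(chain, CDS)
        assert (res.verdict, res.failure) == (INCONSISTENT, EXON_BOUNDARY)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 50), st.integers(1, 60))
    def test_invariant_to_exons_outside_cds_span(self, start, length):
        chain = [iv(100, 200), iv(300, 400), iv(500, 600)]
        base = classify_consistency(chain, CDS)
        decoy_left = iv(start, start + length) if start + length <= 60 else iv(0, 40)
        decoy_right = iv(700 + start, 700 + start + length)
        res = classify_consistency([decoy_left] + chain + [decoy_right], CDS)
        assert (res.verdict, res.failure) == (base.verdict, base.failure)


class TestBaseAccuracy:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        s = random_seq(rng, 1000)
        acc = base_accuracy(s, s)
        assert acc.match_ratio == 1.0
        assert acc.mismatches == acc.insertions == acc.deletions == 0

    def test_single_substitution(self):
        rng = np.random.default_rng(1)
        s = random_seq(rng, 100)
        t = "C" + s[1:] if s[0] != "C" else "G" + s[1:]
        acc = base_accuracy(t, s)
        assert (acc.matches, acc.mismatches) == (99, 1)
        assert acc.match_ratio == pytest.approx(0.99)

    def test_two_substitutions_one_deletion_counts(self):
        rng = np.random.default_rng(2)
        ref = random_seq(rng, 60)
        out = list(ref)
        out[10] = "A" if out[10] != "A" else "T"
        out[40] = "A" if out[40] != "A" else "T"
        del out[25]  # reference base missing from the output
        acc = base_accuracy("".join(out), ref)
        assert acc.ref_len == 60 and acc.aligned_len == 59
        assert (acc.matches, acc.mismatches, acc.deletions, acc.insertions) == (57, 2, 1, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            base_accuracy("", "ACGT")


class TestCoverageBins:
    def test_three_clone_example(self):
        df = coverage_bins([5, 15, 35], [CONSISTENT] * 3)
        assert df.bin_lo.tolist() == [0.0, 10.0, 30.0]
        assert df.n.tolist() == [1, 1, 1]
        assert df.pct_consistent.tolist() == [100.0, 100.0, 100.0]

    def test_empty(self):
        assert coverage_bins([], []).empty

    def test_recount_matches_brute_force(self):
        rng = np.random.default_rng(7)
        covs = rng.uniform(0, 120, 1000).tolist()
        verdicts = [CONSISTENT if rng.random() < 0.8 else INCONSISTENT for _ in covs]
        df = coverage_bins(covs, verdicts)
        for row in df.itertuples():
            members = [
                (c, v) for c, v in zip(covs, verdicts)
                if row.bin_lo <= c < row.bin_hi
            ]
            assert row.n == len(members)
            assert row.n_consistent == sum(v == CONSISTENT for _, v in members)


class TestDownsample:
    READS = [ShortRead(str(i), "ACGT" * 9) for i in range(1000)]

    def test_full_fraction_is_identity(self):
        assert downsample_reads(self.READS, 1.0, 1) == self.READS

    def test_half_fraction_size(self):
        assert len(downsample_reads(self.READS, 0.5, 1)) == 500

    def test_same_seed_same_sample(self):
        a = downsample_reads(self.READS, 0.3, 42)
        b = downsample_reads(self.READS, 0.3, 42)
        assert a == b

    def test_inclusion_rate_unbiased(self):
        hits = 0
        trials = 100
        for seed in range(trials):
            sample = downsample_reads(self.READS, 0.2, seed)
            hits += sum(1 for r in sample if r.id == "17")
        p = hits / trials
        sigma = (0.2 * 0.8 / trials) ** 0.5
        assert abs(p - 0.2) < 3 * sigma


class TestCostModel:
    def test_illumina_multiclone_printed_figure(self):
        assert cost_per_clone(3000, 7, 800, 0.79, 0.97, 2.00) == 2.70

    def test_flx_shotgun_printed_figure(self):
        assert cost_per_clone(8500, 1, 820, 1.0, 1.0, 1.00) == 11.37

    def test_sanger_multiclone_printed_figure(self):
        assert cost_multiclone_sanger(2.0, 6.7, 800, 1.00, 0.81, 5.00) == 24.85

    def test_zero_divisor_rejected(self):
        with pytest.raises(ValueError):
            cost_per_clone(3000, 0, 800, 0.79, 0.97, 2.00)
        with pytest.raises(ValueError):
            cost_per_clone(3000, 7, 800, 0.0, 0.97, 2.00)


class TestTranscriptCdsRange:
    def test_plus_strand_round_trip(self):
        exons = [iv(100, 200), iv(300, 400)]
        cds = [iv(150, 200), iv(300, 350)]
        assert transcript_cds_range(exons, cds, "+") == (50, 150)

    def test_minus_strand_mirrors(self):
        exons = [iv(100, 200), iv(300, 400)]
        cds = [iv(150, 200), iv(300, 350)]
        # spliced length 200; genomic concat range (50,150) mirrors
        assert transcript_cds_range(exons, cds, "-") == (50, 150)
        cds2 = [iv(150, 200)]
        assert transcript_cds_range(exons, cds2, "-") == (100, 150)


def test_longest_orf_finds_planted_frame():
    rng = np.random.default_rng(5)
    inner = "".join(
        c for c in ["GCA"] * 60  # 180 nt with no stop
    )
    seq = "TAA" + inner + "TAG"
    s, e, strand = longest_orf(seq)
    assert (e - s) >= len(inner)
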