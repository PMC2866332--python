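import numpy as np
import pytest

from clonefinish.aligner import Genome, align_contig_spliced, best_hit
from clonefinish.evaluate import map_transcript_range
from clonefinish.reads import revcomp
from clonefinish.simulate import (
    SimConfig,
    debruijn_contigs,
    generate_world,
    sanger_ends,
    shotgun_reads,
    slice_contigs,
)

SMALL = dict(n_clones=8, genome_len=250_000)


class TestDeterminism:
    def test_identical_config_gives_identical_outputs(self):
        cfg = SimConfig(seed=9, **SMALL)
        w1, w2 = generate_world(cfg), generate_world(cfg)
        assert w1.genome == w2.genome
        assert [c.sequence for c in w1.clones] == [c.sequence for c in w2.clones]
        r1, r2 = shotgun_reads(w1), shotgun_reads(w2)
        assert [(r.id, r.sequence) for r in r1] == [(r.id, r.sequence) for r in r2]
        s1, s2 = sanger_ends(w1), sanger_ends(w2)
        assert s1 == s2

    def test_different_seeds_differ(self):
        a = generate_world(SimConfig(seed=1, **SMALL))
        b = generate_world(SimConfig(seed=2, **SMALL))
        assert a.genome != b.genome


class TestWorldStructure:
    def test_short_exon_fraction_zero_means_none(self):
        w = generate_world(SimConfig(seed=3, short_exon_clone_fraction=0.0, **SMALL))
        for c in w.clones:
            assert min(len(e) for e in c.exon_chain) >= 36

    def test_flagged_clones_carry_a_short_exon(self):
        w = generate_world(SimConfig(seed=4, short_exon_clone_fraction=0.5, **SMALL))
        for c in w.clones:
            short = min(len(e) for e in c.exon_chain) < 36
            assert short == c.has_short_exon

    def test_short_exon_count_near_binomial_expectation(self):
        cfg = SimConfig(seed=6, n_clones=100, genome_len=2_000_000,
                        short_exon_clone_fraction=0.14)
        w = generate_world(cfg)
        k = sum(c.has_short_exon for c in w.clones)
        sigma = (100 * 0.14 * 0.86) ** 0.5
        assert abs(k - 14) <= 3 * sigma

    def test_genes_do_not_overlap(self):
        w = generate_world(SimConfig(seed=7, **SMALL))
        spans = sorted(
            (c.exon_chain[0].start, c.exon_chain[-1].end) for c in w.clones
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_world(SimConfig(seed=1, n_clones=50, genome_len=50_000))

    def test_clone_sequence_is_spliced_genome(self):
        w = generate_world(SimConfig(seed=8, **SMALL))
        g = w.genome["chr1"]
        for c in w.clones[:3]:
            spliced = "".join(g[e.start : e.end] for e in c.exon_chain)
            expected = spliced if c.strand == "+" else revcomp(spliced)
            assert c.sequence == expected

    def test_truth_chain_reproduced_by_alignment(self):
        """Aligning a clone sequence back to its genome recovers the
        recorded exon chain exactly (internal consistency oracle)."""
        w = generate_world(SimConfig(seed=10, **SMALL))
        genome = Genome(w.genome)
        for c in w.clones[:3]:
            hit = best_hit(align_contig_spliced(c.sequence, genome, query_id=c.clone_id))
            assert hit is not None
            exons = map_transcript_range(hit, 0, hit.query_len)
            truth = [(e.start, e.end) for e in c.exon_chain]
            got = [(e.start, e.end) for e in exons]
            # junction registers may slide through microhomology, never
            # by more than a few bases, and exon count must agree
            assert len(got) == len(truth)
            for (gs, ge), (ts, te) in zip(got, truth):
                assert abs(gs - ts) <= 3 and abs(ge - te) <= 3


class TestShotgunReads:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = SimConfig(seed=11, subst_error=0.0, mean_coverage=10.0, **SMALL)
        w = generate_world(cfg)
        seqs = {c.clone_id: c.sequence for c in w.clones}
        for r in shotgun_reads(w)[:300]:
            clone_id = r.id.rsplit("_", 1)[0]
            s = seqs[clone_id]
            assert r.sequence in s or revcomp(r.sequence) in s

    def test_pcr_failure_silences_clones(self):
        cfg = SimConfig(seed=12, pcr_success=0.0, **SMALL)
        w = generate_world(cfg)
        assert shotgun_reads(w) == []

    def test_substitution_rate_calibrated(self):
        cfg = SimConfig(seed=13, subst_error=0.005, mean_coverage=15.0,
                        amplification_sigma=0.0, **SMALL)
        w = generate_world(cfg)
        from numpy.lib.stride_tricks import sliding_window_view

        from clonefinish.seedindex import encode

        windows = {
            c.clone_id: sliding_window_view(encode(c.sequence), 36)
            for c in w.clones
        }
        mism = total = 0
        for r in shotgun_reads(w)[:1500]:
            win = windows[r.id.rsplit("_", 1)[0]]
            best = min(
                int((win != encode(o)).sum(axis=1).min())
                for o in (r.sequence, revcomp(r.sequence))
            )
            mism += best
            total += 36
        rate = mism / total
        assert 0.003 < rate < 0.007, rate

    def test_end_depletion_thins_terminal_starts(self):
        cfg = SimConfig(seed=14, subst_error=0.0, mean_coverage=60.0,
                        amplification_sigma=0.0, end_depletion_bp=150, **SMALL)
        w = generate_world(cfg)
        clone = w.clones[0]
        s = clone.sequence
        starts = []
        for r in shotgun_reads(w):
            if not r.id.startswith(clone.clone_id):
                continue
            p = s.find(r.sequence)
            if p < 0:
                p = s.find(revcomp(r.sequence))
            if p >= 0:
                starts.append(p)
        starts = np.array(starts)
        near_end = np.mean(starts < 50)
        interior = np.mean((starts >= 300) & (starts < 350))
        assert near_end < interior  # ramp suppresses terminal starts


class TestSangerEnds:
    def test_five_prime_read_is_clone_prefix(self):
        cfg = SimConfig(seed=15, sanger_error=0.0, **SMALL)
        w = generate_world(cfg)
        sanger = sanger_ends(w)
        by_clone = {}
        for r in sanger:
            by_clone.setdefault(r.clone_id, {})[r.end] = r
        for c in w.clones:
            r5 = by_clone[c.clone_id]["five_prime"]
            r3 = by_clone[c.clone_id]["three_prime"]
            assert c.sequence.startswith(r5.sequence)
            assert c.sequence.endswith(revcomp(r3.sequence))

    def test_reads_capped_at_clone_length(self):
        cfg = SimConfig(seed=16, clone_len=(1200, 1300), sanger_len=(1400, 1500),
                        **SMALL)
        w = generate_world(cfg)
        for r in sanger_ends(w):
            assert len(r) <= 1300

    def test_two_reads_per_clone(self):
        cfg = SimConfig(seed=17, **SMALL)
        w = generate_world(cfg)
        assert len(sanger_ends(w)) == 2 * len(w.clones)


class TestContigEmulators:
    def test_debruijn_reassembles_one_clean_transcript(self):
        cfg = SimConfig(seed=18, n_clones=1, genome_len=60_000, subst_error=0.0,
                        mean_coverage=60.0, amplification_sigma=0.0,
                        end_depletion_bp=1, pcr_success=1.0)
        w = generate_world(cfg)
        reads = shotgun_reads(w)
        contigs = debruijn_contigs(reads, min_count=2)
        tx = w.clones[0].sequence
        best = max(contigs, key=lambda c: len(c[1]))
        assert best[1] in tx or revcomp(best[1]) in tx
        assert len(best[1]) > 0.9 * len(tx)

    def test_slice_contigs_cover_transcripts(self):
        cfg = SimConfig(seed=19, **SMALL)
        w = generate_world(cfg)
        frags = slice_contigs(w, seed=19, dropout=0.0)
        tx = w.clones[0].sequence
        mine = [s for _, s in frags if s in tx]
        assert sum(len(s) - 50 for s in mine) >= len(tx) - 900
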