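"""Coverage binning, Poisson significance, metagenes, occupancy, clustering."""

import mpmath
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from rpg_regulon import chip

SIZES = {"chr1": 10_000}


def iv(chrom, start, end, strand="+"):
    return chip.GenomicInterval(chrom, start, end, strand)


class TestCoverage:
    def test_rpm_definition(self):
        reads = [iv("chr1", 100, 150), iv("chr1", 120, 170)]
        track = chip.coverage_rpm(reads, 50, SIZES, library_size=1_000_000)
        assert track.rpm()["chr1"][2] == pytest.approx(2.0)

    def test_rpm_conservation(self, rng):
        reads = [iv("chr1", int(p), int(p) + 30)
                 for p in rng.integers(0, 9000, size=500)]
        track = chip.coverage_rpm(reads, 100, SIZES)
        assert sum(v.sum() for v in track.rpm().values()) == pytest.approx(1e6)

    def test_minus_strand_counts_at_five_prime(self):
        track = chip.coverage_rpm([iv("chr1", 100, 150, "-")], 50, SIZES)
        assert track.counts["chr1"][2] == 1   # 5' end at 149
        assert track.counts["chr1"][3] == 0

    def test_empty_reads_rejected(self):
        with pytest.raises(ValueError):
            chip.coverage_rpm([], 50, SIZES)

    def test_read_beyond_chrom_rejected(self):
        with pytest.raises(ValueError):
            chip.coverage_rpm([iv("chr1", 9_990, 10_050, "-")], 50, SIZES)


class TestPoissonTrack:
    def test_zero_count_bins_are_zero(self):
        track = chip.coverage_rpm([iv("chr1", 0, 30)], 50, SIZES)
        sig = chip.poisson_track(track)
        assert np.all(sig.values["chr1"][1:] == 0.0)

    def test_closed_form_tail(self):
        # lambda = 1, k = 5: -log10 P(X >= 5)
        counts = {"chr1": np.ones(200, dtype=np.int64)}
        counts["chr1"][100] = 5
        track = chip.CoverageTrack(50, counts, int(counts["chr1"].sum()))
        sig = chip.poisson_track(track, local_window=500)
        lam = sig.lambda_global
        expected = -np.log10(float(mpmath.gammainc(5, 0, lam,
                                                   regularized=True)))
        assert sig.values["chr1"][100] == pytest.approx(expected, rel=1e-9)

    def test_reference_value_lambda_one(self):
        from scipy.stats import poisson
        assert -np.log10(poisson.sf(4, 1.0)) == pytest.approx(2.436, abs=1e-3)

    def test_matches_gamma_oracle_grid(self):
        from scipy.stats import poisson
        for lam in [0.5, 2.0, 7.7, 20.0]:
            for k in [1, 5, 17, 50]:
                ours = poisson.sf(k - 1, lam)
                oracle = float(mpmath.gammainc(k, 0, lam, regularized=True))
                assert ours == pytest.approx(oracle, rel=1e-10)

    def test_local_lambda_reduces_significance(self):
        counts = {"chr1": np.ones(200, dtype=np.int64)}
        counts["chr1"][95:105] = 4
        counts["chr1"][100] = 5
        track = chip.CoverageTrack(50, counts, int(counts["chr1"].sum()))
        hot = chip.poisson_track(track, local_window=500).values["chr1"][100]
        flat = {"chr1": np.ones(200, dtype=np.int64)}
        flat["chr1"][100] = 5
        track2 = chip.CoverageTrack(50, flat, int(flat["chr1"].sum()))
        cold = chip.poisson_track(track2, local_window=500).values["chr1"][100]
        assert hot < cold

    def test_window_smaller_than_bin_rejected(self):
        track = chip.coverage_rpm([iv("chr1", 0, 30)], 50, SIZES)
        with pytest.raises(ValueError):
            chip.poisson_track(track, local_window=10)


class TestMetagene:
    def _flat_sig(self, value=2.0):
        return chip.SignificanceTrack(
            50, {"chr1": np.full(200, value)}, 1.0)

    def test_constant_signal_flat_curve(self):
        prof = chip.metagene_profile(
            self._flat_sig(), [chip.TSSAnchor("g", "chr1", 5000, "+")], 3000)
        assert np.allclose(prof.mean_curve, 2.0)

    def test_planted_peak_at_minus_200(self):
        values = np.zeros(200)
        anchors = [chip.TSSAnchor(f"g{i}", "chr1", p, "+")
                   for i, p in enumerate([4000, 5000, 6000])]
        for a in anchors:
            values[(a.pos - 200) // 50] = 9.0
        sig = chip.SignificanceTrack(50, {"chr1": values}, 1.0)
        prof = chip.metagene_profile(sig, anchors, 3000)
        assert prof.offsets[np.argmax(prof.mean_curve)] == -200

    def test_minus_strand_orientation_flip(self):
        # a minus-strand gene transcribes leftward: genome position TSS-200
        # is 200 bp downstream (3') and must appear at +200 after the flip
        values = np.zeros(200)
        values[(5000 - 200) // 50] = 9.0
        sig = chip.SignificanceTrack(50, {"chr1": values}, 1.0)
        prof = chip.metagene_profile(
            sig, [chip.TSSAnchor("g", "chr1", 5000, "-")], 3000)
        assert prof.offsets[np.argmax(prof.mean_curve)] == 200

    def test_empty_anchor_list_rejected(self):
        with pytest.raises(ValueError):
            chip.metagene_profile(self._flat_sig(), [], 3000)


class TestOccupancy:
    def _sig_with_peak(self, pos, value):
        values = np.zeros(200)
        values[pos // 50] = value
        return chip.SignificanceTrack(50, {"chr1": values}, 1.0)

    def test_peak_inside_window_bound(self):
        sig = self._sig_with_peak(4900, 8.0)
        call = chip.call_occupancy(sig, chip.TSSAnchor("g", "chr1", 5000, "+"))
        assert call.bound and call.score == 8.0

    def test_peak_outside_window_unbound(self):
        sig = self._sig_with_peak(2500, 8.0)
        call = chip.call_occupancy(sig, chip.TSSAnchor("g", "chr1", 5000, "+"))
        assert not call.bound

    def test_score_exactly_threshold_is_bound(self):
        sig = self._sig_with_peak(5000, 5.0)
        call = chip.call_occupancy(sig, chip.TSSAnchor("g", "chr1", 5000, "+"),
                                   threshold=5.0)
        assert call.bound


class TestClusterBinding:
    def test_recovers_separated_groups(self, rng):
        a = rng.normal(10, 0.5, size=(20, 8))
        b = rng.normal(0.5, 0.2, size=(30, 8))
        matrix = np.abs(np.vstack([a, b]))
        truth = [0] * 20 + [1] * 30
        labels, profiles = chip.cluster_binding(matrix, 2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0
        # cluster 1 is the high-signal group
        assert set(labels[:20]) == {1}
        assert profiles.shape == (2, 8)

    def test_deterministic_and_permutation_invariant(self, rng):
        # three well-separated groups: the optimum is unique, so the
        # partition must not depend on row order
        groups = [rng.normal(c, 0.3, size=(12, 6)) for c in (1.0, 5.0, 20.0)]
        matrix = np.abs(np.vstack(groups))
        l1, _ = chip.cluster_binding(matrix, 3, seed=7)
        l2, _ = chip.cluster_binding(matrix, 3, seed=7)
        assert np.array_equal(l1, l2)
        perm = rng.permutation(len(matrix))
        l3, _ = chip.cluster_binding(matrix[perm], 3, seed=7)
        assert adjusted_rand_score(l1[perm], l3) == 1.0

    def test_identical_rows_deterministic(self):
        matrix = np.ones((10, 4))
        labels, _ = chip.cluster_binding(matrix, 2, seed=0)
        assert set(labels) == {1}

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            chip.cluster_binding(np.ones((5, 3)), 0)
        with pytest.raises(ValueError):
            chip.cluster_binding(np.ones((5, 3)), 6)


class TestOverlapsAndPairs:
    def test_venn_partition(self):
        calls = {
            "t98g": {"A": True, "B": True, "C": False},
            "u2os": {"A": False, "B": True, "C": True},
            "hela": {"A": False, "B": True, "C": False},
        }
        regions = chip.overlap_sets(calls)
        assert regions[("hela", "t98g", "u2os")] == ["B"]
        assert regions[("t98g",)] == ["A"]
        assert regions[("u2os",)] == ["C"]

    def test_disjoint_and_identical_sets(self):
        calls = {"a": {"x": True, "y": False},
                 "b": {"x": False, "y": True}}
        regions = chip.overlap_sets(calls)
        assert ("a", "b") not in regions
        calls = {"a": {"x": True}, "b": {"x": True}}
        assert chip.overlap_sets(calls)[("a", "b")] == ["x"]

    def test_inconsistent_universe_rejected(self):
        with pytest.raises(ValueError):
            chip.overlap_sets({"a": {"x": True}, "b": {"y": True}})

    def test_divergent_pair_within_gap(self):
        g1 = chip.TSSAnchor("g1", "chr1", 1000, "-")
        g2 = chip.TSSAnchor("g2", "chr1", 1300, "+")
        assert [(p[0].gene_id, p[1].gene_id)
                for p in chip.bidirectional_pairs([g1, g2], 500)] == [("g1", "g2")]

    def test_same_strand_and_too_far_excluded(self):
        a = chip.TSSAnchor("a", "chr1", 1000, "+")
        b = chip.TSSAnchor("b", "chr1", 1100, "+")
        assert chip.bidirectional_pairs([a, b], 500) == []
        g1 = chip.TSSAnchor("g1", "chr1", 1000, "-")
        g2 = chip.TSSAnchor("g2", "chr1", 1501, "+")
        assert chip.bidirectional_pairs([g1, g2], 500) == []
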