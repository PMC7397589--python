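"""KR balancing, O/E, compartments, APA and LRI scores."""

import numpy as np
import pytest

import loopspread as ls
from loopspread import hic
from loopspread.synthetic import GenomeSpec, SimulationParams


def kr_oracle(a, tol=1e-14, max_iter=200_000):
    """Independent averaged fixed-point iteration for x_i (A x)_i = 1."""
    x = np.ones(a.shape[0])
    for _ in range(max_iter):
        x_new = 1.0 / (a @ x)
        x = 0.5 * (x + x_new)
        if np.abs(x * (a @ x) - 1).max() < tol:
            return x
    raise RuntimeError("oracle did not converge")


class TestKRBalance:
    def test_row_sums_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            a = rng.random((200, 200)) + 0.05
            a = (a + a.T) / 2
            w, bal, mask = hic.kr_balance(a, mask_percentile=0)
            rows = np.nansum(bal, axis=1)
            assert np.abs(rows[~mask] - 1).max() < 1e-10

    @pytest.mark.parametrize("a", [
        [[2.0, 1.0], [1.0, 2.0]],
        [[3.0, 1.0, 0.5], [1.0, 2.0, 1.5], [0.5, 1.5, 4.0]],
    ])
    def test_small_cases_match_fixed_point_oracle(self, a):
        a = np.array(a)
        w, _, _ = hic.kr_balance(a, tol=1e-14, mask_percentile=0)
        x = kr_oracle(a)
        assert np.abs(w - x).max() < 1e-12

    def test_equal_sum_matrix_equal_weights(self):
        a = np.full((5, 5), 2.0)
        w, _, _ = hic.kr_balance(a, mask_percentile=0)
        assert np.allclose(w, w[0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.random((50, 50)) + 0.1
        a = (a + a.T) / 2
        _, b1, _ = hic.kr_balance(a, mask_percentile=0)
        _, b2, _ = hic.kr_balance(10 * a, mask_percentile=0)
        assert np.nanmax(np.abs(b1 - b2)) < 1e-9

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            hic.kr_balance(np.array([[1.0, 2.0], [3.0, 1.0]]))

    def test_zero_rows_masked(self):
        a = np.diag([0.0, 1.0, 1.0])
        a[1, 2] = a[2, 1] = 1.0
        w, bal, mask = hic.kr_balance(a, mask_percentile=0)
        assert mask[0] and not mask[1]
        assert np.isnan(w[0])


class TestExpectedOE:
    def test_pure_distance_function_gives_unit_oe(self):
        n = 80
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        mat = 1.0 / (d + 1.0)
        oe, exp = hic.oe_normalize(mat)
        assert np.allclose(oe, 1.0)

    def test_per_diagonal_mean_is_one(self):
        rng = np.random.default_rng(2)
        n = 100
        mat = rng.random((n, n)) + 0.2
        mat = (mat + mat.T) / 2
        oe, _ = hic.oe_normalize(mat)
        for d in range(0, n, 13):
            assert np.nanmean(np.diagonal(oe, d)) == pytest.approx(1.0, abs=1e-12)

    def test_planted_pixel_strength(self):
        n = 120
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        mat = 100.0 / (d + 1.0)
        mat[30, 70] *= 4
        mat[70, 30] = mat[30, 70]
        oe, _ = hic.oe_normalize(mat)
        assert oe[30, 70] == pytest.approx(4.0, rel=0.05)


class TestCompartments:
    def test_exact_two_block_checkerboard(self):
        """Analytic block O/E: eigenvector signs reproduce the blocks exactly."""
        n = 60
        labels = np.where(np.arange(n) < 30, 1, -1)
        oe = np.where(np.equal.outer(labels, labels), 1.5, 0.5).astype(float)
        rng = np.random.default_rng(0)
        oe = oe * (1 + 1e-6 * rng.random((n, n)))   # break exact degeneracy
        oe = (oe + oe.T) / 2
        vec, called = hic.compartment_eigenvector(oe, labels.astype(float))
        assert np.array_equal(called, labels)

    def test_orientation_flip_flips_signs(self):
        n = 60
        labels = np.where(np.arange(n) % 20 < 10, 1.0, -1.0)
        oe = np.where(np.equal.outer(labels, labels), 1.4, 0.6) + 0.01 * np.eye(n)
        vec1, l1 = hic.compartment_eigenvector(oe, labels)
        vec2, l2 = hic.compartment_eigenvector(oe, -labels)
        assert np.array_equal(l1, -l2)

    def test_synthetic_recovery(self, default_manifest, default_oe):
        oe, masks = default_oe
        agree = []
        for chrom in default_manifest.spec.chrom_names:
            truth = default_manifest.compartment_labels[chrom]
            vec, called = hic.compartment_eigenvector(
                oe["WT"][chrom], truth.astype(float), masks["WT"][chrom])
            free = called != 0
            agree.append((called[free] == truth[free]).mean())
        assert min(agree) >= 0.95

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            hic.compartment_eigenvector(np.ones((10, 10)), np.ones(10))


class TestAggregate:
    def test_single_pair_identity(self):
        rng = np.random.default_rng(3)
        oe = rng.random((100, 100)) + 0.5
        agg = hic.aggregate_pairs(oe, [20], [70], window_bins=5, min_sep_bins=3)
        assert agg.n_pairs == 1
        assert np.array_equal(agg.matrix, oe[15:26, 65:76])

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        oe = rng.random((200, 200)) + 0.5
        a = np.array([20, 40, 60, 80, 100])
        b = np.array([120, 140, 160])
        w = 4
        agg = hic.aggregate_pairs(oe, a, b, window_bins=w, min_sep_bins=3)
        subs = []
        for x in a:
            for y in b:
                lo, hi = min(x, y), max(x, y)
                if hi - lo > 3 and lo - w >= 0 and hi + w < 200:
                    subs.append(oe[lo - w: lo + w + 1, hi - w: hi + w + 1])
        assert len(subs) == agg.n_pairs
        assert np.allclose(agg.matrix, np.mean(subs, axis=0))

    def test_linearity_over_disjoint_pair_sets(self):
        rng = np.random.default_rng(5)
        oe = rng.random((200, 200)) + 0.5
        agg1 = hic.aggregate_pairs(oe, [20], [100], 4, 3)
        agg2 = hic.aggregate_pairs(oe, [50, 60], [150], 4, 3)
        both = hic.aggregate_pairs(oe, [20, 50, 60], [100, 150], 4, 3)
        manual = []
        for x in (20, 50, 60):
            for y in (100, 150):
                manual.append(oe[x - 4: x + 5, y - 4: y + 5])
        assert np.allclose(both.matrix, np.mean(manual, axis=0))

    def test_no_admissible_pairs_raises(self):
        oe = np.ones((50, 50))
        with pytest.raises(ValueError, match="admissible"):
            hic.aggregate_pairs(oe, [10], [12], window_bins=5, min_sep_bins=10)


class TestLRIScores:
    def test_all_ones_submatrix_zero_scores(self):
        oe = np.ones((200, 200))
        l1, l2, l3 = hic.score_lri_pair(oe, 60, 120)
        assert l1 == 0 and l2 == 0 and l3 == 0

    def test_center_block_arithmetic(self):
        """Center 3x3 at 4, rest 1 -> lri3 = 2, lri1 = lri2 = 0."""
        oe = np.ones((200, 200))
        a, b = 60, 120
        oe[a - 1: a + 2, b - 1: b + 2] = 4.0
        oe[b - 1: b + 2, a - 1: a + 2] = 4.0
        l1, l2, l3 = hic.score_lri_pair(oe, a, b)
        assert l3 == pytest.approx(2.0)
        assert l1 == pytest.approx(0.0)
        assert l2 == pytest.approx(0.0)

    def test_planted_loops_score_two_controls_zero(self, default_manifest, default_oe):
        oe, _ = default_oe
        bs = default_manifest.spec.hic_bin_size
        loops = default_manifest.planted_loops
        vals, ctrl_vals = [], []
        rng = np.random.default_rng(0)
        for chrom in default_manifest.spec.chrom_names:
            n = oe["WT"][chrom].shape[0]
            sub = loops[(loops.chrom == chrom) & loops.beaf_anchored]
            for r in sub.itertuples(index=False):
                a, b = sorted((int(r.anchor_a) // bs, int(r.anchor_b) // bs))
                vals.append(hic.score_lri_pair(oe["WT"][chrom], a, b)[2])
                off = int(rng.integers(15, 30))
                if b + off + 10 < n:
                    ctrl_vals.append(hic.score_lri_pair(oe["WT"][chrom], a, b + off)[2])
        assert np.nanmean(vals) == pytest.approx(2.0, abs=0.2)
        assert abs(np.nanmean(ctrl_vals)) < 0.2

    def test_delta_identical_conditions_zero(self, default_oe):
        oe, _ = default_oe
        pairs = [(50, 100), (200, 300)]
        r1 = hic.score_lri_records(oe["WT"]["chr2L"], pairs, 2000, "chr2L", "WT")
        r2 = hic.score_lri_records(oe["WT"]["chr2L"], pairs, 2000, "chr2L", "WT")
        d = hic.delta_lri(r1, r2)
        assert np.allclose(d[["delta_lri1", "delta_lri2", "delta_lri3"]], 0.0)

    def test_delta_pair_mismatch_raises(self, default_oe):
        oe, _ = default_oe
        r1 = hic.score_lri_records(oe["WT"]["chr2L"], [(50, 100)], 2000, "chr2L")
        r2 = hic.score_lri_records(oe["WT"]["chr2L"], [(50, 101)], 2000, "chr2L")
        with pytest.raises(ValueError, match="universes"):
            hic.delta_lri(r1, r2)

    def test_depth_invariance_of_delta(self, default_manifest, default_hic):
        """Down-sampling one condition 2x leaves Δ scores unchanged (via O/E)."""
        rng = np.random.default_rng(9)
        chrom = "chr2L"
        full = default_hic["KD"][chrom]
        thin = rng.binomial(full.astype(np.int64), 0.5).astype(float)
        thin = np.triu(thin) + np.triu(thin, 1).T
        oe_full, _ = hic.balance_and_oe(full)
        oe_thin, _ = hic.balance_and_oe(thin)
        oe_wt, _ = hic.balance_and_oe(default_hic["WT"][chrom])
        bs = default_manifest.spec.hic_bin_size
        loops = default_manifest.planted_loops
        sub = loops[(loops.chrom == chrom) & loops.beaf_anchored]
        pairs = sorted({tuple(sorted((int(r.anchor_a) // bs, int(r.anchor_b) // bs)))
                        for r in sub.itertuples(index=False)})
        rw = hic.score_lri_records(oe_wt, pairs, bs, chrom)
        d_full = hic.delta_lri(rw, hic.score_lri_records(oe_full, pairs, bs, chrom))
        d_thin = hic.delta_lri(rw, hic.score_lri_records(oe_thin, pairs, bs, chrom))
        assert d_full["delta_lri3"].mean() == pytest.approx(
            d_thin["delta_lri3"].mean(), abs=0.1)


class TestTadStrength:
    def test_decay_only_scores_near_zero(self):
        params = SimulationParams(compartment_amplitude=0, tad_amplitude=0,
                                  loop_strength=1, hic_depth=2000, seed=12)
        m = ls.build_genome(GenomeSpec(), params)
        hc = ls.simulate_hic(m, conditions=("WT",))
        oe, _ = hic.balance_and_oe(hc["WT"]["chr2L"])
        tb = hic.tads_to_bins(m.tad_intervals, "chr2L", 2000)
        scores = hic.tad_strength(oe, tb)
        assert abs(np.nanmean(scores)) < 0.05

    def test_planted_amplitude_one_scores_one(self):
        """tad_amplitude 1 (2x within-TAD contact) -> score ~ 1 without confounders."""
        params = SimulationParams(compartment_amplitude=0, tad_amplitude=1.0,
                                  loop_strength=1, hic_depth=2000, seed=13)
        m = ls.build_genome(GenomeSpec(), params)
        hc = ls.simulate_hic(m, conditions=("WT",))
        oe, _ = hic.balance_and_oe(hc["WT"]["chr2L"])
        tb = hic.tads_to_bins(m.tad_intervals, "chr2L", 2000)
        scores = hic.tad_strength(oe, tb)
        # interior TADs only: chromosome-edge TADs lack full straddle context
        assert np.nanmean(scores[1:-1]) == pytest.approx(1.0, abs=0.15)

    def test_matches_per_tad_recomputation(self, default_oe):
        oe, _ = default_oe
        tb = [(100, 130), (130, 180)]
        scores = hic.tad_strength(oe["WT"]["chr2L"], tb)
        single = [hic.tad_strength(oe["WT"]["chr2L"], [t])[0] for t in tb]
        assert np.allclose(scores, single, equal_nan=True)
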