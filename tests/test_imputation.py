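"""The six imputation methods and the NRMSE assessment harness."""

import numpy as np
import pytest

from peakproc.imputation import (
    assess_mvi,
    impute,
    impute_bpca,
    impute_knn,
    impute_mean,
    impute_median,
    impute_rf,
    impute_small_value,
    pairwise_feature_distances,
)

from conftest import make_table


class TestSimpleImputers:
    def test_small_value_uses_half_global_minimum_everywhere(self):
        x = np.array([[8.0, np.nan], [20.0, np.nan], [16.0, 40.0]])
        out = impute_small_value(make_table(x))
        assert out.intensities[0, 1] == out.intensities[1, 1] == 4.0

    def test_mean_and_median_differ_on_skewed_feature(self):
        x = np.array([[1.0], [2.0], [9.0], [np.nan]])
        t = make_table(x)
        assert impute_mean(t).intensities[3, 0] == 4.0
        assert impute_median(t).intensities[3, 0] == 2.0

    @pytest.mark.parametrize("method", ["SV", "MN", "MD", "KNN", "BPCA", "RF"])
    def test_no_missing_is_identity(self, method, rng):
        x = np.exp(rng.normal(5, 0.5, (8, 12)))
        t = make_table(x)
        out = impute(t, method, seed=1)
        np.testing.assert_array_equal(out.intensities, x)

    @pytest.mark.parametrize("method", ["SV", "MN", "MD", "KNN", "BPCA", "RF"])
    def test_complete_output_and_observed_cells_bit_identical(self, method, rng):
        x = np.exp(rng.normal(5, 0.5, (10, 15)))
        mask = rng.random((10, 15)) < 0.12
        mask[:, 0] = False
        x_missing = x.copy()
        x_missing[mask] = np.nan
        t = make_table(x_missing)
        out = impute(t, method, seed=1)
        assert not out.missing.any()
        np.testing.assert_array_equal(out.intensities[~mask], x[~mask])

    def test_feature_with_no_observed_value_rejected(self):
        x = np.array([[np.nan, 1.0], [np.nan, 2.0]])
        with pytest.raises(ValueError):
            impute_mean(make_table(x))

    def test_unknown_method_rejected(self, small_table):
        with pytest.raises(ValueError, match="unknown"):
            impute(small_table, "MICE")


class TestKnn:
    def test_duplicate_feature_is_zero_distance_neighbour(self, rng):
        x = np.exp(rng.normal(5, 0.5, (8, 6)))
        x = np.column_stack([x, x[:, 0]])  # feature 7 duplicates feature 1
        x_missing = x.copy()
        x_missing[2, 6] = np.nan
        out = impute_knn(make_table(x_missing), k=1)
        assert out.intensities[2, 6] == pytest.approx(x[2, 0], rel=1e-12)

    def test_fallback_to_feature_mean_when_neighbours_unobserved(self):
        # features 1 and 2 are twins; both missing at sample 0 -> fall back
        x = np.array(
            [
                [np.nan, np.nan, 7.0],
                [2.0, 2.0, 8.0],
                [4.0, 4.0, 9.0],
            ]
        )
        out = impute_knn(make_table(x), k=1)
        assert out.intensities[0, 0] == pytest.approx(3.0)  # mean of [2, 4]

    def test_matches_bruteforce_neighbour_oracle(self, rng):
        n, p, k = 20, 15, 3
        x = np.exp(rng.normal(5, 0.5, (n, p)))
        mask = rng.random((n, p)) < 0.15
        mask[:, -1] = False
        xm = np.where(mask, np.nan, x)
        out = impute_knn(make_table(xm), k=k)

        # brute force: all-pairs scaled Euclidean over joint samples
        def dist(a, b):
            joint = ~np.isnan(xm[:, a]) & ~np.isnan(xm[:, b])
            if not joint.any():
                return np.inf
            d2 = np.sum((xm[joint, a] - xm[joint, b]) ** 2) * n / joint.sum()
            return np.sqrt(d2)

        for f in range(p):
            order = sorted((dist(f, g), g) for g in range(p) if g != f)
            neigh = [g for _, g in order[:k]]
            for s in range(n):
                if not mask[s, f]:
                    continue
                vals = [xm[s, g] for g in neigh if not np.isnan(xm[s, g])]
                expected = np.mean(vals) if vals else np.nanmean(xm[:, f])
                assert out.intensities[s, f] == pytest.approx(expected, rel=1e-12)

    def test_k_bounds_enforced(self, small_table):
        with pytest.raises(ValueError):
            impute_knn(small_table, k=3)
        with pytest.raises(ValueError):
            impute_knn(small_table, k=0)

    def test_pairwise_distance_scaling(self):
        # 2 features observed jointly on half the samples: distance scaled by sqrt(2)
        x = np.array([[0.0, 3.0], [4.0, np.nan], [0.0, 0.0], [np.nan, 1.0]])
        d = pairwise_feature_distances(x)
        expected = np.sqrt((9.0 + 0.0) * 4 / 2)
        assert d[0, 1] == pytest.approx(expected)


class TestBpca:
    def test_rank_one_completion_within_one_percent(self, rng):
        u = rng.uniform(1, 2, 12)
        v = rng.uniform(10, 20, 8)
        x = np.outer(u, v)
        xm = x.copy()
        xm[3, 4] = np.nan
        out = impute_bpca(make_table(xm), n_axes=3)
        assert out.intensities[3, 4] == pytest.approx(x[3, 4], rel=0.01)

    def test_zero_axes_degenerates_to_feature_means(self):
        x = np.array([[1.0, 5.0], [3.0, np.nan], [2.0, 7.0]])
        out = impute_bpca(make_table(x), n_axes=0)
        assert out.intensities[1, 1] == pytest.approx(6.0)

    def test_beats_mean_imputation_on_noisy_low_rank_data(self, rng):
        a = rng.normal(0, 1, (30, 2))
        b = rng.normal(0, 1, (2, 40))
        x = 100.0 + 10.0 * (a @ b) + rng.normal(0, 1, (30, 40))
        mask = rng.random((30, 40)) < 0.10
        mask[:, 0] = False
        xm = np.where(mask, np.nan, x)
        t = make_table(xm)
        err_bpca = np.sqrt(np.mean((impute_bpca(t).intensities[mask] - x[mask]) ** 2))
        err_mean = np.sqrt(np.mean((impute_mean(t).intensities[mask] - x[mask]) ** 2))
        assert err_bpca < err_mean

    def test_axis_bound_enforced(self, small_table):
        with pytest.raises(ValueError):
            impute_bpca(small_table, n_axes=10)


class TestRandomForest:
    def test_same_seed_identical_output(self, rng):
        x = np.exp(rng.normal(5, 0.5, (12, 10)))
        mask = rng.random((12, 10)) < 0.1
        mask[:, 0] = False
        t = make_table(np.where(mask, np.nan, x))
        a = impute_rf(t, n_trees=20, seed=42)
        b = impute_rf(t, n_trees=20, seed=42)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_recovers_structure_on_noisy_rank_one_data(self, rng):
        u = rng.uniform(1, 2, 40)
        v = rng.uniform(10, 20, 25)
        x = np.outer(u, v) * np.exp(rng.normal(0, 0.05, (40, 25)))
        mask = rng.random((40, 25)) < 0.10
        mask[:, 0] = False
        t = make_table(np.where(mask, np.nan, x))
        out = impute_rf(t, n_trees=30, seed=7)
        r = np.corrcoef(out.intensities[mask], x[mask])[0, 1]
        assert r > 0.9


class TestAssessMvi:
    def test_constant_matrix_mean_type_imputers_have_zero_nrmse(self):
        t = make_table(np.full((8, 8), 7.0))
        res = assess_mvi(t, ["MN", "MD"], rate=0.1, seed=1, sum_normalise=False)
        for r in res:
            assert r.nrmse == pytest.approx(0.0, abs=1e-12)
            assert r.n_masked == 6  # floor(0.1 * 64)

    def test_toy_nrmse_hand_value(self):
        # masked truths {4, 6} imputed as {2, 8}: rmse 2; matrix mean 5 -> 0.4
        truth = np.array([4.0, 6.0])
        imputed = np.array([2.0, 8.0])
        nrmse = np.sqrt(np.mean((truth - imputed) ** 2)) / 5.0
        assert nrmse == pytest.approx(0.4)

    def test_perfect_imputer_zero_nrmse_via_duplicate_features(self, rng):
        # exact duplicate features whose twins stay observed: 1-NN imputation
        # restores the truth, so NRMSE over the masked cells is zero
        base = np.exp(rng.normal(5, 0.5, (10, 6)))
        x = np.repeat(base, 2, axis=1)  # every feature twinned
        truth = x.copy()
        for s, f in [(1, 0), (4, 3), (7, 8), (2, 11)]:
            x[s, f] = np.nan  # twins of these cells remain observed
        t = make_table(x)
        out = impute_knn(t, k=1)
        cells = np.isnan(x)
        nrmse = np.sqrt(np.mean((out.intensities[cells] - truth[cells]) ** 2)) / truth.mean()
        assert nrmse == pytest.approx(0.0, abs=1e-12)

    def test_requires_complete_table(self, small_table):
        with pytest.raises(ValueError, match="complete"):
            assess_mvi(small_table, ["MN"], seed=0)

    @pytest.mark.parametrize("method", ["SV", "MN", "MD"])
    def test_feature_local_imputers_commute_with_feature_order(self, method, rng):
        x = np.exp(rng.normal(5, 0.5, (10, 12)))
        mask = rng.random((10, 12)) < 0.15
        mask[:, 0] = False
        t = make_table(np.where(mask, np.nan, x))
        perm = rng.permutation(12)
        direct = impute(t.subset_features(perm), method)
        reordered = impute(t, method).subset_features(perm)
        np.testing.assert_array_equal(direct.intensities, reordered.intensities)
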