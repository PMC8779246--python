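import numpy as np
import pytest
from scipy.stats import multivariate_normal

from bprsnet.polychoric import (
    bvn_cdf,
    estimate_pair_rho,
    estimate_thresholds,
    nearest_pd_correlation,
    pair_neg_loglik,
    polychoric_matrix,
)


def _discretize(z: np.ndarray, cuts) -> np.ndarray:
    return 1 + np.searchsorted(np.asarray(cuts), z)


class TestBvnCdf:
    @pytest.mark.parametrize("rho", [-0.95, -0.4, 0.0, 0.3, 0.8, 0.99])
    def test_matches_scipy_mvn(self, rho):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(scale=1.5, size=(40, 2)),
                         [[0.0, 0.0], [0.0, -1.0], [1.0, 0.0]]])
        ref = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf(pts)
        ours = bvn_cdf(pts[:, 0], pts[:, 1], rho)
        np.testing.assert_allclose(ours, ref, atol=1e-6)

    def test_infinite_limits_reduce_to_marginals(self):
        from scipy.special import ndtr

        assert bvn_cdf(np.inf, 0.7, 0.5) == pytest.approx(ndtr(0.7))
        assert bvn_cdf(-np.inf, 0.7, 0.5) == 0.0
        assert bvn_cdf(np.inf, np.inf, -0.3) == 1.0


class TestThresholds:
    def test_median_split_gives_zero_cut(self):
        x = np.array([1] * 50 + [2] * 50)
        y = np.array([1, 2] * 50)
        ts = estimate_thresholds(np.column_stack([x, y]), K=2)
        assert ts.cuts[0][0] == pytest.approx(0.0, abs=1e-12)

    def test_skewed_marginal_cut_matches_inverse_normal(self):
        # 840 of 1438 in category 1 -> first cut at Phi^-1(0.58414) = 0.212508
        counts = (840, 258, 199, 87, 37, 13, 4)
        x = np.repeat(np.arange(1, 8), counts)
        other = np.resize([1, 2], x.size)
        ts = estimate_thresholds(np.column_stack([x, other]), K=7)
        assert ts.cuts[0][0] == pytest.approx(0.21250803575992122, abs=1e-10)

    def test_uniform_categories_closed_form(self):
        x = np.repeat(np.arange(1, 8), 100)
        other = np.resize([1, 2], x.size)
        ts = estimate_thresholds(np.column_stack([x, other]), K=7)
        expected = [-1.06757052, -0.56594882, -0.18001237,
                    0.18001237, 0.56594882, 1.06757052]
        np.testing.assert_allclose(ts.cuts[0], expected, atol=1e-7)

    def test_constant_item_is_an_error(self):
        data = np.column_stack([np.full(20, 3), np.resize([1, 2], 20)])
        with pytest.raises(ValueError, match="V1"):
            estimate_thresholds(data, K=7)

    def test_internal_empty_category_merged_upward(self):
        # category 2 never observed: scores 1 and 3 only
        x = np.array([1] * 30 + [3] * 70)
        other = np.resize([1, 2], x.size)
        ts = estimate_thresholds(np.column_stack([x, other]), K=3)
        assert ts.n_effective(0) == 2
        assert ("V1", 2) in ts.merge_log
        assert np.all(np.diff(ts.cuts[0]) > 0) if len(ts.cuts[0]) > 1 else True


class TestPairRho:
    def test_identical_vectors_near_one(self):
        rng = np.random.default_rng(3)
        x = rng.integers(1, 8, 500)
        ts = estimate_thresholds(np.column_stack([x, x]), K=7)
        rho, _ = estimate_pair_rho(x, x, ts.cuts[0], ts.cuts[1])
        assert rho >= 0.99

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(4)
        x = rng.integers(1, 8, 5000)
        y = rng.integers(1, 8, 5000)
        ts = estimate_thresholds(np.column_stack([x, y]), K=7)
        rho, _ = estimate_pair_rho(x, y, ts.cuts[0], ts.cuts[1])
        assert abs(rho) < 0.05

    def test_ml_matches_grid_search_oracle(self):
        """The bounded ML optimum must agree with an exhaustive grid search
        of the same likelihood to within one grid step (0.01)."""
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=5000)
        X = (z > 0).astype(np.int64) + 1
        ts = estimate_thresholds(X, K=2)
        rho, _ = estimate_pair_rho(X[:, 0], X[:, 1], ts.cuts[0], ts.cuts[1])
        assert 0.45 <= rho <= 0.55

        table = np.zeros((2, 2))
        for a, b in X - 1:
            table[a, b] += 1
        grid = np.arange(-0.99, 0.995, 0.01)
        nlls = [pair_neg_loglik(table, ts.cuts[0], ts.cuts[1], g) for g in grid]
        assert abs(rho - grid[int(np.argmin(nlls))]) <= 0.011


class TestMatrix:
    def test_two_item_matrix_consistent_with_pair(self):
        rng = np.random.default_rng(8)
        z = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=800)
        X = np.column_stack(
            [_discretize(z[:, 0], [-0.5, 0.5]), _discretize(z[:, 1], [0.0])]
        ).astype(np.int64)
        res = polychoric_matrix(X)
        ts = estimate_thresholds(X)
        rho, _ = estimate_pair_rho(X[:, 0], X[:, 1], ts.cuts[0], ts.cuts[1])
        assert res.correlation[0, 1] == pytest.approx(rho, abs=1e-6)
        np.testing.assert_allclose(np.diag(res.correlation), 1.0)

    def test_row_permutation_invariance(self, tiny_matrix):
        rng = np.random.default_rng(9)
        perm = rng.permutation(tiny_matrix.n)
        a = polychoric_matrix(tiny_matrix)
        b = polychoric_matrix(tiny_matrix.subset_rows(perm))
        np.testing.assert_allclose(a.correlation, b.correlation, atol=1e-9)

    def test_score_shift_invariance(self, tiny_matrix):
        shifted = tiny_matrix.values + 1  # scores 2..8 on a 1..8 scale
        a = polychoric_matrix(tiny_matrix.values)
        b = polychoric_matrix(shifted)
        np.testing.assert_allclose(a.correlation, b.correlation, atol=1e-9)

    def test_matrix_recovers_latent_truth(self, default_dataset):
        res = polychoric_matrix(default_dataset.data)
        dev = np.abs(res.correlation - default_dataset.spec.latent_corr).max()
        assert dev < 0.08
        w = np.linalg.eigvalsh(res.correlation)
        assert w.min() >= 1e-8 or not res.pd_adjusted

    def test_parameter_recovery_over_rho_grid(self):
        """Mean absolute error of rho-hat < 0.05 across true correlations
        and skewed thresholds at the cohort's sample size."""
        skew_cuts = [0.2125, 0.7, 1.1, 1.55, 1.95, 2.35]  # heavy floor effect
        errors = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            for true_rho in (-0.8, -0.4, 0.0, 0.4, 0.8):
                z = rng.multivariate_normal(
                    [0, 0], [[1, true_rho], [true_rho, 1]], size=1438,
                    method="cholesky",
                )
                X = np.column_stack(
                    [_discretize(z[:, 0], skew_cuts), _discretize(z[:, 1], skew_cuts)]
                ).astype(np.int64)
                ts = estimate_thresholds(X, K=7)
                rho, _ = estimate_pair_rho(
                    ts.category_map[0][X[:, 0] - 1],
                    ts.category_map[1][X[:, 1] - 1],
                    ts.cuts[0],
                    ts.cuts[1],
                    xi_is_effective=True,
                )
                errors.append(abs(rho - true_rho))
        assert np.mean(errors) < 0.05


class TestNearestPd:
    def test_projection_restores_definiteness(self):
        R = np.array([
            [1.0, 0.95, -0.4],
            [0.95, 1.0, 0.6],
            [-0.4, 0.6, 1.0],
        ])
        assert np.linalg.eigvalsh(R).min() < 0
        fixed = nearest_pd_correlation(R)
        assert np.linalg.eigvalsh(fixed).min() >= 1e-9
        np.testing.assert_allclose(np.diag(fixed), 1.0)
        np.testing.assert_allclose(fixed, fixed.T)
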