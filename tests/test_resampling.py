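import numpy as np
import pytest

from bprsnet import bprs_catalog, make_truth_network, sample_ordinal
from bprsnet.data import OrdinalResponseMatrix
from bprsnet.resampling import (
    FitConfig,
    case_drop_stability,
    compute_cs,
    group_centrality_permutation,
    nonparametric_bootstrap,
)

FAST = FitConfig(n_lambda=30)


class TestPermutationTest:
    def test_exchangeable_values_give_p_one(self, catalog):
        res = group_centrality_permutation(np.full(18, 2.5), catalog)
        assert res.p_value == 1.0

    def test_extreme_separation_exact_p(self, catalog):
        """With group sizes 8/10 and values 10 for every group-1 node, the
        difference in means is 2.25k - 8 for k tens assigned to group 1, so
        |diff| = 10 is reached by exactly one of the C(18,8)=43758
        assignments (the observed one; the mirror split has size 10 and is
        not a valid assignment)."""
        values = np.where(catalog.group_indicator("DSM"), 10.0, 0.0)
        res = group_centrality_permutation(values, catalog, mode="exhaustive")
        assert res.n_null == 43758
        assert res.p_value == pytest.approx(1 / 43758)

    def test_monte_carlo_close_to_exhaustive(self, catalog):
        rng = np.random.default_rng(0)
        values = rng.normal(size=18)
        exact = group_centrality_permutation(values, catalog, mode="exhaustive")
        R = 20_000
        mc = group_centrality_permutation(
            values, catalog, mode="monte-carlo", R=R, seed=1
        )
        tol = 3 * np.sqrt(exact.p_value * (1 - exact.p_value) / R)
        assert abs(mc.p_value - exact.p_value) <= tol + 2 / R

    def test_monte_carlo_deterministic_given_seed(self, catalog):
        rng = np.random.default_rng(2)
        values = rng.normal(size=18)
        a = group_centrality_permutation(values, catalog, mode="monte-carlo",
                                         R=5000, seed=7)
        b = group_centrality_permutation(values, catalog, mode="monte-carlo",
                                         R=5000, seed=7)
        assert a.p_value == b.p_value

    def test_auto_mode_enumerates_when_cheaper(self, catalog):
        values = np.arange(18.0)
        res = group_centrality_permutation(values, catalog, R=100_000, mode="auto")
        assert res.mode == "exhaustive"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            group_centrality_permutation(np.arange(4.0), np.array([True] * 4))

    def test_boolean_mask_and_label_array_agree(self):
        values = np.array([1.0, 5.0, 2.0, 4.0, 3.0, 0.0])
        mask = np.array([True, False, True, False, True, False])
        labels = np.where(mask, "DSM", "other")
        a = group_centrality_permutation(values, mask)
        b = group_centrality_permutation(values, labels)
        assert a.p_value == b.p_value and a.observed == b.observed


class TestCaseDropStability:
    def test_tiny_drop_is_maximally_stable(self, small_dataset):
        res = case_drop_stability(
            small_dataset.data, FAST, grid=(0.05, 0.1), B_per=6, seed=0
        )
        assert res.cs["strength"] == 0.1
        cors = res.correlations["strength"]
        assert np.nanmin(cors) > 0.7

    def test_interpretability_thresholds(self, small_dataset):
        res = case_drop_stability(
            small_dataset.data, FAST, grid=(0.05,), B_per=4, seed=1
        )
        # the flags implement the published rule: >0.25 interpretable, >0.5 preferred
        made_up = {**res.cs}
        assert res.interpretability("strength") in {"low", "interpretable", "preferred"}
        object.__setattr__(res, "cs", {**made_up, "strength": 0.3})
        assert res.interpretability("strength") == "interpretable"
        object.__setattr__(res, "cs", {**made_up, "strength": 0.55})
        assert res.interpretability("strength") == "preferred"

    def test_cs_nonincreasing_in_correlation_threshold(self, small_dataset):
        res = case_drop_stability(
            small_dataset.data, FAST, grid=(0.1, 0.3, 0.5), B_per=8, seed=2
        )
        cors = res.correlations["strength"]
        values = [
            compute_cs(cors, res.grid, cor_threshold=t) for t in (0.5, 0.6, 0.7, 0.8, 0.9)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_failed_subsamples_are_counted_not_fatal(self):
        # one item deviates in a single subject: half the 50%-subsamples
        # leave it constant, which the polychoric step rejects
        rng = np.random.default_rng(3)
        values = rng.integers(1, 5, size=(60, 3))
        values[:, 2] = 1
        values[0, 2] = 2
        data = OrdinalResponseMatrix(values, ("A", "B", "C"), K=7)
        res = case_drop_stability(data, FAST, grid=(0.5,), B_per=10, seed=4)
        assert res.n_failed >= 1
        assert np.isnan(res.correlations["strength"]).sum() == res.n_failed

    def test_largest_drop_must_leave_enough_cases(self, small_dataset):
        tiny = small_dataset.data.subset_rows(np.arange(8))
        with pytest.raises(ValueError, match="too few"):
            case_drop_stability(tiny, FAST, grid=(0.75,), B_per=2, seed=0)


class TestCsOrdering:
    def test_strength_at_least_as_stable_as_betweenness(self):
        """Across replicated synthetic cohorts, the CS-coefficient of
        strength should not fall below that of betweenness — the qualitative
        pattern reported for real symptom networks, where shortest-path
        counts are far noisier than summed edge mass."""
        from bprsnet.experiments import cs_coefficient_comparison

        results = cs_coefficient_comparison(n_seeds=4, B_per=8, base_seed=0)
        ok = sum(r["strength"] >= r["betweenness"] for r in results)
        assert ok >= 3, results


class TestBootstrap:
    def test_deterministic_given_seed(self, small_dataset):
        a = nonparametric_bootstrap(small_dataset.data, FAST, B=2, seed=5)
        b = nonparametric_bootstrap(small_dataset.data, FAST, B=2, seed=5)
        np.testing.assert_array_equal(a.edge_draws, b.edge_draws)
        for idx in a.centrality_draws:
            np.testing.assert_array_equal(
                a.centrality_draws[idx], b.centrality_draws[idx]
            )

    def test_interval_bounds_ordered(self, small_dataset):
        res = nonparametric_bootstrap(small_dataset.data, FAST, B=12, seed=6)
        for k, (i, j) in enumerate(res.pairs):
            lo, hi = res.edge_interval(i, j)
            assert lo <= hi
        lo, hi = res.centrality_difference_interval("strength", 0, 1)
        assert lo <= hi

    def test_true_zero_edge_interval_covers_zero(self):
        """An edge absent from the generator should have a 95% bootstrap
        interval containing 0 in nearly all replicates (the sparse estimator
        sits at exactly zero in most resamples, so coverage exceeds the
        nominal 95%)."""
        spec = make_truth_network(
            blocks=(2, 2), within_density=1.0, bridge_count=0, seed=8,
        )
        # pair (0, 2) crosses the blocks: true weight 0
        zero_pair = (0, 2)
        assert spec.partials[zero_pair] == 0.0
        covered = 0
        n_rep = 12
        for rep in range(n_rep):
            ds = sample_ordinal(spec, n=300, seed=500 + rep)
            res = nonparametric_bootstrap(ds.data, FAST, B=40, seed=rep)
            lo, hi = res.edge_interval(*zero_pair)
            covered += lo <= 0.0 <= hi
        assert covered >= 10
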