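import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bprsnet import make_truth_network, sample_ordinal, spec_from_partials
from bprsnet.centrality import centrality_table, shortest_path_metrics, strength
from bprsnet.network import RegularizedNetwork
from bprsnet.resampling import fit_centrality


def _net(W, codes=None):
    W = np.asarray(W, dtype=float)
    codes = codes or tuple(chr(65 + i) for i in range(W.shape[0]))
    return RegularizedNetwork(W, codes, lam=0.1, gamma_ebic=0.5, n=100)


def brute_force_metrics(W: np.ndarray):
    """Independent oracle: enumerate every simple path between every pair,
    take the minimum 1/|w| length, split ties fractionally."""
    p = W.shape[0]

    def all_paths(s, t):
        out = []

        def dfs(node, visited, length, path):
            if node == t:
                out.append((length, list(path)))
                return
            for nxt in range(p):
                if W[node, nxt] != 0 and nxt not in visited:
                    visited.add(nxt)
                    path.append(nxt)
                    dfs(nxt, visited, length + 1.0 / abs(W[node, nxt]), path)
                    path.pop()
                    visited.remove(nxt)

        dfs(s, {s}, 0.0, [s])
        return out

    dist = np.full((p, p), np.inf)
    betweenness = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            paths = all_paths(s, t)
            if not paths:
                continue
            dmin = min(length for length, _ in paths)
            dist[s, t] = dist[t, s] = dmin
            shortest = [path for length, path in paths if length <= dmin + 1e-12]
            for v in range(p):
                if v in (s, t):
                    continue
                through = sum(1 for path in shortest if v in path)
                betweenness[v] += through / len(shortest)
    closeness = np.zeros(p)
    for i in range(p):
        finite = dist[i][np.isfinite(dist[i])]
        finite = finite[finite > 0]
        if finite.size:
            closeness[i] = (p - 1) / finite.sum()
    return closeness, betweenness


class TestStrength:
    def test_empty_network_all_zero(self):
        assert np.all(strength(_net(np.zeros((4, 4)))) == 0)

    def test_triangle_arithmetic(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[0, 2] = W[2, 0] = 0.2
        assert strength(_net(W))[0] == pytest.approx(0.5)

    def test_negative_edges_count_by_magnitude(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = -0.4
        np.testing.assert_allclose(strength(_net(W)), [0.4, 0.4])

    def test_adding_an_edge_never_decreases_strength(self):
        rng = np.random.default_rng(0)
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 0.3
        before = strength(_net(W))
        W2 = W.copy()
        W2[2, 3] = W2[3, 2] = 0.2
        after = strength(_net(W2))
        assert np.all(after >= before - 1e-12)


class TestShortestPaths:
    def test_four_node_path_counts(self):
        """A-B-C-D chain, all |w|=0.5: B and C each carry 2 source-target
        pairs (enumerated by hand)."""
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 0.5
        closeness, betweenness = shortest_path_metrics(_net(W))
        np.testing.assert_allclose(betweenness, [0, 2, 2, 0])
        # distances from A: 2,4,6 -> closeness 3/12
        assert closeness[0] == pytest.approx(3 / 12)

    def test_disconnected_graph_zero_closeness(self):
        closeness, betweenness = shortest_path_metrics(_net(np.zeros((3, 3))))
        assert np.all(closeness == 0) and np.all(betweenness == 0)

    def test_matches_brute_force_on_fixed_graph(self):
        rng = np.random.default_rng(3)
        W = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        mask = rng.random(len(iu[0])) < 0.6
        vals = rng.uniform(0.2, 0.9, len(iu[0])) * np.where(rng.random(len(iu[0])) < 0.3, -1, 1)
        W[iu] = np.where(mask, vals, 0.0)
        W = W + W.T
        closeness, betweenness = shortest_path_metrics(_net(W))
        ref_clos, ref_bet = brute_force_metrics(W)
        np.testing.assert_allclose(closeness, ref_clos, atol=1e-9)
        np.testing.assert_allclose(betweenness, ref_bet, atol=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_on_random_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 7))
        W = np.zeros((p, p))
        iu = np.triu_indices(p, 1)
        mask = rng.random(len(iu[0])) < 0.5
        vals = rng.uniform(0.1, 0.95, len(iu[0]))
        W[iu] = np.where(mask, vals, 0.0)
        W = W + W.T
        closeness, betweenness = shortest_path_metrics(_net(W))
        ref_clos, ref_bet = brute_force_metrics(W)
        np.testing.assert_allclose(closeness, ref_clos, atol=1e-9)
        np.testing.assert_allclose(betweenness, ref_bet, atol=1e-9)


class TestCentralityTable:
    def test_two_node_symmetry(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 0.5
        table = centrality_table(_net(W))
        assert table.strength[0] == table.strength[1]
        assert table.closeness[0] == table.closeness[1]
        assert table.betweenness[0] == table.betweenness[1]

    def test_zscores_standardized(self):
        rng = np.random.default_rng(4)
        W = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        W[iu] = rng.uniform(0.1, 0.5, len(iu[0]))
        W = W + W.T
        table = centrality_table(_net(W))
        z = table.z("strength")
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_constant_metric_warns_and_zeroes(self):
        W = np.zeros((3, 3))
        net = _net(W)
        table = centrality_table(net)
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.all(table.z("strength") == 0)

    def test_node_relabeling_permutes_metrics(self):
        rng = np.random.default_rng(6)
        W = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        W[iu] = rng.uniform(0.1, 0.6, len(iu[0])) * (rng.random(len(iu[0])) < 0.7)
        W = W + W.T
        perm = rng.permutation(5)
        table = centrality_table(_net(W))
        table_p = centrality_table(_net(W[np.ix_(perm, perm)]))
        np.testing.assert_allclose(table_p.strength, table.strength[perm], atol=1e-12)
        np.testing.assert_allclose(table_p.closeness, table.closeness[perm], atol=1e-12)
        np.testing.assert_allclose(table_p.betweenness, table.betweenness[perm], atol=1e-12)

    def test_planted_hub_is_recovered(self):
        """A node with dominant true strength should top the estimated
        strength ranking in nearly every replicate."""
        p = 8
        target = np.zeros((p, p))
        for j in range(1, p):
            target[0, j] = target[j, 0] = 0.25
        for j in range(1, p - 1):
            target[j, j + 1] = target[j + 1, j] = 0.12
        spec = spec_from_partials(target)
        hub = spec.item_codes[int(np.argmax(np.abs(spec.partials).sum(axis=1)))]
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            ds = sample_ordinal(spec, n=800, seed=300 + seed)
            _, table = fit_centrality(ds.data)
            hits += table.top_node("strength") == hub
        assert hits >= 9
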