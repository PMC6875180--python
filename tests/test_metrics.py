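"""Nodal graph metrics, sparsity curves, AUC integration, feature tables."""

import numpy as np
import pytest

from netscale.metrics import (
    METRIC_NAMES,
    auc,
    betweenness,
    build_feature_table,
    degree,
    metric_curves,
    nodal_efficiency,
)
from netscale.network import BinaryNetwork, correlation_matrix, threshold_by_sparsity
from netscale.parcellation import subdivide_atlas


def net_from(adj):
    adj = np.asarray(adj, dtype=np.int8)
    e = int(adj.sum() // 2)
    n = adj.shape[0]
    return BinaryNetwork(adjacency=adj, sparsity=2 * e / (n * (n - 1)), edge_count=e)


def path3():
    return net_from([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


def complete(n):
    return net_from(1 - np.eye(n, dtype=np.int8))


def bfs_distances(adj, src):
    n = adj.shape[0]
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u, v] and v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_betweenness(adj, normalized=True):
    """Pair-enumeration oracle: sigma counting over BFS shortest paths."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            ds = bfs_distances(adj, s)
            if t not in ds:
                continue
            # count shortest paths via DP over distance layers
            sigma_s = path_counts(adj, s)
            sigma_t = path_counts(adj, t)
            total = sigma_s[t]
            for v in range(n):
                if v in (s, t) or v not in ds:
                    continue
                dt = bfs_distances(adj, t)
                if v in dt and ds[v] + dt[v] == ds[t]:
                    bc[v] += sigma_s[v] * sigma_t[v] / total
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2
    return bc


def path_counts(adj, src):
    dist = bfs_distances(adj, src)
    n = adj.shape[0]
    sigma = np.zeros(n)
    sigma[src] = 1
    for d in range(1, n):
        for v in range(n):
            if dist.get(v) == d:
                sigma[v] = sum(
                    sigma[u] for u in range(n) if adj[u, v] and dist.get(u) == d - 1
                )
    return sigma


def brute_efficiency(adj):
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        dist = bfs_distances(adj, i)
        out[i] = sum(1.0 / d for v, d in dist.items() if v != i) / (n - 1)
    return out


class TestDegree:
    def test_complete_and_path(self):
        np.testing.assert_allclose(degree(complete(4)), 3)
        np.testing.assert_allclose(degree(path3()), [1, 2, 1])

    def test_handshake_lemma(self, rng):
        for _ in range(10):
            adj = rng.integers(0, 2, size=(8, 8))
            adj = np.triu(adj, 1)
            adj = (adj + adj.T).astype(np.int8)
            net = net_from(adj)
            assert degree(net).sum() == 2 * net.edge_count


class TestBetweenness:
    def test_path_star_complete(self):
        np.testing.assert_allclose(betweenness(path3()), [0, 1, 0])
        star = np.zeros((5, 5), dtype=np.int8)
        star[0, 1:] = star[1:, 0] = 1
        np.testing.assert_allclose(betweenness(net_from(star)), [1, 0, 0, 0, 0])
        np.testing.assert_allclose(betweenness(complete(5)), 0)

    def test_unnormalized_option(self):
        np.testing.assert_allclose(betweenness(path3(), normalized=False), [0, 1, 0])
        star = np.zeros((4, 4), dtype=np.int8)
        star[0, 1:] = star[1:, 0] = 1
        np.testing.assert_allclose(
            betweenness(net_from(star), normalized=False), [3, 0, 0, 0]
        )


class TestNodalEfficiency:
    def test_examples(self):
        np.testing.assert_allclose(nodal_efficiency(complete(4)), 1.0)
        np.testing.assert_allclose(nodal_efficiency(path3()), [0.75, 1.0, 0.75])
        iso = np.zeros((3, 3), dtype=np.int8)
        iso[0, 1] = iso[1, 0] = 1
        assert nodal_efficiency(net_from(iso))[2] == 0.0


class TestOracleEquivalence:
    def test_random_graphs_match_bruteforce(self, rng):
        """Both path-based metrics agree with an enumeration oracle."""
        for _ in range(60):
            p = rng.uniform(0.15, 0.9)
            adj = (rng.random((8, 8)) < p).astype(np.int8)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            net = net_from(adj)
            np.testing.assert_allclose(
                betweenness(net), brute_betweenness(adj), atol=1e-12
            )
            np.testing.assert_allclose(
                nodal_efficiency(net), brute_efficiency(adj), atol=1e-12
            )

    def test_permutation_equivariance(self, rng):
        adj = (rng.random((7, 7)) < 0.4).astype(np.int8)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        perm = rng.permutation(7)
        padj = adj[np.ix_(perm, perm)]
        for fn in (degree, betweenness, nodal_efficiency):
            np.testing.assert_allclose(
                fn(net_from(padj)), fn(net_from(adj))[perm], atol=1e-12
            )


class TestMetricCurvesAndAUC:
    def test_single_threshold_equals_direct_calls(self, rng):
        corr = correlation_matrix(rng.standard_normal((6, 30)))
        curves = metric_curves(corr, np.array([0.3]))
        net = threshold_by_sparsity(corr, 0.3)
        np.testing.assert_allclose(curves["degree"][0], degree(net))
        np.testing.assert_allclose(curves["betweenness"][0], betweenness(net))
        np.testing.assert_allclose(curves["nodal_efficiency"][0], nodal_efficiency(net))

    def test_degree_curves_nondecreasing_in_sparsity(self, rng):
        corr = correlation_matrix(rng.standard_normal((8, 40)))
        curves = metric_curves(corr, np.array([0.1, 0.2, 0.4, 0.8]))
        assert np.all(np.diff(curves["degree"], axis=0) >= 0)

    def test_full_sparsity_limits(self, rng):
        corr = correlation_matrix(rng.standard_normal((6, 30)))
        curves = metric_curves(corr, np.array([0.5, 1.0]))
        np.testing.assert_allclose(curves["nodal_efficiency"][1], 1.0)
        np.testing.assert_allclose(curves["betweenness"][1], 0.0)

    def test_auc_constant_linear_and_summation_oracle(self, rng):
        grid = np.array([0.08, 0.13, 0.18, 0.23, 0.28])
        np.testing.assert_allclose(auc(np.full(5, 3.0), grid), 0.2 * 3.0)
        np.testing.assert_allclose(auc(10 * grid, grid), 5 * (0.28**2 - 0.08**2))
        vals = rng.standard_normal(5)
        mid = sum(
            (vals[i] + vals[i + 1]) / 2 * (grid[i + 1] - grid[i]) for i in range(4)
        )
        assert auc(vals, grid) == pytest.approx(mid)

    def test_auc_rejects_single_point(self):
        with pytest.raises(ValueError):
            auc(np.array([1.0]), np.array([0.1]))


class TestFeatureTable:
    def test_shape_and_metadata_roundtrip(self, tiny_atlas, effect_cohort, tmp_path):
        parc = subdivide_atlas(tiny_atlas, 6, seed=0)
        table = build_feature_table(effect_cohort, parc)
        assert table.n_features == 3 * parc.achieved_N
        assert table.X.shape == (effect_cohort.n_subjects, table.n_features)
        assert np.all(np.isfinite(table.X))
        assert list(table.meta["metric"].unique()) == list(METRIC_NAMES)
        fpath, mpath = tmp_path / "f.tsv", tmp_path / "m.tsv"
        table.to_tsv(fpath, mpath)
        back = type(table).from_tsv(fpath, mpath)
        np.testing.assert_allclose(back.X, table.X, atol=1e-12)
        np.testing.assert_array_equal(back.group, table.group)
        assert back.meta["feature"].tolist() == table.meta["feature"].tolist()
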