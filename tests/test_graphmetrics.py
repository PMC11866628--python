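"""Thresholding and global topology metrics against brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from eegtopo.graphmetrics import (
    DEFAULT_SPARSITY_GRID,
    METRIC_NAMES,
    BinaryGraph,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    rewire_null,
    small_world_indices,
    sparsity_threshold,
    sweep_metrics,
)
from eegtopo.spectral import BandAdjacency
from eegtopo.synth import make_fixture_graph

from conftest import random_weight_matrix

# ---------------------------------------------------------------------------
# brute-force oracles (pure python, independent of the implementation)


def brute_distances(adj: np.ndarray) -> dict[tuple[int, int], float]:
    n = adj.shape[0]
    d = {(i, j): (1.0 if adj[i, j] else np.inf) for i in range(n) for j in range(n)}
    for i in range(n):
        d[(i, i)] = 0.0
    for k in range(n):  # Floyd-Warshall
        for i in range(n):
            for j in range(n):
                if d[(i, k)] + d[(k, j)] < d[(i, j)]:
                    d[(i, j)] = d[(i, k)] + d[(k, j)]
    return d


def brute_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    coeffs = []
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        if len(nbrs) < 2:
            coeffs.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        coeffs.append(2.0 * links / (len(nbrs) * (len(nbrs) - 1)))
    return sum(coeffs) / n


def brute_path_length(adj: np.ndarray) -> float:
    d = brute_distances(adj)
    vals = [
        d[(i, j)]
        for i, j in itertools.combinations(range(adj.shape[0]), 2)
        if np.isfinite(d[(i, j)])
    ]
    return sum(vals) / len(vals)


def brute_global_efficiency(adj: np.ndarray) -> float:
    d = brute_distances(adj)
    pairs = list(itertools.combinations(range(adj.shape[0]), 2))
    return sum(
        (1.0 / d[(i, j)] if np.isfinite(d[(i, j)]) else 0.0) for i, j in pairs
    ) / len(pairs)


def brute_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += brute_global_efficiency(sub)
    return total / n


def _graph(edges, n):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return BinaryGraph(adjacency=a)


# ---------------------------------------------------------------------------


class TestSparsityThreshold:
    def test_full_sparsity_gives_complete_graph(self):
        w = random_weight_matrix(8, seed=0)
        g = sparsity_threshold(w, 1.0)
        assert g.n_edges == 8 * 7 // 2

    def test_rounding_rule_on_171_pairs(self):
        w = random_weight_matrix(19, seed=1)
        assert sparsity_threshold(w, 0.05).n_edges == 9  # round(8.55) up
        assert sparsity_threshold(w, 0.10).n_edges == 17  # round(17.1) down

    @pytest.mark.parametrize("seed", range(5))
    def test_keeps_largest_edges_vs_sort_oracle(self, seed):
        n = 6
        w = random_weight_matrix(n, seed=seed)
        s = 0.5
        g = sparsity_threshold(w, s)
        pairs = sorted(
            itertools.combinations(range(n), 2), key=lambda p: -w[p[0], p[1]]
        )
        k = int(np.floor(s * len(pairs) + 0.5))
        expected = set(pairs[:k])
        got = {tuple(e) for e in g.edge_list()}
        assert got == expected

    def test_tie_break_deterministic(self):
        w = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        w[iu] = 0.5  # all weights equal
        w = w + w.T
        g1 = sparsity_threshold(w, 0.5)
        g2 = sparsity_threshold(w, 0.5)
        assert np.array_equal(g1.adjacency, g2.adjacency)
        # lexicographically first pairs kept: (0,1), (0,2), (0,3)
        assert {tuple(e) for e in g1.edge_list()} == {(0, 1), (0, 2), (0, 3)}

    def test_all_zero_adjacency_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sparsity_threshold(np.zeros((5, 5)), 0.5)

    def test_band_adjacency_input(self):
        w = random_weight_matrix(5, seed=2)
        adj = BandAdjacency(band="alpha", low=8, high=13, W=w / w.max() * 0.9)
        g = sparsity_threshold(adj, 0.3)
        assert g.sparsity == 0.3


class TestMetricExamples:
    def test_complete_k4(self):
        g = _graph(itertools.combinations(range(4), 2), 4)
        assert clustering_coefficient(g) == 1.0
        assert characteristic_path_length(g)[0] == 1.0
        assert global_efficiency(g) == 1.0
        assert local_efficiency(g) == 1.0

    def test_star(self):
        g = _graph([(0, i) for i in range(1, 5)], 5)
        assert clustering_coefficient(g) == 0.0
        assert local_efficiency(g) == 0.0

    def test_triangle_plus_pendant(self):
        g = _graph([(0, 1), (1, 2), (2, 0), (0, 3)], 4)
        assert clustering_coefficient(g) == pytest.approx(7 / 12, abs=1e-15)
        assert local_efficiency(g) == pytest.approx(7 / 12, abs=1e-15)

    def test_path_and_ring_path_lengths(self):
        path = _graph([(0, 1), (1, 2)], 3)
        lp, unreachable = characteristic_path_length(path)
        assert lp == pytest.approx(4 / 3, abs=1e-15)
        assert unreachable == 0
        assert global_efficiency(path) == pytest.approx((1 + 1 + 0.5) / 3, abs=1e-15)
        ring = _graph([(i, (i + 1) % 5) for i in range(5)], 5)
        assert characteristic_path_length(ring)[0] == 1.5

    def test_disconnected_pairs(self):
        two_edges = _graph([(0, 1), (2, 3)], 4)
        assert global_efficiency(two_edges) == pytest.approx(1 / 3, abs=1e-15)
        lp, unreachable = characteristic_path_length(two_edges)
        assert lp == 1.0  # reachable pairs only
        assert unreachable == 4
        empty = _graph([], 3)
        with pytest.raises(ValueError, match="connected"):
            characteristic_path_length(empty)


class TestOracleEquivalence:
    def test_all_graphs_up_to_six_nodes(self):
        """Cp, Lp, Eg, Eloc match brute force to 1e-12 on the full atlas."""
        checked = 0
        for G in nx.graph_atlas_g()[1:]:
            n = G.number_of_nodes()
            if n < 2 or n > 6 or G.number_of_edges() == 0:
                continue
            adj = nx.to_numpy_array(G, dtype=bool)
            g = BinaryGraph(adjacency=adj)
            assert clustering_coefficient(g) == pytest.approx(
                brute_clustering(adj), abs=1e-12
            )
            assert global_efficiency(g) == pytest.approx(
                brute_global_efficiency(adj), abs=1e-12
            )
            assert local_efficiency(g) == pytest.approx(
                brute_local_efficiency(adj), abs=1e-12
            )
            if nx.number_connected_components(G) < n:  # some connected pair
                assert characteristic_path_length(g)[0] == pytest.approx(
                    brute_path_length(adj), abs=1e-12
                )
            checked += 1
        assert checked > 100

    @pytest.mark.parametrize("seed", range(10))
    def test_random_19_node_graphs_vs_networkx(self, seed):
        """Independent cross-check against networkx on montage-sized graphs."""
        rng = np.random.default_rng(seed)
        adj = rng.uniform(size=(19, 19)) < 0.25
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        if adj.sum() == 0:
            return
        g = BinaryGraph(adjacency=adj)
        G = nx.from_numpy_array(adj)
        assert clustering_coefficient(g) == pytest.approx(
            nx.average_clustering(G), abs=1e-12
        )
        assert global_efficiency(g) == pytest.approx(
            nx.global_efficiency(G), abs=1e-12
        )
        assert local_efficiency(g) == pytest.approx(
            nx.local_efficiency(G), abs=1e-12
        )


class TestRewireNull:
    @pytest.mark.parametrize("seed", range(10))
    def test_degree_sequence_and_edge_count_preserved(self, seed):
        w = random_weight_matrix(19, seed=seed)
        g = sparsity_threshold(w, 0.3)
        null = rewire_null(g, seed=seed)
        assert np.array_equal(null.degrees(), g.degrees())
        assert null.n_edges == g.n_edges
        assert not np.any(np.diag(null.adjacency))

    def test_same_seed_identical_null(self):
        g = sparsity_threshold(random_weight_matrix(12, seed=3), 0.4)
        a = rewire_null(g, seed=77)
        b = rewire_null(g, seed=77)
        assert np.array_equal(a.adjacency, b.adjacency)
        c = rewire_null(g, seed=78)
        assert not np.array_equal(a.adjacency, c.adjacency)

    def test_actually_randomizes(self):
        g = make_fixture_graph("ring_lattice", {"n": 30, "k": 4})
        null = rewire_null(g, seed=0)
        assert not np.array_equal(null.adjacency, g.adjacency)

    def test_too_few_edges_raises(self):
        g = _graph([(0, 1)], 3)
        with pytest.raises(ValueError):
            rewire_null(g, seed=0)


class TestSmallWorldIndices:
    def test_ring_lattice_gamma_above_one(self):
        g = make_fixture_graph("ring_lattice", {"n": 50, "k": 6})
        gamma, lam, sigma = small_world_indices(g, n_null=20, seed=5)
        assert gamma > 1.0
        assert sigma == pytest.approx(gamma / lam, abs=1e-15)

    def test_dense_random_graph_self_normalizes(self):
        g = make_fixture_graph("erdos_renyi", {"n": 50, "p": 0.5}, seed=9)
        cps = []
        rng = np.random.default_rng(0)
        for i in range(20):
            cps.append(clustering_coefficient(rewire_null(g, seed=rng)))
        gamma, lam, sigma = small_world_indices(g, n_null=20, seed=1)
        spread = 2 * np.std(cps) / np.mean(cps)
        assert abs(gamma - 1.0) < max(spread, 0.05)
        assert abs(sigma - 1.0) < max(2 * spread, 0.1)

    def test_n_null_minimum(self):
        g = make_fixture_graph("ring_lattice", {"n": 20, "k": 4})
        with pytest.raises(ValueError, match="n_null"):
            small_world_indices(g, n_null=1, seed=0)


@pytest.fixture(scope="module")
def curves():
    w = random_weight_matrix(19, seed=7)
    adj = BandAdjacency(band="alpha", low=8, high=13, W=w / w.max() * 0.9)
    return sweep_metrics(adj, n_null=4, seed=0)


class TestSweepMetrics:
    def test_default_grid_has_19_levels(self):
        assert len(DEFAULT_SPARSITY_GRID) == 19
        assert DEFAULT_SPARSITY_GRID[0] == pytest.approx(0.05)
        assert DEFAULT_SPARSITY_GRID[-1] == pytest.approx(0.95)
        assert np.allclose(np.diff(DEFAULT_SPARSITY_GRID), 0.05)

    def test_shape_and_metric_axis(self, curves):
        assert curves.values.shape == (7, 1, 19)
        assert curves.metrics == METRIC_NAMES

    def test_eg_and_cp_nondecreasing_in_sparsity(self, curves):
        eg = curves.get("Eg", "alpha")
        assert np.all(np.diff(eg) >= -1e-12)

    def test_cp_is_one_at_full_sparsity(self):
        w = random_weight_matrix(10, seed=8)
        adj = BandAdjacency(band="beta", low=13, high=30, W=w / w.max() * 0.9)
        mc = sweep_metrics(adj, grid=(0.5, 1.0), n_null=2, seed=0)
        assert mc.get("Cp", "beta")[-1] == 1.0

    def test_empty_grid_rejected(self):
        w = random_weight_matrix(5, seed=9)
        adj = BandAdjacency(band="delta", low=1, high=4, W=w / w.max() * 0.9)
        with pytest.raises(ValueError):
            sweep_metrics(adj, grid=(), n_null=2, seed=0)

    def test_undefined_levels_are_nan_not_fabricated(self):
        # a weight matrix whose 5% graph has almost no triangles/edges
        w = np.zeros((19, 19))
        w[0, 1] = w[1, 0] = 0.9
        w[2, 3] = w[3, 2] = 0.8
        w[4, 5] = w[5, 4] = 0.7
        for i in range(19):  # tiny distinct weights elsewhere
            for j in range(i + 1, 19):
                if w[i, j] == 0:
                    w[i, j] = w[j, i] = 1e-4 + 1e-6 * (19 * i + j)
        adj = BandAdjacency(band="theta", low=4, high=8, W=w)
        mc = sweep_metrics(adj, grid=(0.02, 0.5), n_null=4, seed=0)
        gamma_low = mc.get("gamma", "theta")[0]
        assert np.isnan(gamma_low)  # 3 disjoint edges: null mean Cp = 0
        assert np.isfinite(mc.get("Cp", "theta")).all()
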