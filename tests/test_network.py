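"""Proportional thresholding, weighted graph metrics, and null models."""

import itertools

import networkx as nx
import numpy as np
import pytest

from plinet.connectivity import ConnectivityMatrix
from plinet.network import (
    DEFAULT_SWEEP,
    WeightedNetwork,
    maslov_sneppen_rewire,
    metrics_over_sweep,
    proportional_threshold,
    small_world_sigma,
    threshold_sweep,
    weighted_clustering,
    weighted_path_length,
)

from conftest import random_connectivity


def _random_network(rng, n_nodes=8, density=0.5):
    iu = np.triu_indices(n_nodes, k=1)
    keep = rng.random(len(iu[0])) < density
    while keep.sum() < 2:
        keep = rng.random(len(iu[0])) < density
    edges = np.column_stack((iu[0][keep], iu[1][keep]))
    return WeightedNetwork(
        nodes=tuple(f"n{i}" for i in range(n_nodes)),
        edge_index=edges,
        weights=rng.uniform(0.05, 1.0, keep.sum()),
    )


def _to_nx(net: WeightedNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    for (i, j), w in zip(net.edge_index, net.weights):
        g.add_edge(int(i), int(j), weight=float(w), length=1.0 / float(w))
    return g


class TestProportionalThreshold:
    def test_quarter_density_on_16_nodes(self, connectivity_16):
        assert proportional_threshold(connectivity_16, 0.25).n_edges == 30

    def test_full_retention(self, connectivity_16):
        net = proportional_threshold(connectivity_16, 1.0)
        assert net.n_edges == 120

    def test_top_one_selection(self):
        v = np.array(
            [[0, 0.9, 0.5], [0.9, 0, 0.1], [0.5, 0.1, 0]], dtype=float
        )
        net = proportional_threshold(ConnectivityMatrix(v, ("a", "b", "c")), 1 / 3)
        assert net.n_edges == 1
        assert net.weights[0] == 0.9
        assert tuple(net.edge_index[0]) == (0, 1)

    def test_invalid_fraction(self, connectivity_16):
        for bad in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError, match="fraction"):
                proportional_threshold(connectivity_16, bad)

    def test_retained_weights_are_the_largest(self, connectivity_16):
        net = proportional_threshold(connectivity_16, 0.3)
        iu = np.triu_indices(16, k=1)
        all_w = np.sort(connectivity_16.values[iu])[::-1]
        np.testing.assert_allclose(np.sort(net.weights)[::-1], all_w[: net.n_edges])

    def test_tie_break_is_deterministic(self):
        v = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        v[iu] = 0.5  # all weights tied
        v += v.T
        net = proportional_threshold(ConnectivityMatrix(v, tuple("abcd")), 2 / 6)
        assert [tuple(e) for e in net.edge_index] == [(0, 1), (0, 2)]


class TestThresholdSweep:
    def test_default_sweep_gives_11_networks(self, connectivity_16):
        nets = threshold_sweep(connectivity_16)
        assert len(nets) == 11
        assert [n.n_edges for n in nets] == [round(f * 120) for f in DEFAULT_SWEEP]

    def test_edge_counts_at_sweep_ends(self, connectivity_16):
        nets = threshold_sweep(connectivity_16, [0.25, 0.35])
        assert [n.n_edges for n in nets] == [30, 42]

    def test_nested_edge_sets_for_distinct_weights(self, connectivity_16):
        lo, hi = threshold_sweep(connectivity_16, [0.25, 0.35])
        lo_set = set(map(tuple, lo.edge_index))
        hi_set = set(map(tuple, hi.edge_index))
        assert lo_set <= hi_set

    def test_empty_fraction_list_rejected(self, connectivity_16):
        with pytest.raises(ValueError, match="non-empty"):
            threshold_sweep(connectivity_16, [])


class TestWeightedClustering:
    def test_unit_weight_triangle_saturates(self):
        net = WeightedNetwork(("a", "b", "c"), [[0, 1], [0, 2], [1, 2]], [1, 1, 1])
        per_node, mean = weighted_clustering(net)
        np.testing.assert_allclose(per_node, 1.0)
        assert mean == pytest.approx(1.0)

    def test_any_pure_triangle_saturates(self, triangle):
        # every neighbour pair of every node closes, so the normalised
        # triangle intensity is 1 regardless of the weights
        per_node, mean = weighted_clustering(triangle)
        np.testing.assert_allclose(per_node, 1.0)
        assert mean == pytest.approx(1.0)

    def test_path_has_no_triangles(self):
        net = WeightedNetwork(("a", "b", "c"), [[0, 1], [1, 2]], [0.7, 0.2])
        per_node, mean = weighted_clustering(net)
        np.testing.assert_array_equal(per_node, 0.0)
        assert mean == 0.0

    def test_open_triple_hand_value(self):
        # square with one diagonal: node 0 neighbours {1, 2, 3}; only the
        # (1, 2) pair closes -> C_0 = 2 * (w01 + w02)/2 / (S_0 * (k_0 - 1))
        net = WeightedNetwork(
            ("a", "b", "c", "d"),
            [[0, 1], [0, 2], [0, 3], [1, 2]],
            [0.4, 0.8, 0.6, 0.5],
        )
        per_node, _ = weighted_clustering(net)
        s0, k0 = 0.4 + 0.8 + 0.6, 3
        assert per_node[0] == pytest.approx((0.4 + 0.8) / (s0 * (k0 - 1)))

    def test_normalisation_bounds_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            net = _random_network(rng, n_nodes=int(rng.integers(4, 10)))
            per_node, mean = weighted_clustering(net)
            assert np.all(per_node >= 0) and np.all(per_node <= 1 + 1e-12)
            assert 0 <= mean <= 1 + 1e-12

    def test_equal_weights_reduce_to_binary_clustering(self):
        rng = np.random.default_rng(11)
        for w in (0.3, 1.0):
            net = _random_network(rng, n_nodes=9)
            net = WeightedNetwork(
                net.nodes, net.edge_index, np.full(net.n_edges, w)
            )
            per_node, _ = weighted_clustering(net)
            binary = nx.clustering(_to_nx(net))
            for i in range(net.n_nodes):
                assert per_node[i] == pytest.approx(binary[i], abs=1e-12)

    def test_triple_enumeration_oracle(self):
        """Barrat coefficient equals direct enumeration over neighbour pairs."""
        rng = np.random.default_rng(13)
        for _ in range(200):
            net = _random_network(rng, n_nodes=6)
            w = net.adjacency()
            per_node, _ = weighted_clustering(net)
            for i in range(6):
                nbrs = np.flatnonzero(w[i])
                if len(nbrs) < 2:
                    assert per_node[i] == 0.0
                    continue
                acc = sum(
                    (w[i, j] + w[i, h]) / 2
                    for j, h in itertools.permutations(nbrs, 2)
                    if w[j, h] > 0
                )
                expected = acc / (w[i].sum() * (len(nbrs) - 1))
                assert per_node[i] == pytest.approx(expected, abs=1e-12)


class TestWeightedPathLength:
    def test_single_edge(self):
        net = WeightedNetwork(("a", "b"), [[0, 1]], [0.5])
        assert weighted_path_length(net).value == pytest.approx(2.0)

    def test_triangle_hand_value(self, triangle):
        # l(a,b) = 2, l(a,c) = 2, l(b,c) = 1; the 1/0.5 + 1/1 = 3 detour never wins
        pl = weighted_path_length(triangle)
        assert pl.value == pytest.approx(5 / 3)
        assert not pl.disconnected

    def test_disconnected_component_flagged(self):
        net = WeightedNetwork(("a", "b", "c"), [[0, 1]], [0.5])
        pl = weighted_path_length(net)
        assert pl.disconnected
        assert pl.n_unreachable_pairs == 2
        assert pl.value == pytest.approx(2.0)  # mean over the reachable pair

    def test_equal_weights_reduce_to_scaled_binary_path_length(self):
        rng = np.random.default_rng(3)
        for w in (0.25, 0.8):
            net = _random_network(rng, n_nodes=8, density=0.6)
            net = WeightedNetwork(net.nodes, net.edge_index, np.full(net.n_edges, w))
            g = _to_nx(net)
            if not nx.is_connected(g):
                continue
            binary_l = nx.average_shortest_path_length(g)
            assert weighted_path_length(net).value == pytest.approx(binary_l / w)

    def test_dijkstra_oracle_on_small_graphs(self):
        """Matches networkx all-pairs Dijkstra on random <= 6-node graphs."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            net = _random_network(rng, n_nodes=int(rng.integers(3, 7)))
            g = _to_nx(net)
            dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
            pairs = [
                dist[i][j]
                for i in range(net.n_nodes)
                for j in range(net.n_nodes)
                if i != j and j in dist[i]
            ]
            assert weighted_path_length(net).value == pytest.approx(
                np.mean(pairs), abs=1e-12
            )


class TestMaslovSneppen:
    def test_conservation_laws(self, rng):
        for seed in range(10):
            net = _random_network(rng, n_nodes=12, density=0.35)
            surr = maslov_sneppen_rewire(net, swaps_per_edge=10, seed=seed)
            assert surr.n_nodes == net.n_nodes
            assert surr.n_edges == net.n_edges
            assert sorted(surr.degrees()) == sorted(net.degrees())
            np.testing.assert_allclose(
                np.sort(surr.weights), np.sort(net.weights)
            )
            pairs = set(map(tuple, surr.edge_index))
            assert len(pairs) == surr.n_edges
            assert all(i < j for i, j in pairs)

    def test_three_node_path_cannot_be_rewired(self):
        net = WeightedNetwork(("a", "b", "c"), [[0, 1], [1, 2]], [0.4, 0.6])
        surr = maslov_sneppen_rewire(net, swaps_per_edge=5, seed=0)
        assert surr.rewire_failed
        np.testing.assert_array_equal(surr.edge_index, net.edge_index)

    def test_deterministic_for_fixed_seed(self, rng):
        net = _random_network(rng, n_nodes=10, density=0.4)
        a = maslov_sneppen_rewire(net, 10, seed=42)
        b = maslov_sneppen_rewire(net, 10, seed=42)
        np.testing.assert_array_equal(a.edge_index, b.edge_index)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_actually_randomises(self, rng):
        net = _random_network(rng, n_nodes=12, density=0.4)
        surr = maslov_sneppen_rewire(net, 10, seed=1)
        assert set(map(tuple, surr.edge_index)) != set(map(tuple, net.edge_index))


def _planted_block_matrix() -> ConnectivityMatrix:
    """Two dense high-weight blocks on 16 nodes: strongly clustered topology."""
    rng = np.random.default_rng(99)
    v = np.zeros((16, 16))
    iu = np.triu_indices(16, 1)
    v[iu] = rng.uniform(0.05, 0.25, 120)
    for block in (range(0, 6), range(8, 14)):
        for i, j in itertools.combinations(block, 2):
            v[i, j] = rng.uniform(0.7, 0.95)
    v = np.triu(v, 1) + np.triu(v, 1).T
    return ConnectivityMatrix(v, tuple(f"e{i:02d}" for i in range(16)))


class TestSmallWorldSigma:
    def test_complete_equal_weight_graph_has_sigma_one(self):
        idx = list(itertools.combinations(range(6), 2))
        net = WeightedNetwork(tuple("abcdef"), idx, [0.5] * len(idx))
        rec = small_world_sigma(net, n_surrogates=5, seed=0)
        assert rec.sigma == pytest.approx(1.0)
        assert rec.c_rand == pytest.approx(rec.clustering_mean)
        assert rec.l_rand == pytest.approx(rec.path_length)

    def test_deterministic_for_fixed_seed(self):
        net = proportional_threshold(_planted_block_matrix(), 0.3)
        a = small_world_sigma(net, n_surrogates=50, seed=123)
        b = small_world_sigma(net, n_surrogates=50, seed=123)
        assert a.sigma == b.sigma
        assert a.c_rand == b.c_rand and a.l_rand == b.l_rand

    def test_clustered_topology_exceeds_random_clustering(self):
        net = proportional_threshold(_planted_block_matrix(), 0.3)
        rec = small_world_sigma(net, n_surrogates=50, seed=5)
        assert rec.c_exceeds_random
        assert rec.clustering_mean / rec.c_rand > 1.5

    def test_sampling_stability_when_doubling_surrogates(self):
        """sigma moves by less than 3x the surrogate-mean standard error."""
        from plinet.network import _child_seeds

        net = proportional_threshold(_planted_block_matrix(), 0.3)
        n = 40
        a = small_world_sigma(net, n_surrogates=n, seed=7)
        b = small_world_sigma(net, n_surrogates=2 * n, seed=7)
        # independent estimate of the surrogate spread at the same seed family
        c_vals, l_vals = [], []
        for child in _child_seeds(7, n):
            surr = maslov_sneppen_rewire(net, 10, seed=child)
            c_vals.append(weighted_clustering(surr)[1])
            l_vals.append(weighted_path_length(surr).value)
        rel_se = np.hypot(
            np.std(c_vals) / np.mean(c_vals), np.std(l_vals) / np.mean(l_vals)
        ) / np.sqrt(n)
        assert abs(a.sigma - b.sigma) < 3 * rel_se * a.sigma + 1e-12


class TestMetricsOverSweep:
    def test_summary_is_column_mean_of_11_rows(self, connectivity_16):
        sweep = metrics_over_sweep(connectivity_16, n_surrogates=5, seed=1)
        assert len(sweep.per_threshold) == 11
        for col, attr in [("Cw", "clustering_mean"), ("Lw", "path_length"), ("sigma", "sigma")]:
            assert getattr(sweep.summary, attr) == pytest.approx(
                sweep.per_threshold[col].mean()
            )

    def test_single_fraction_equals_direct_call(self, connectivity_16):
        sweep = metrics_over_sweep(
            connectivity_16, fractions=[0.30], n_surrogates=5, seed=9
        )
        row = sweep.per_threshold.iloc[0]
        assert sweep.summary.clustering_mean == pytest.approx(row["Cw"])
        assert sweep.summary.path_length == pytest.approx(row["Lw"])
        assert sweep.summary.sigma == pytest.approx(row["sigma"])

    def test_per_threshold_rows_match_independent_metric_calls(self, connectivity_16):
        sweep = metrics_over_sweep(connectivity_16, n_surrogates=3, seed=2)
        for _, row in sweep.per_threshold.iterrows():
            net = proportional_threshold(connectivity_16, row["threshold"])
            assert row["n_edges"] == net.n_edges
            assert row["Cw"] == pytest.approx(weighted_clustering(net)[1])
            assert row["Lw"] == pytest.approx(weighted_path_length(net).value)
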