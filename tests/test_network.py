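"""Containers, I/O, thresholding, graph metrics and null models.

Metric implementations are checked against independent brute-force
computations (triangle counting, shortest-path enumeration via networkx)
on small and random graphs.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from connectogen import (
    SpatialNetwork,
    WeightedConnectome,
    degree_preserving_null,
    global_metrics,
    load_connectome,
    nodal_metrics,
    random_wired_ensemble,
    save_connectome,
    threshold_binarize,
)
from connectogen.network import (
    clustering_coefficients,
    global_efficiency,
    long_distance_count,
    matching_index_matrix,
)

from conftest import adjacency_from_edges, make_network, random_network


def _coords(n, seed=0):
    return np.random.default_rng(seed).normal(size=(n, 3)) * 3.0


class TestIO:
    def test_symmetrization_by_max(self, tmp_path):
        mat = np.zeros((3, 3))
        mat[0, 1] = 5.0  # (1,2) entry set, transpose entry zero
        pd.DataFrame(mat).to_csv(tmp_path / "m.csv", index=False, header=False)
        coords = _coords(3)
        pd.DataFrame(
            {"label": ["a", "b", "c"], "x": coords[:, 0], "y": coords[:, 1],
             "z": coords[:, 2]}
        ).to_csv(tmp_path / "c.csv", index=False)
        wc = load_connectome(tmp_path / "m.csv", tmp_path / "c.csv")
        assert wc.weights[0, 1] == wc.weights[1, 0] == 5.0

    def test_self_connections_removed(self, tmp_path):
        mat = np.eye(4) * 9.0
        pd.DataFrame(mat).to_csv(tmp_path / "m.csv", index=False, header=False)
        coords = _coords(4)
        pd.DataFrame(
            {"label": list("abcd"), "x": coords[:, 0], "y": coords[:, 1],
             "z": coords[:, 2]}
        ).to_csv(tmp_path / "c.csv", index=False)
        wc = load_connectome(tmp_path / "m.csv", tmp_path / "c.csv")
        assert np.all(np.diag(wc.weights) == 0)

    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        w = rng.integers(0, 10_000, size=(6, 6)).astype(float)
        w = np.maximum(w, w.T)
        np.fill_diagonal(w, 0)
        wc = WeightedConnectome(w, [f"r{i}" for i in range(6)], _coords(6))
        save_connectome(wc, tmp_path / "m.csv", tmp_path / "c.csv")
        back = load_connectome(tmp_path / "m.csv", tmp_path / "c.csv")
        np.testing.assert_array_equal(back.weights, wc.weights)
        np.testing.assert_array_equal(back.coords, wc.coords)
        assert back.labels == wc.labels

    def test_rejects_non_square_and_negative(self, tmp_path):
        pd.DataFrame(np.ones((2, 3))).to_csv(
            tmp_path / "bad.csv", index=False, header=False
        )
        coords = _coords(3)
        pd.DataFrame(
            {"label": list("abc"), "x": coords[:, 0], "y": coords[:, 1],
             "z": coords[:, 2]}
        ).to_csv(tmp_path / "c.csv", index=False)
        with pytest.raises(ValueError, match="square"):
            load_connectome(tmp_path / "bad.csv", tmp_path / "c.csv")
        with pytest.raises(ValueError):
            WeightedConnectome(-np.ones((3, 3)), list("abc"), coords)


class TestThreshold:
    def test_streamline_threshold(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 5000.0
        w[1, 2] = w[2, 1] = 7000.0
        wc = WeightedConnectome(w, list("abc"), _coords(3))
        net = threshold_binarize(wc, 6100.0)
        assert net.n_edges == 1 and net.adjacency[1, 2] == 1

    def test_zero_threshold_connects_all_positive(self):
        n = 5
        w = np.full((n, n), 3.0)
        np.fill_diagonal(w, 0)
        net = threshold_binarize(WeightedConnectome(w, list("abcde"), _coords(5)), 0.0)
        assert net.n_edges == n * (n - 1) // 2

    def test_percentile_threshold_matches_brute_force(self):
        rng = np.random.default_rng(7)
        w = rng.random((10, 10)) * 100
        w = np.maximum(w, w.T)
        np.fill_diagonal(w, 0)
        iu, ju = np.triu_indices(10, k=1)
        thr = np.percentile(w[iu, ju], 90)
        net = threshold_binarize(
            WeightedConnectome(w, [f"r{i}" for i in range(10)], _coords(10)), thr
        )
        assert net.n_edges == int(np.sum(w[iu, ju] > thr))


class TestNodalMetrics:
    def test_complete_graph_closed_form(self):
        net = make_network(adjacency_from_edges(4, itertools.combinations(range(4), 2)))
        p = nodal_metrics(net)
        np.testing.assert_array_equal(p.degree, [3, 3, 3, 3])
        np.testing.assert_array_equal(p.clustering, [1, 1, 1, 1])
        np.testing.assert_array_equal(p.betweenness, [0, 0, 0, 0])

    def test_path_graph_betweenness(self):
        net = make_network(adjacency_from_edges(3, [(0, 1), (1, 2)]))
        p = nodal_metrics(net)
        np.testing.assert_array_equal(p.betweenness, [0, 1, 0])
        np.testing.assert_array_equal(p.clustering, [0, 0, 0])

    def test_empty_graph_all_zero(self):
        net = make_network(np.zeros((5, 5), dtype=int))
        assert not np.any(nodal_metrics(net).as_matrix())

    def test_incident_edge_length_uses_distances(self):
        net = make_network(adjacency_from_edges(3, [(0, 1), (1, 2)]))
        p = nodal_metrics(net)
        d = net.distances
        assert p.edge_length[1] == pytest.approx(d[0, 1] + d[1, 2])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_networkx_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(7, 0.45, rng)
        g = net.to_networkx()
        p = nodal_metrics(net)
        np.testing.assert_allclose(
            p.clustering, [nx.clustering(g, v) for v in g], atol=1e-12
        )
        bc = nx.betweenness_centrality(g, normalized=False)
        np.testing.assert_allclose(p.betweenness, [bc[v] for v in g], atol=1e-9)

    def test_matching_index_brute_force(self):
        rng = np.random.default_rng(1)
        net = random_network(7, 0.5, rng)
        adj = net.adjacency
        m = matching_index_matrix(adj)
        for i in range(7):
            for j in range(7):
                if i == j:
                    continue
                ni = set(np.flatnonzero(adj[i])) - {j}
                nj = set(np.flatnonzero(adj[j])) - {i}
                union = ni | nj
                expect = len(ni & nj) / len(union) if union else 0.0
                assert m[i, j] == pytest.approx(expect, abs=1e-12)


class TestGlobalMetrics:
    def test_complete_graph_efficiency_one(self):
        net = make_network(adjacency_from_edges(5, itertools.combinations(range(5), 2)))
        assert global_efficiency(net) == pytest.approx(1.0)

    def test_efficiency_matches_bfs_oracle(self):
        net = make_network(
            adjacency_from_edges(6, [(0, 1), (1, 2), (2, 3), (3, 4), (0, 5)])
        )
        g = net.to_networkx()
        total = 0.0
        for u, v in itertools.combinations(range(6), 2):
            try:
                total += 1.0 / nx.shortest_path_length(g, u, v)
            except nx.NetworkXNoPath:
                pass
        assert global_efficiency(net) == pytest.approx(total / 15, abs=1e-12)

    def test_long_distance_rule_hand_arithmetic(self):
        # collinear layout so edge lengths are exact by construction
        def path_net(xs):
            coords = np.column_stack([xs, np.zeros(len(xs)), np.zeros(len(xs))])
            edges = [(i, i + 1) for i in range(len(xs) - 1)]
            return make_network(adjacency_from_edges(len(xs), edges), coords)

        # lengths {1,1,1,10}: mean 3.25, SD 3.897 -> cut 11.04, no long edges
        assert long_distance_count(path_net([0, 1, 2, 3, 13]), 2.0) == 0
        # lengths {1,1,1,1,1,20}: mean 4.167, SD 7.081 -> cut 18.33, one
        assert long_distance_count(path_net([0, 1, 2, 3, 4, 5, 25]), 2.0) == 1
        # cohort-pooled reference set overrides the network's own lengths
        assert long_distance_count(
            path_net([0, 1, 2, 3, 13]), 2.0, reference_lengths=np.ones(50)
        ) == 1

    def test_profile_fields(self, small_cohort):
        net = small_cohort.networks[small_cohort.subjects[0]]
        rng = np.random.default_rng(0)
        prof = global_metrics(net, n_null=20, rng=rng)
        assert prof.n_edges == net.n_edges
        assert prof.n_long_distance <= prof.n_edges
        assert 0 <= prof.global_efficiency <= 1
        assert -0.5 <= prof.modularity <= 1


class TestNullModels:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(2)
        net = random_network(12, 0.3, rng)
        for null in degree_preserving_null(net, n=5, rng=rng):
            np.testing.assert_array_equal(
                np.sort(null.degrees), np.sort(net.degrees)
            )
            assert np.all(np.diag(null.adjacency) == 0)

    def test_four_cycle_stays_simple(self):
        net = make_network(adjacency_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)]))
        rng = np.random.default_rng(0)
        for null in degree_preserving_null(net, n=20, rng=rng):
            assert np.all(np.diag(null.adjacency) == 0)
            assert np.array_equal(null.adjacency, null.adjacency.T)
            assert set(np.unique(null.adjacency)) <= {0, 1}
            assert null.n_edges == 4

    def test_random_ensemble_edge_count_exact(self):
        rng = np.random.default_rng(3)
        net = random_network(10, 0.3, rng)
        for member in random_wired_ensemble(net, n=10, rng=rng):
            assert member.n_edges == net.n_edges

    def test_random_ensemble_uniform_over_pairs(self):
        # 5 nodes, 3 edges: each of the 10 pairs appears with prob 3/10
        rng = np.random.default_rng(4)
        net = make_network(adjacency_from_edges(5, [(0, 1), (2, 3), (1, 4)]))
        counts = np.zeros((5, 5))
        n_members = 4000
        for member in random_wired_ensemble(net, n=n_members, rng=rng):
            counts += member.adjacency
        iu, ju = np.triu_indices(5, k=1)
        freqs = counts[iu, ju] / n_members
        np.testing.assert_allclose(freqs, 0.3, atol=0.03)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_adding_edge_never_decreases_efficiency(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(10, 0.25, rng)
        before = global_efficiency(net)
        iu, ju = np.triu_indices(10, k=1)
        absent = np.flatnonzero(net.adjacency[iu, ju] == 0)
        if absent.size == 0:
            pytest.skip("graph complete")
        pick = rng.choice(absent)
        adj = net.adjacency.copy()
        adj[iu[pick], ju[pick]] = adj[ju[pick], iu[pick]] = 1
        assert global_efficiency(net.with_adjacency(adj)) >= before - 1e-12

    def test_spatialnetwork_invariants_enforced(self):
        coords = _coords(3)
        with pytest.raises(ValueError, match="symmetric"):
            SpatialNetwork.from_adjacency(
                np.array([[0, 1, 0], [0, 0, 0], [0, 0, 0]]), coords
            )
        with pytest.raises(ValueError, match="binary"):
            SpatialNetwork.from_adjacency(
                np.array([[0, 2, 2], [2, 0, 0], [2, 0, 0]]), coords
            )
        with pytest.raises(ValueError, match="diagonal"):
            SpatialNetwork.from_adjacency(np.eye(3, dtype=int), coords)
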