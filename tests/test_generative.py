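"""Generative rules, wiring probabilities and the growth process."""

import numpy as np
import pytest

from connectogen import (
    GenerativeParams,
    grow_network,
    topology_value,
    trace_statistics,
    wiring_probabilities,
)
from connectogen.generative import RULES

from conftest import adjacency_from_edges, make_network


class TestTopologyValue:
    def test_empty_adjacency_neighbors_zero(self):
        assert not np.any(topology_value(np.zeros((5, 5), dtype=int), "neighbors"))

    def test_common_neighbors_and_matching_toy(self):
        # nodes 1 and 2 share neighbours {3, 4}; their neighbourhoods match
        adj = adjacency_from_edges(5, [(1, 3), (2, 3), (1, 4), (2, 4)])
        k = topology_value(adj, "neighbors")
        assert k[1, 2] == 2
        m = topology_value(adj, "matching")
        assert m[1, 2] == pytest.approx(1.0)

    def test_degree_difference(self):
        adj = adjacency_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        k = topology_value(adj, "deg-diff")
        assert k[0, 1] == 2  # |3 - 1|

    def test_spatial_is_constant_one(self):
        k = topology_value(adjacency_from_edges(4, [(0, 1)]), "spatial")
        off = k[~np.eye(4, dtype=bool)]
        assert np.all(off == 1)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown rule"):
            topology_value(np.zeros((3, 3), dtype=int), "does-not-exist")

    @pytest.mark.parametrize("rule", RULES)
    def test_symmetric_zero_diagonal(self, rule):
        rng = np.random.default_rng(0)
        adj = np.triu((rng.random((8, 8)) < 0.4), k=1).astype(np.uint8)
        adj |= adj.T
        k = topology_value(adj, rule)
        np.testing.assert_allclose(k, k.T, atol=1e-12)
        assert np.all(np.diag(k) == 0)
        assert np.all(k >= 0)


class TestWiringProbabilities:
    def test_flat_exponents_give_uniform(self):
        adj = adjacency_from_edges(5, [(0, 1)])
        net = make_network(adj)
        p = wiring_probabilities(adj, net.distances,
                                 GenerativeParams("neighbors", 0.0, 0.0))
        eligible = (adj == 0) & ~np.eye(5, dtype=bool)
        n_pairs = eligible.sum() // 2  # each unordered pair appears twice
        np.testing.assert_allclose(p[eligible], 1.0 / n_pairs, atol=1e-15)
        assert p[0, 1] == 0.0

    def test_spatial_hand_normalization(self):
        # distances from node 0: 1, 2, 4; all other pairs already connected
        coords = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 4]], dtype=float
        )
        adj = adjacency_from_edges(4, [(1, 2), (1, 3), (2, 3)])
        net = make_network(adj, coords)
        p = wiring_probabilities(adj, net.distances,
                                 GenerativeParams("spatial", -1.0))
        # scores 1, 1/2, 1/4 -> probabilities 4/7, 2/7, 1/7
        assert p[0, 1] == pytest.approx(4 / 7)
        assert p[0, 2] == pytest.approx(2 / 7)
        assert p[0, 3] == pytest.approx(1 / 7)

    def test_connected_pairs_exactly_zero_and_sum_one(self):
        rng = np.random.default_rng(2)
        adj = np.triu(rng.random((7, 7)) < 0.3, k=1).astype(np.uint8)
        adj |= adj.T
        net = make_network(adj)
        p = wiring_probabilities(adj, net.distances,
                                 GenerativeParams("neighbors", -2.0, 0.5))
        assert np.all(p[adj.astype(bool)] == 0.0)
        assert np.all(np.diag(p) == 0.0)
        np.testing.assert_allclose(p, p.T, atol=1e-15)
        assert np.triu(p, k=1).sum() == pytest.approx(1.0, abs=1e-12)


class TestGrowth:
    @pytest.fixture()
    def seed_net(self, small_cohort):
        return small_cohort.seed_network

    def test_zero_growth_returns_seed(self, seed_net):
        tr = grow_network(seed_net.n_edges, seed_net,
                          GenerativeParams("neighbors", -2.0, 0.3),
                          np.random.default_rng(0))
        assert tr.n_steps == 0
        np.testing.assert_array_equal(tr.network.adjacency, seed_net.adjacency)

    def test_target_and_seed_containment(self, seed_net):
        tr = grow_network(100, seed_net, GenerativeParams("matching", -1.5, 0.4),
                          np.random.default_rng(1))
        assert tr.network.n_edges == 100
        assert np.all(tr.network.adjacency[seed_net.adjacency.astype(bool)] == 1)

    def test_target_below_seed_rejected(self, seed_net):
        with pytest.raises(ValueError, match="below seed"):
            grow_network(seed_net.n_edges - 1, seed_net,
                         GenerativeParams("spatial", -1.0))

    def test_determinism_bit_identical(self, seed_net):
        a = grow_network(80, seed_net, GenerativeParams("neighbors", -2.75, 0.4),
                         np.random.default_rng(42))
        b = grow_network(80, seed_net, GenerativeParams("neighbors", -2.75, 0.4),
                         np.random.default_rng(42))
        np.testing.assert_array_equal(a.added_edges, b.added_edges)
        np.testing.assert_array_equal(a.p_variance, b.p_variance)

    def test_flat_single_step_sampling_uniform(self):
        # eta = gamma = 0: every eligible pair equally likely to win the step
        adj = adjacency_from_edges(5, [(0, 1), (2, 3)])
        net = make_network(adj)
        eligible = [(i, j) for i in range(5) for j in range(i + 1, 5)
                    if not adj[i, j]]
        rng = np.random.default_rng(3)
        counts = {e: 0 for e in eligible}
        n_rep = 8000
        for _ in range(n_rep):
            tr = grow_network(3, net, GenerativeParams("neighbors", 0.0, 0.0),
                              rng, record_p_summaries=False)
            counts[tuple(tr.added_edges[0])] += 1
        freqs = np.array([counts[e] / n_rep for e in eligible])
        np.testing.assert_allclose(freqs, 1 / len(eligible), atol=0.02)

    @pytest.mark.parametrize("rule", ["neighbors", "clu-avg", "deg-prod"])
    def test_probabilities_valid_at_every_step(self, seed_net, rule):
        tr = grow_network(60, seed_net, GenerativeParams(rule, -2.0, 0.5),
                          np.random.default_rng(0), record_p_matrices=True)
        seed_adj = seed_net.adjacency.astype(bool)
        connected = seed_adj.copy()
        for t in range(tr.n_steps):
            p = tr.p_matrices[t]
            assert p[np.eye(p.shape[0], dtype=bool)].max() == 0.0
            assert p[connected].max() == 0.0
            assert np.all(p >= 0)
            # matrix stores both (i,j) and (j,i): eligible mass sums to 2
            assert p.sum() == pytest.approx(2.0, abs=1e-9)
            i, j = tr.added_edges[t]
            connected[i, j] = connected[j, i] = True


class TestTraceStatistics:
    def test_uniform_probabilities_zero_variance(self):
        net = make_network(adjacency_from_edges(6, [(0, 1)]))
        tr = grow_network(4, net, GenerativeParams("neighbors", 0.0, 0.0),
                          np.random.default_rng(0))
        np.testing.assert_allclose(tr.p_variance, 0.0, atol=1e-20)

    def test_two_value_hand_variance(self):
        # distribution {0.75, 0.25}: variance 0.0625
        p = np.array([0.75, 0.25])
        assert p.var() == pytest.approx(0.0625)
        # realized inside a trace: 3 nodes, one existing edge, eta=-1 with
        # distances engineered so that scores are 3:1
        coords = np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0.0]])
        adj = adjacency_from_edges(3, [(0, 1)])
        net = make_network(adj, coords)
        tr = grow_network(2, net, GenerativeParams("spatial", -1.0),
                          np.random.default_rng(0))
        # pair (0,2): d=3 -> 1/3; pair (1,2): d=2 -> 1/2; P = {2/5, 3/5}
        expected = np.array([2 / 5, 3 / 5]).var()
        assert tr.p_variance[0] == pytest.approx(expected, abs=1e-12)

    def test_trajectories_rescaled_to_100_points(self, small_cohort):
        seed_net = small_cohort.seed_network
        tr = grow_network(50, seed_net, GenerativeParams("neighbors", -2.0, 0.3),
                          np.random.default_rng(0), record_trajectories=True)
        st = trace_statistics(tr)
        assert st.efficiency_trajectory.shape == (100,)
        assert st.modularity_trajectory.shape == (100,)
        assert st.p_variance_scaled.shape == (100,)

    def test_efficiency_trajectory_non_decreasing(self, small_cohort):
        seed_net = small_cohort.seed_network
        tr = grow_network(60, seed_net, GenerativeParams("neighbors", -2.5, 0.4),
                          np.random.default_rng(1), record_trajectories=True)
        diffs = np.diff(tr.efficiency_trajectory)
        assert np.all(diffs >= -1e-12)

    def test_summaries_required(self, small_cohort):
        seed_net = small_cohort.seed_network
        tr = grow_network(40, seed_net, GenerativeParams("neighbors", -2.0, 0.3),
                          np.random.default_rng(0), record_p_summaries=False)
        with pytest.raises(ValueError):
            trace_statistics(tr)


def test_flat_growth_matches_uniform_oracle(small_cohort):
    """With eta = gamma = 0 the process is a uniform random graph process
    conditioned on the seed: edge-presence frequencies match the
    hypergeometric expectation."""
    seed_net = small_cohort.seed_network
    n = seed_net.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    eligible = seed_net.adjacency[iu, ju] == 0
    target = seed_net.n_edges + 30
    rng = np.random.default_rng(9)
    hits = np.zeros(iu.size)
    n_rep = 400
    for _ in range(n_rep):
        tr = grow_network(target, seed_net, GenerativeParams("spatial", 0.0),
                          rng, record_p_summaries=False)
        hits += tr.network.adjacency[iu, ju]
    freq = hits[eligible] / n_rep
    expect = 30 / eligible.sum()  # uniform choice of 30 of the eligible pairs
    assert abs(freq.mean() - expect) < 1e-9  # mass conservation
    assert freq.std() < 4 * np.sqrt(expect * (1 - expect) / n_rep)
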