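import numpy as np
import pytest

from connectogen import (
    GroupParams,
    SpatialNetwork,
    desk_spec,
    synthesize_cohort,
    synthesize_layout,
)


def make_network(adj, coords=None, rng_seed=0):
    """SpatialNetwork from an adjacency matrix, with random coordinates if
    none are given."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    if coords is None:
        rng = np.random.default_rng(rng_seed)
        coords = rng.normal(size=(n, 3)) * 3.0
    return SpatialNetwork.from_adjacency(adj, coords)


def adjacency_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return adj


def random_network(n, p_edge, rng, ensure_edge=True):
    """Erdős–Rényi spatial network on random coordinates."""
    while True:
        upper = rng.random((n, n)) < p_edge
        adj = np.triu(upper, k=1).astype(np.uint8)
        adj |= adj.T
        if not ensure_edge or adj.sum() > 0:
            break
    coords = rng.normal(size=(n, 3)) * 3.0
    return SpatialNetwork.from_adjacency(adj, coords)


@pytest.fixture(scope="session")
def layout60():
    return synthesize_layout(60, bilateral=True, rng=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4 + 4 desk-scale cohort, shared across read-only tests."""
    spec = desk_spec(
        groups=(
            GroupParams("control", 4, -2.76, 0.40),
            GroupParams("stress", 4, -2.60, 0.38),
        ),
        seed=5,
    )
    return synthesize_cohort(spec)
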