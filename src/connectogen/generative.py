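"""Economic generative growth of binary spatial networks.

A network grows from a sparse seed by adding one edge per step. The
probability of wiring two unconnected regions i and j trades off a wiring
cost against a topological value:

    P_ij ∝ (D_ij)^η · (K_ij)^γ

where D_ij is the Euclidean distance between the regions (η ≤ 0 penalizes
long connections) and K_ij is a rule-dependent topological score (γ ≥ 0
favours topologically valuable pairs). K — and therefore P — is recomputed
after every addition, so wiring preferences shift dynamically as topology
emerges. Growth stops when the simulated network reaches the observed edge
count.

Thirteen generative rules are supported: a purely spatial model (K ≡ 1),
two homophily rules (common-neighbour count and matching index), and five
clustering-based plus five degree-based rules (average / min / max /
absolute difference / product of the two nodes' clustering coefficients or
degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import (
    SpatialNetwork,
    clustering_coefficients,
    global_efficiency,
    matching_index_matrix,
    max_modularity,
)

__all__ = [
    "RULES",
    "HOMOPHILY_RULES",
    "RULE_FAMILIES",
    "GenerativeParams",
    "GenerativeTrace",
    "topology_value",
    "wiring_probabilities",
    "grow_network",
    "trace_statistics",
    "TraceStatistics",
]

RULES = (
    "spatial",
    "neighbors",
    "matching",
    "clu-avg",
    "clu-min",
    "clu-max",
    "clu-diff",
    "clu-prod",
    "deg-avg",
    "deg-min",
    "deg-max",
    "deg-diff",
    "deg-prod",
)

HOMOPHILY_RULES = ("neighbors", "matching")

RULE_FAMILIES = {
    "spatial": "spatial",
    "neighbors": "homophily",
    "matching": "homophily",
    "clu-avg": "clustering",
    "clu-min": "clustering",
    "clu-max": "clustering",
    "clu-diff": "clustering",
    "clu-prod": "clustering",
    "deg-avg": "degree",
    "deg-min": "degree",
    "deg-max": "degree",
    "deg-diff": "degree",
    "deg-prod": "degree",
}

#: Regularization added to K before exponentiation so that zero-value pairs
#: (e.g. no common neighbours early in growth) retain nonzero probability.
DEFAULT_EPSILON = 1e-5

#: Histogram bins for per-step wiring-probability summaries. Probabilities
#: are binned on the relative scale p · m (m = eligible pairs), i.e. as
#: multiples of the uniform probability, so summaries are comparable across
#: steps and network sizes. Range [0, 20] in 200 bins, last bin open.
P_HIST_BINS = np.linspace(0.0, 20.0, 201)


@dataclass(frozen=True)
class GenerativeParams:
    """A generative rule with its cost exponent η (≤ 0) and value exponent γ (≥ 0)."""

    rule: str
    eta: float
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; valid: {RULES}")
        if self.eta > 0:
            raise ValueError("eta must be <= 0 (distance is penalized)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    def scaled(self, fraction: float) -> "GenerativeParams":
        """Parameters scaled toward the origin: (f·η, f·γ)."""
        return GenerativeParams(self.rule, fraction * self.eta, fraction * self.gamma)

    def origin_distance(self) -> float:
        """Distance √(η² + γ²) from the origin of the parameter space."""
        return float(np.hypot(self.eta, self.gamma))


def _pairwise(stat: np.ndarray, how: str) -> np.ndarray:
    s_i = stat[:, None]
    s_j = stat[None, :]
    if how == "avg":
        return (s_i + s_j) / 2.0
    if how == "min":
        return np.minimum(s_i, s_j)
    if how == "max":
        return np.maximum(s_i, s_j)
    if how == "diff":
        return np.abs(s_i - s_j)
    if how == "prod":
        return s_i * s_j
    raise ValueError(how)


def topology_value(adjacency: np.ndarray, rule: str) -> np.ndarray:
    """Topological value matrix K for the given rule (zero diagonal).

    ``spatial`` returns all-ones (the value factor is identically 1);
    ``neighbors`` counts common neighbours; ``matching`` is the normalized
    neighbourhood overlap; ``clu-*`` / ``deg-*`` apply a symmetric functional
    to the two nodes' clustering coefficients / degrees.
    """
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    if rule == "spatial":
        k = np.ones((n, n))
    elif rule == "neighbors":
        k = a @ a
    elif rule == "matching":
        k = matching_index_matrix(adjacency)
    elif rule.startswith("clu-"):
        k = _pairwise(clustering_coefficients(adjacency), rule[4:])
    elif rule.startswith("deg-"):
        k = _pairwise(a.sum(axis=1), rule[4:])
    else:
        raise ValueError(f"unknown rule {rule!r}")
    np.fill_diagonal(k, 0.0)
    return k


def wiring_probabilities(
    adjacency: np.ndarray,
    distances: np.ndarray,
    params: GenerativeParams,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Normalized wiring probability matrix P for the current state.

    Raw score (D_ij)^η · (K_ij + ε)^γ on every unconnected off-diagonal
    pair; connected pairs and the diagonal are exactly 0. Entry (i, j)
    holds the probability that the unordered pair {i, j} wins the next
    step, so the matrix is symmetric and its distinct (upper-triangle)
    eligible entries sum to 1. The spatial rule uses a value factor of
    exactly 1; exponents of 0 disable a factor entirely (0⁰ := 1).
    """
    a = np.asarray(adjacency)
    n = a.shape[0]
    eligible = ~(a.astype(bool)) & ~np.eye(n, dtype=bool)
    d = np.asarray(distances, dtype=float)
    if np.any(d[eligible] <= 0):
        raise ValueError("distances must be strictly positive off-diagonal")
    score = np.ones((n, n))
    if params.eta != 0.0:
        with np.errstate(divide="ignore"):  # diagonal zeros are masked below
            score = d**params.eta
    if params.rule != "spatial" and params.gamma != 0.0:
        k = topology_value(a, params.rule)
        score = score * (k + epsilon) ** params.gamma
    score = np.where(eligible, score, 0.0)
    total = np.triu(score, k=1).sum()
    if total <= 0:
        raise ValueError("all wiring scores are zero; cannot normalize")
    return score / total


@dataclass
class GenerativeTrace:
    """Record of one generative growth run.

    ``added_edges`` lists the (i, j) pairs in addition order. Per-step
    summaries (variance of the eligible-pair probabilities and a fixed-bin
    histogram on the relative scale p·m) are always recorded; full P
    matrices and efficiency/modularity trajectories are opt-in.
    """

    params: GenerativeParams
    seed_edges: np.ndarray
    added_edges: np.ndarray
    network: SpatialNetwork
    p_variance: np.ndarray  # variance of eligible P at each growth step
    p_histograms: np.ndarray  # (steps, len(P_HIST_BINS)-1) counts, relative scale
    efficiency_trajectory: np.ndarray | None = None
    modularity_trajectory: np.ndarray | None = None
    p_matrices: np.ndarray | None = None  # (steps, n, n), opt-in

    @property
    def n_steps(self) -> int:
        return len(self.added_edges)

    def export_edges(self, path: str | Path) -> None:
        df = pd.DataFrame(self.added_edges, columns=["node_i", "node_j"])
        df.insert(0, "step", np.arange(1, len(df) + 1))
        df.to_csv(path, index=False)


def grow_network(
    target_edges: int,
    seed: SpatialNetwork,
    params: GenerativeParams,
    rng: np.random.Generator | None = None,
    epsilon: float = DEFAULT_EPSILON,
    record_p_summaries: bool = True,
    record_trajectories: bool = False,
    record_p_matrices: bool = False,
    trajectory_modularity_restarts: int = 3,
) -> GenerativeTrace:
    """Grow a network from ``seed`` to exactly ``target_edges`` edges.

    One edge is added per step by categorical sampling over the normalized
    wiring probabilities, which are recomputed after every addition.
    Deterministic given ``rng`` state and inputs (the edge sequence does not
    depend on which summaries are recorded).

    ``record_p_summaries=False`` skips the per-step variance/histogram
    bookkeeping; grid searches use this, since they only need the final
    network.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = seed.n_nodes
    e_seed = seed.n_edges
    if target_edges < e_seed:
        raise ValueError(f"target ({target_edges}) below seed edge count ({e_seed})")
    n_pairs = n * (n - 1) // 2
    if target_edges > n_pairs:
        raise ValueError("target exceeds the number of distinct node pairs")

    adj = seed.adjacency.astype(np.uint8).copy()
    d = seed.distances
    iu, ju = np.triu_indices(n, k=1)
    dpow = np.ones(iu.size) if params.eta == 0.0 else d[iu, ju] ** params.eta
    connected = adj[iu, ju].astype(bool)
    use_k = params.rule != "spatial" and params.gamma != 0.0

    n_steps = target_edges - e_seed
    added = np.zeros((n_steps, 2), dtype=int)
    n_sum = n_steps if record_p_summaries else 0
    p_var = np.zeros(n_sum)
    p_hist = np.zeros((n_sum, P_HIST_BINS.size - 1))
    hist_scale = (P_HIST_BINS.size - 1) / P_HIST_BINS[-1]
    p_mats = np.zeros((n_steps, n, n)) if record_p_matrices else None
    eff_traj = [] if record_trajectories else None
    q_traj = [] if record_trajectories else None

    for t in range(n_steps):
        if use_k:
            k = topology_value(adj, params.rule)[iu, ju]
            raw = dpow * (k + epsilon) ** params.gamma
        else:
            raw = dpow.copy()
        raw[connected] = 0.0
        total = raw.sum()
        if total <= 0:
            raise ValueError("all wiring scores are zero; cannot normalize")
        p = raw / total
        if record_p_summaries:
            m_elig = int((~connected).sum())
            pe = p[~connected]
            p_var[t] = pe.var()
            rel = np.minimum(pe * m_elig, P_HIST_BINS[-1])
            idx_bins = np.minimum((rel * hist_scale).astype(np.intp),
                                  P_HIST_BINS.size - 2)
            p_hist[t] = np.bincount(idx_bins, minlength=P_HIST_BINS.size - 1)
        if record_p_matrices:
            mat = np.zeros((n, n))
            mat[iu, ju] = p
            p_mats[t] = mat + mat.T
        # categorical draw over pairs
        idx = int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))
        idx = min(idx, p.size - 1)
        i, j = int(iu[idx]), int(ju[idx])
        adj[i, j] = adj[j, i] = 1
        connected[idx] = True
        added[t] = (i, j)
        if record_trajectories:
            net_t = seed.with_adjacency(adj.copy())
            eff_traj.append(global_efficiency(net_t))
            q_traj.append(
                max_modularity(net_t, n_restarts=trajectory_modularity_restarts)
            )

    return GenerativeTrace(
        params=params,
        seed_edges=seed.edge_list(),
        added_edges=added,
        network=seed.with_adjacency(adj),
        p_variance=p_var,
        p_histograms=p_hist,
        efficiency_trajectory=np.asarray(eff_traj) if record_trajectories else None,
        modularity_trajectory=np.asarray(q_traj) if record_trajectories else None,
        p_matrices=p_mats,
    )


def _rescale_to(y: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Linear interpolation of a series onto ``n_points`` equal fractions of
    developmental time."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty trajectory")
    if y.size == 1:
        return np.full(n_points, y[0])
    x = np.linspace(0.0, 1.0, y.size)
    return np.interp(np.linspace(0.0, 1.0, n_points), x, y)


@dataclass
class TraceStatistics:
    """Summaries of one trace over developmental time."""

    p_variance: np.ndarray  # raw per-step variance of eligible P
    p_variance_scaled: np.ndarray  # rescaled to 100 time points
    p_distribution: np.ndarray  # step-averaged histogram (density over bins)
    p_bin_centers: np.ndarray
    efficiency_trajectory: np.ndarray | None  # length 100
    modularity_trajectory: np.ndarray | None  # length 100


def trace_statistics(trace: GenerativeTrace, n_points: int = 100) -> TraceStatistics:
    """Per-step probability summaries and trajectories rescaled to 100 steps.

    The wiring-probability value distribution is the average over growth
    steps of the eligible-pair histogram (probabilities on the relative
    scale p·m, multiples of uniform). Trajectories, when recorded, are
    linearly interpolated onto ``n_points`` equal fractions of developmental
    time.
    """
    if trace.n_steps == 0:
        raise ValueError("trace has no growth steps to summarize")
    if trace.p_histograms.shape[0] == 0:
        raise ValueError(
            "trace was recorded with record_p_summaries=False; re-run the "
            "growth with summaries enabled"
        )
    hists = trace.p_histograms
    densities = hists / hists.sum(axis=1, keepdims=True)
    pooled = densities.mean(axis=0)
    centers = (P_HIST_BINS[:-1] + P_HIST_BINS[1:]) / 2.0
    eff = (
        _rescale_to(trace.efficiency_trajectory, n_points)
        if trace.efficiency_trajectory is not None
        else None
    )
    mod = (
        _rescale_to(trace.modularity_trajectory, n_points)
        if trace.modularity_trajectory is not None
        else None
    )
    return TraceStatistics(
        p_variance=trace.p_variance.copy(),
        p_variance_scaled=_rescale_to(trace.p_variance, n_points),
        p_distribution=pooled,
        p_bin_centers=centers,
        efficiency_trajectory=eff,
        modularity_trajectory=mod,
    )
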