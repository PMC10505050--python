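"""Core connectome containers, file I/O, thresholding and graph metrics.

The package represents a structural connectome at two levels:

* :class:`WeightedConnectome` — the raw symmetrized streamline-count (or
  otherwise weighted) region-by-region matrix together with 3D region
  coordinates.
* :class:`SpatialNetwork` — the binary graph obtained by thresholding,
  carrying the Euclidean distance matrix derived from the coordinates.
  Every downstream computation (generative growth, energy, fingerprints,
  group statistics) operates on this type.

Nodal and global topology measures follow the conventions of the Brain
Connectivity Toolbox for binary undirected graphs: betweenness is the raw
(unnormalized) Brandes count, clustering is the triangle density around a
node, local efficiency of a node is the global efficiency of the subgraph
induced by its neighbours, and unreachable node pairs contribute zero
inverse path length ("efficiency convention").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "WeightedConnectome",
    "SpatialNetwork",
    "NodalProfile",
    "GlobalProfile",
    "load_connectome",
    "save_connectome",
    "threshold_binarize",
    "nodal_metrics",
    "global_metrics",
    "degree_preserving_null",
    "random_wired_ensemble",
    "matching_index_matrix",
    "euclidean_distances",
    "NODAL_MEASURES",
]

#: Canonical ordering of the six nodal measures used by topological
#: fingerprints and spatial-layout analyses.
NODAL_MEASURES = (
    "degree",
    "clustering",
    "betweenness",
    "edge_length",
    "local_efficiency",
    "matching",
)


def euclidean_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix for an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _default_labels(n: int) -> list[str]:
    return [f"region_{i}" for i in range(n)]


@dataclass
class WeightedConnectome:
    """Symmetric nonnegative weighted connectivity matrix with coordinates.

    Parameters
    ----------
    weights : (n, n) array of nonnegative reals, symmetric, zero diagonal.
    labels : region identifiers, one per row.
    coords : (n, 3) spatial positions of region centroids.
    """

    weights: np.ndarray
    labels: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape[1] != n:
            raise ValueError("weight matrix must be square")
        if len(self.labels) != n:
            raise ValueError("label count does not match matrix size")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n, 3)")
        if np.any(self.weights < 0):
            raise ValueError("negative weights are not allowed")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero (self-connections removed)")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class SpatialNetwork:
    """Binary symmetric graph embedded in space.

    ``distances`` is always recomputed from ``coords`` so that the Euclidean
    invariant cannot be violated by inconsistent input files.
    """

    adjacency: np.ndarray
    labels: list[str]
    coords: np.ndarray
    distances: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        vals = np.unique(adj)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = adj.astype(np.uint8)
        self.coords = np.asarray(self.coords, dtype=float)
        n = adj.shape[0]
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n, 3)")
        if len(self.labels) != n:
            raise ValueError("label count does not match adjacency size")
        self.distances = euclidean_distances(self.coords)
        off = self.distances[~np.eye(n, dtype=bool)]
        if n > 1 and np.any(off <= 0):
            raise ValueError("coincident region coordinates (zero distance)")

    @classmethod
    def from_adjacency(
        cls,
        adjacency: np.ndarray,
        coords: np.ndarray,
        labels: Sequence[str] | None = None,
    ) -> "SpatialNetwork":
        n = np.asarray(adjacency).shape[0]
        return cls(adjacency, list(labels) if labels else _default_labels(n), coords)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_list(self) -> np.ndarray:
        """(e, 2) array of node-index pairs (i < j) for present edges."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu, ju] > 0
        return np.column_stack([iu[mask], ju[mask]])

    def edge_lengths(self) -> np.ndarray:
        """Euclidean lengths of the realized edges."""
        edges = self.edge_list()
        return self.distances[edges[:, 0], edges[:, 1]]

    def to_igraph(self) -> ig.Graph:
        return ig.Graph(self.n_nodes, [tuple(e) for e in self.edge_list()])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edge_list()))
        return g

    def with_adjacency(self, adjacency: np.ndarray) -> "SpatialNetwork":
        """New network on the same layout with a different edge set."""
        return SpatialNetwork(adjacency, self.labels, self.coords)


@dataclass
class NodalProfile:
    """Per-node topology vectors (all length n, canonical measure order)."""

    degree: np.ndarray
    clustering: np.ndarray
    betweenness: np.ndarray
    edge_length: np.ndarray
    local_efficiency: np.ndarray
    matching: np.ndarray

    def as_matrix(self) -> np.ndarray:
        """(n, 6) matrix of the measures in canonical order."""
        return np.column_stack([getattr(self, m) for m in NODAL_MEASURES])

    def as_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.as_matrix(), columns=list(NODAL_MEASURES))
        if labels is not None:
            df.index = list(labels)
        return df


@dataclass
class GlobalProfile:
    """Whole-network summary statistics."""

    n_edges: int
    total_edge_length: float
    n_long_distance: int
    global_efficiency: float
    small_worldness: float
    modularity: float
    connected: bool

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "n_edges": self.n_edges,
                "total_edge_length": self.total_edge_length,
                "n_long_distance": self.n_long_distance,
                "global_efficiency": self.global_efficiency,
                "small_worldness": self.small_worldness,
                "modularity": self.modularity,
                "connected": self.connected,
            }
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a square numeric CSV/TSV, with an optional header row of labels."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = first.iloc[0].apply(
        lambda v: isinstance(v, str) and not v.replace(".", "", 1).lstrip("-").isdigit()
    ).any()
    if has_header:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        labels = [str(c) for c in df.columns]
    else:
        df = pd.read_csv(path, sep=sep, header=None, float_precision="round_trip")
        labels = None
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"matrix in {path} is not square: {mat.shape}")
    return mat, labels


def _read_coords(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    missing = {"label", "x", "y", "z"} - set(cols)
    if missing:
        raise ValueError(f"coordinate file missing columns: {sorted(missing)}")
    labels = [str(v) for v in df[cols["label"]]]
    coords = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
    return labels, coords


def load_connectome(path: str | Path, coords_path: str | Path) -> WeightedConnectome:
    """Load a weighted connectivity matrix plus region coordinates.

    The matrix is symmetrized by the elementwise maximum of itself and its
    transpose, and self-connections (the diagonal) are removed.
    """
    mat, mat_labels = _read_matrix(path)
    labels, coords = _read_coords(coords_path)
    if len(labels) != mat.shape[0]:
        raise ValueError(
            f"coordinate file has {len(labels)} regions, matrix has {mat.shape[0]}"
        )
    if mat_labels is not None and mat_labels != labels:
        raise ValueError("labels differ between matrix header and coordinate file")
    if np.any(mat < 0):
        raise ValueError("negative weights in connectivity matrix")
    sym = np.maximum(mat, mat.T)
    np.fill_diagonal(sym, 0.0)
    return WeightedConnectome(sym, labels, coords)


def save_connectome(
    wc: WeightedConnectome, path: str | Path, coords_path: str | Path
) -> None:
    """Write the matrix (with label header) and coordinate table as CSV."""
    fmt = "%.17g"  # full double precision so round trips are bit-exact
    pd.DataFrame(wc.weights, columns=wc.labels).to_csv(
        path, index=False, float_format=fmt
    )
    pd.DataFrame(
        {
            "label": wc.labels,
            "x": wc.coords[:, 0],
            "y": wc.coords[:, 1],
            "z": wc.coords[:, 2],
        }
    ).to_csv(coords_path, index=False, float_format=fmt)


def threshold_binarize(wc: WeightedConnectome, threshold: float) -> SpatialNetwork:
    """Binarize a weighted connectome: edge iff weight strictly above threshold.

    The study design motivating this package applied a streamline-count
    threshold (6100) to reach a sparse density; here the threshold is a plain
    parameter.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    adj = (wc.weights > threshold).astype(np.uint8)
    return SpatialNetwork(adj, wc.labels, wc.coords)


# ---------------------------------------------------------------------------
# Nodal metrics
# ---------------------------------------------------------------------------

def clustering_coefficients(adjacency: np.ndarray) -> np.ndarray:
    """Binary clustering coefficient per node; 0 for degree < 2."""
    a = adjacency.astype(float)
    k = a.sum(axis=1)
    # triangles through i = (A^3)_ii / 2, computed without forming A^3
    tri = ((a @ a) * a).sum(axis=1) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def matching_index_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Matching index M_ij = |N(i) ∩ N(j)| / |N(i) ∪ N(j)|, i and j excluded
    from both neighbourhoods; 0 where the union is empty. Zero diagonal."""
    a = adjacency.astype(float)
    k = a.sum(axis=1)
    common = a @ a  # A_ii = 0, so i/j never count as common neighbours
    union = k[:, None] + k[None, :] - 2.0 * a - common
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(union > 0, common / union, 0.0)
    np.fill_diagonal(m, 0.0)
    return m


def _betweenness(net: SpatialNetwork) -> np.ndarray:
    """Unnormalized betweenness centrality (undirected pair counted once)."""
    if net.n_edges == 0:
        return np.zeros(net.n_nodes)
    return np.asarray(net.to_igraph().betweenness(), dtype=float)


def _subgraph_efficiency(g: ig.Graph) -> float:
    """Mean inverse shortest-path length over ordered pairs, 0 if < 2 nodes."""
    n = g.vcount()
    if n < 2:
        return 0.0
    sp = np.asarray(g.distances(), dtype=float)
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency_vector(net: SpatialNetwork) -> np.ndarray:
    """Local efficiency: global efficiency of each node's neighbour subgraph."""
    g = net.to_igraph()
    out = np.zeros(net.n_nodes)
    adj = net.adjacency
    for i in range(net.n_nodes):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        out[i] = _subgraph_efficiency(g.induced_subgraph([int(v) for v in nbrs]))
    return out


def nodal_metrics(net: SpatialNetwork) -> NodalProfile:
    """Compute the six nodal measures on the binary graph.

    Isolated and degree-1 nodes receive clustering and local efficiency 0.
    Total incident edge length sums the Euclidean lengths of a node's edges.
    """
    a = net.adjacency.astype(float)
    return NodalProfile(
        degree=a.sum(axis=1),
        clustering=clustering_coefficients(net.adjacency),
        betweenness=_betweenness(net),
        edge_length=(a * net.distances).sum(axis=1),
        local_efficiency=local_efficiency_vector(net),
        matching=matching_index_matrix(net.adjacency).sum(axis=1)
        / max(net.n_nodes - 1, 1),
    )


# ---------------------------------------------------------------------------
# Global metrics
# ---------------------------------------------------------------------------

def global_efficiency(net: SpatialNetwork) -> float:
    """Average inverse shortest path length (unreachable pairs contribute 0)."""
    return _subgraph_efficiency(net.to_igraph())


def characteristic_path_length(net: SpatialNetwork) -> tuple[float, bool]:
    """(L, connected). For disconnected graphs L is the inverse of global
    efficiency (harmonic-mean convention), keeping σ defined."""
    g = net.to_igraph()
    sp = np.asarray(g.distances(), dtype=float)
    n = net.n_nodes
    off = sp[~np.eye(n, dtype=bool)]
    connected = bool(np.all(np.isfinite(off))) if n > 1 else True
    if connected:
        return float(off.mean()), True
    eff = _subgraph_efficiency(g)
    return (np.inf if eff == 0 else 1.0 / eff), False


def max_modularity(
    net: SpatialNetwork, n_restarts: int = 10, seed: int = 0
) -> float:
    """Maximum modularity Q via Louvain optimization, best of ``n_restarts``."""
    g = net.to_networkx()
    if net.n_edges == 0:
        return 0.0
    best = -np.inf
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(g, seed=seed + r)
        q = nx.community.modularity(g, comms)
        best = max(best, q)
    return float(best)


def long_distance_count(
    net: SpatialNetwork,
    long_dist_sd: float = 2.0,
    reference_lengths: np.ndarray | None = None,
) -> int:
    """Edges longer than mean + ``long_dist_sd``·SD of the reference lengths.

    By default the reference set is the network's own edge lengths; for
    cohort comparisons pass the pooled edge lengths of all subjects.
    """
    lengths = net.edge_lengths()
    ref = lengths if reference_lengths is None else np.asarray(reference_lengths)
    if ref.size == 0:
        return 0
    cut = ref.mean() + long_dist_sd * ref.std(ddof=0)
    return int(np.sum(lengths > cut))


def degree_preserving_null(
    net: SpatialNetwork,
    n: int = 500,
    rng: np.random.Generator | None = None,
) -> list[SpatialNetwork]:
    """Ensemble of degree-preserving rewirings (double-edge swaps).

    Each member attempts 10·|E| swaps; failed graphs (too rigid to swap)
    fall back to fewer swaps with a warning.
    """
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng() if rng is None else rng
    g0 = net.to_networkx()
    nswap = 10 * net.n_edges
    out = []
    for _ in range(n):
        g = g0.copy()
        try:
            nx.double_edge_swap(
                g, nswap=nswap, max_tries=100 * nswap,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXAlgorithmError:
            warnings.warn("rewiring stalled before reaching the requested swaps")
        adj = np.zeros_like(net.adjacency)
        for u, v in g.edges():
            adj[u, v] = adj[v, u] = 1
        out.append(net.with_adjacency(adj))
    return out


def random_wired_ensemble(
    net: SpatialNetwork,
    n: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[SpatialNetwork]:
    """Uniformly random graphs with the same nodes, coordinates and edge count."""
    rng = np.random.default_rng() if rng is None else rng
    nn = net.n_nodes
    iu, ju = np.triu_indices(nn, k=1)
    n_pairs = iu.size
    e = net.n_edges
    if e > n_pairs:
        raise ValueError("edge count exceeds the number of distinct pairs")
    out = []
    for _ in range(n):
        chosen = rng.choice(n_pairs, size=e, replace=False)
        adj = np.zeros((nn, nn), dtype=np.uint8)
        adj[iu[chosen], ju[chosen]] = 1
        adj |= adj.T
        out.append(net.with_adjacency(adj))
    return out


def global_metrics(
    net: SpatialNetwork,
    long_dist_sd: float = 2.0,
    n_null: int = 500,
    rng: np.random.Generator | None = None,
    reference_lengths: np.ndarray | None = None,
    modularity_restarts: int = 10,
) -> GlobalProfile:
    """Whole-network profile: edges, wiring length, long-distance edges,
    global efficiency, small-worldness σ and maximum modularity Q.

    σ = (C / C_rand) / (L / L_rand) against a degree-preserving null ensemble
    of size ``n_null``. Disconnected networks use the efficiency convention
    for path length and are flagged via ``connected=False``.
    """
    rng = np.random.default_rng() if rng is None else rng
    if net.n_edges == 0:
        raise ValueError("global metrics require a non-empty network")
    lengths = net.edge_lengths()
    c_obs = float(clustering_coefficients(net.adjacency).mean())
    l_obs, connected = characteristic_path_length(net)
    c_rand, l_rand = [], []
    for null in degree_preserving_null(net, n=n_null, rng=rng):
        c_rand.append(clustering_coefficients(null.adjacency).mean())
        l_rand.append(characteristic_path_length(null)[0])
    c_rand_m = float(np.mean(c_rand))
    l_rand_m = float(np.mean(l_rand))
    if c_rand_m > 0 and l_rand_m > 0 and np.isfinite(l_obs) and l_obs > 0:
        sigma = (c_obs / c_rand_m) / (l_obs / l_rand_m)
    else:
        sigma = np.nan
    return GlobalProfile(
        n_edges=net.n_edges,
        total_edge_length=float(lengths.sum()),
        n_long_distance=long_distance_count(net, long_dist_sd, reference_lengths),
        global_efficiency=global_efficiency(net),
        small_worldness=float(sigma),
        modularity=max_modularity(net, n_restarts=modularity_restarts),
        connected=connected,
    )
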