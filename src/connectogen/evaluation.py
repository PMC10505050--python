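"""Model-fit metrics: KS energy, topological fingerprints, edge overlap and
spatial layout error.

The fit of a simulated network to an observed connectome is summarized by
the energy

    E = max(KS_k, KS_c, KS_b, KS_d)

the maximum of four two-sample Kolmogorov–Smirnov statistics comparing the
distributions of node degree (k), nodal clustering (c), nodal betweenness
(b) and realized edge length (d). Lower energy means a closer match of the
topological distributions.

A topological fingerprint (TF) is the 6×6 Pearson correlation matrix among
six nodal measures (degree, clustering, betweenness, total incident edge
length, local efficiency, mean matching index); ΔTF, the Frobenius norm of
the difference between two TFs, quantifies how far apart two networks (or
cohorts) are in their local organisational structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import NODAL_MEASURES, NodalProfile, SpatialNetwork, nodal_metrics

__all__ = [
    "EnergyResult",
    "TFMatrix",
    "SpatialErrorMap",
    "ks_statistic",
    "model_energy",
    "energy_from_profiles",
    "topological_fingerprint",
    "delta_tf",
    "edge_overlap",
    "spatial_error",
]


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sample KS statistic: sup |F_x − F_y| over the pooled support."""
    x = np.sort(np.asarray(x, dtype=float).ravel())
    y = np.sort(np.asarray(y, dtype=float).ravel())
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_statistic requires non-empty samples")
    support = np.concatenate([x, y])
    fx = np.searchsorted(x, support, side="right") / x.size
    fy = np.searchsorted(y, support, side="right") / y.size
    return float(np.max(np.abs(fx - fy)))


@dataclass(frozen=True)
class EnergyResult:
    """The four KS components and their maximum E (all in [0, 1])."""

    ks_degree: float
    ks_clustering: float
    ks_betweenness: float
    ks_edge_length: float

    @property
    def energy(self) -> float:
        return max(
            self.ks_degree,
            self.ks_clustering,
            self.ks_betweenness,
            self.ks_edge_length,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "ks_k": self.ks_degree,
            "ks_c": self.ks_clustering,
            "ks_b": self.ks_betweenness,
            "ks_d": self.ks_edge_length,
            "energy": self.energy,
        }


def _energy_vectors(net: SpatialNetwork, profile: NodalProfile | None = None):
    """The four distributions entering the energy: k, c, b per node and the
    lengths of realized edges. Only these are computed (grid searches call
    this tens of thousands of times)."""
    if profile is not None:
        return profile.degree, profile.clustering, profile.betweenness, net.edge_lengths()
    from .network import _betweenness, clustering_coefficients

    a = net.adjacency.astype(float)
    return (
        a.sum(axis=1),
        clustering_coefficients(net.adjacency),
        _betweenness(net),
        net.edge_lengths(),
    )


def energy_from_profiles(
    sim: SpatialNetwork,
    obs_vectors: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    sim_profile: NodalProfile | None = None,
) -> EnergyResult:
    """Energy against precomputed observed-side distributions.

    Used by grid searches, where the observed connectome's metric vectors
    are fixed across thousands of evaluations.
    """
    sk, sc, sb, sd = _energy_vectors(sim, sim_profile)
    ok, oc, ob, od = obs_vectors
    if sk.size != ok.size:
        raise ValueError("node-count mismatch between simulation and observation")
    if sd.size == 0 or od.size == 0:
        raise ValueError("energy requires both networks to have edges")
    return EnergyResult(
        ks_degree=ks_statistic(sk, ok),
        ks_clustering=ks_statistic(sc, oc),
        ks_betweenness=ks_statistic(sb, ob),
        ks_edge_length=ks_statistic(sd, od),
    )


def model_energy(sim: SpatialNetwork, obs: SpatialNetwork) -> EnergyResult:
    """KS energy between a simulated and an observed network."""
    if sim.n_nodes != obs.n_nodes:
        raise ValueError("node-count mismatch between simulation and observation")
    return energy_from_profiles(sim, _energy_vectors(obs))


@dataclass
class TFMatrix:
    """6×6 Pearson correlation matrix among the canonical nodal measures.

    ``degenerate`` flags measures whose nodal vector had zero variance in at
    least one contributing network; their correlation entries are set to 0.
    """

    values: np.ndarray
    measures: tuple[str, ...] = NODAL_MEASURES
    degenerate: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.measures),) * 2:
            raise ValueError("TF matrix shape does not match measure list")
        self.values = v

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.measures), columns=list(self.measures)
        )

    def to_csv(self, path: str | Path) -> None:
        self.as_frame().to_csv(path)


def _single_tf(profile: NodalProfile) -> tuple[np.ndarray, set[str]]:
    mat = profile.as_matrix()  # (n, 6)
    sd = mat.std(axis=0)
    degenerate = {NODAL_MEASURES[i] for i in np.flatnonzero(sd == 0)}
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    bad = sd == 0
    corr[bad, :] = 0.0
    corr[:, bad] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr, degenerate


def topological_fingerprint(
    nets: SpatialNetwork | Sequence[SpatialNetwork],
    profiles: Sequence[NodalProfile] | None = None,
) -> TFMatrix:
    """Topological fingerprint of a network, or the elementwise mean TF of a
    cohort (correlations computed per network, then averaged).

    Zero-variance measures (e.g. constant degree) get correlation 0 and are
    flagged rather than left undefined, keeping ΔTF usable on degenerate
    simulations.
    """
    if isinstance(nets, SpatialNetwork):
        nets = [nets]
    if len(nets) == 0:
        raise ValueError("need at least one network")
    if any(net.n_nodes < 3 for net in nets):
        raise ValueError("topological fingerprint requires >= 3 nodes")
    if profiles is None:
        profiles = [nodal_metrics(net) for net in nets]
    mats, degenerate = [], set()
    for prof in profiles:
        corr, bad = _single_tf(prof)
        mats.append(corr)
        degenerate |= bad
    return TFMatrix(np.mean(mats, axis=0), degenerate=tuple(sorted(degenerate)))


def delta_tf(a: TFMatrix, b: TFMatrix) -> float:
    """ΔTF: entrywise Euclidean (Frobenius) norm of the difference of two TFs."""
    if a.measures != b.measures:
        raise ValueError("TF matrices use different measure orderings")
    return float(np.linalg.norm(a.values - b.values))


def edge_overlap(sim: SpatialNetwork, obs: SpatialNetwork) -> dict[str, float]:
    """Agreement between two edge sets over all distinct node pairs.

    Count of pairs where both networks agree (edge in both, or absent from
    both — true positives plus true negatives), and that count as a
    fraction of all pairs.
    """
    if sim.n_nodes != obs.n_nodes:
        raise ValueError("node-count mismatch")
    n = sim.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    agree = int(np.sum(sim.adjacency[iu, ju] == obs.adjacency[iu, ju]))
    return {"count": agree, "fraction": agree / iu.size}


@dataclass
class SpatialErrorMap:
    """Node-by-measure spatial discrepancy between cohorts.

    error = empirical nodal mean − synthetic nodal mean, per node and
    measure; ``correlations`` holds the across-node Pearson r between the
    two cohort-mean vectors per measure; ``absolute_error`` sums |Z-scored
    error| (Z across nodes within measure) over the six measures. A
    ``signed`` absolute error (plain sum of Z-scores, allowing cancellation)
    is available for sensitivity analyses.
    """

    error: pd.DataFrame  # nodes × measures
    correlations: pd.Series  # per measure
    absolute_error: pd.Series  # per node
    signed_error: pd.Series  # per node

    def to_csv(self, path: str | Path) -> None:
        out = self.error.copy()
        out["absolute_error"] = self.absolute_error
        out.to_csv(path)


def _cohort_nodal_means(
    nets: Sequence[SpatialNetwork],
    profiles: Sequence[NodalProfile] | None = None,
) -> np.ndarray:
    if profiles is None:
        profiles = [nodal_metrics(net) for net in nets]
    return np.mean([p.as_matrix() for p in profiles], axis=0)


def spatial_error(
    sims: Sequence[SpatialNetwork],
    obs: Sequence[SpatialNetwork],
    sim_profiles: Sequence[NodalProfile] | None = None,
    obs_profiles: Sequence[NodalProfile] | None = None,
) -> SpatialErrorMap:
    """Spatial layout comparison between a synthetic and an empirical cohort.

    Nodal measures are averaged across each cohort to one vector per
    measure; the map reports per-node errors (empirical − synthetic),
    per-measure across-node correlations, and the per-node absolute error
    aggregating the six |Z-scored| errors.
    """
    if len(sims) == 0 or len(obs) == 0:
        raise ValueError("both cohorts must be non-empty")
    n = obs[0].n_nodes
    if any(x.n_nodes != n for x in list(sims) + list(obs)):
        raise ValueError("cohorts must share node count and node order")
    labels = obs[0].labels
    syn = _cohort_nodal_means(sims, sim_profiles)
    emp = _cohort_nodal_means(obs, obs_profiles)
    err = emp - syn
    corrs = []
    for m in range(len(NODAL_MEASURES)):
        if syn[:, m].std() == 0 or emp[:, m].std() == 0:
            corrs.append(0.0)
        else:
            corrs.append(float(np.corrcoef(syn[:, m], emp[:, m])[0, 1]))
    sd = err.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (err - err.mean(axis=0)) / sd
    return SpatialErrorMap(
        error=pd.DataFrame(err, index=labels, columns=list(NODAL_MEASURES)),
        correlations=pd.Series(corrs, index=list(NODAL_MEASURES)),
        absolute_error=pd.Series(np.abs(z).sum(axis=1), index=labels),
        signed_error=pd.Series(z.sum(axis=1), index=labels),
    )
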