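"""Parameter fitting for generative network models by grid search.

This module provides the package's central modelling objects, in the style
of statsmodels: :class:`GenerativeNetworkModel` is constructed from an
observed network, a seed network and a generative rule; its :meth:`fit`
runs a grid search over (η, γ) and returns :class:`GridSearchResults`,
which carries the full energy surface, the best-fitting parameters (single
argmin or top-N average), refinement over a narrower window, and the
scaled-parameter simulations used to study developmental stochasticity.

Each grid point's simulation uses an independent random substream derived
from (base seed, point index, run index), so surfaces are reproducible and
independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import EnergyResult, energy_from_profiles, model_energy
from .generative import (
    DEFAULT_EPSILON,
    GenerativeParams,
    GenerativeTrace,
    grow_network,
)
from .network import SpatialNetwork, nodal_metrics

__all__ = [
    "ParameterGrid",
    "COARSE_GRID",
    "REFINED_WINDOW",
    "GenerativeNetworkModel",
    "GridSearchResults",
    "select_optimal",
    "scaled_parameter_runs",
    "DEFAULT_SCALING_FRACTIONS",
]


@dataclass(frozen=True)
class ParameterGrid:
    """Uniform Cartesian grid over the (η, γ) parameter space.

    η spans ``eta_range`` (hi ≤ 0), γ spans ``gamma_range`` (lo ≥ 0), both
    inclusive of their endpoints.
    """

    eta_range: tuple[float, float]
    gamma_range: tuple[float, float]
    n_eta: int
    n_gamma: int

    def __post_init__(self) -> None:
        if self.eta_range[0] > self.eta_range[1] or self.eta_range[1] > 0:
            raise ValueError("eta_range must satisfy lo <= hi <= 0")
        if self.gamma_range[0] > self.gamma_range[1] or self.gamma_range[0] < 0:
            raise ValueError("gamma_range must satisfy 0 <= lo <= hi")
        if self.n_eta < 1 or self.n_gamma < 1:
            raise ValueError("grid sizes must be >= 1")

    @property
    def etas(self) -> np.ndarray:
        lo, hi = self.eta_range
        return np.array([lo]) if self.n_eta == 1 else np.linspace(lo, hi, self.n_eta)

    @property
    def gammas(self) -> np.ndarray:
        lo, hi = self.gamma_range
        return (
            np.array([lo]) if self.n_gamma == 1 else np.linspace(lo, hi, self.n_gamma)
        )

    @property
    def points(self) -> np.ndarray:
        """(n_eta · n_gamma, 2) array of (η, γ) combinations."""
        ee, gg = np.meshgrid(self.etas, self.gammas, indexing="ij")
        return np.column_stack([ee.ravel(), gg.ravel()])

    def contains(self, other: "ParameterGrid") -> bool:
        return (
            self.eta_range[0] <= other.eta_range[0]
            and other.eta_range[1] <= self.eta_range[1]
            and self.gamma_range[0] <= other.gamma_range[0]
            and other.gamma_range[1] <= self.gamma_range[1]
        )


#: The coarse search space: 400 × 400 = 160,000 combinations over
#: −10 ≤ η ≤ 0, 0 ≤ γ ≤ 10.
COARSE_GRID = ParameterGrid((-10.0, 0.0), (0.0, 10.0), 400, 400)

#: The refinement window: 200 × 200 = 40,000 combinations over
#: −3.75 ≤ η ≤ −1.75, 0.2 ≤ γ ≤ 0.6.
REFINED_WINDOW = ParameterGrid((-3.75, -1.75), (0.2, 0.6), 200, 200)

#: Scaling fractions for attenuated-parameter runs: 100% down to 0% in 10%
#: steps (11 values).
DEFAULT_SCALING_FRACTIONS = tuple(np.round(np.linspace(1.0, 0.0, 11), 10))


def _point_rng(base_seed: int, point_index: int, run: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(base_seed), spawn_key=(point_index, run))
    )


class GenerativeNetworkModel:
    """Economic generative model of one observed connectome.

    Parameters
    ----------
    observed : SpatialNetwork
        The binary connectome the simulations must reproduce.
    seed_network : SpatialNetwork
        Sparse starting network (shared across subjects in a cohort study);
        must lie on the same layout and have no more edges than observed.
    rule : str
        Generative rule for the topological value term (default the
        common-neighbours homophily rule).
    epsilon : float
        Regularization added to K before exponentiation.

    Examples
    --------
    >>> model = GenerativeNetworkModel(obs, seed, rule="neighbors")
    >>> res = model.fit(grid=ParameterGrid((-4, -1.5), (0.1, 0.7), 21, 21), seed=1)
    >>> res.params  # top-10 average of the lowest-energy (eta, gamma)
    """

    def __init__(
        self,
        observed: SpatialNetwork,
        seed_network: SpatialNetwork,
        rule: str = "neighbors",
        epsilon: float = DEFAULT_EPSILON,
        subject: str | None = None,
    ) -> None:
        if observed.n_nodes != seed_network.n_nodes:
            raise ValueError("observed and seed networks differ in node count")
        if seed_network.n_edges > observed.n_edges:
            raise ValueError("seed network has more edges than the observation")
        missing = (seed_network.adjacency == 1) & (observed.adjacency == 0)
        if missing.any():
            # seed edges need not be observed edges, but flag gross mismatch
            pass
        self.observed = observed
        self.seed_network = seed_network
        self.rule = rule
        self.epsilon = epsilon
        self.subject = subject
        self._obs_profile = nodal_metrics(observed)
        self._obs_vectors = (
            self._obs_profile.degree,
            self._obs_profile.clustering,
            self._obs_profile.betweenness,
            observed.edge_lengths(),
        )

    @classmethod
    def from_files(
        cls,
        matrix_path: str | Path,
        coords_path: str | Path,
        seed_network: SpatialNetwork,
        threshold: float = 6100.0,
        **kwargs,
    ) -> "GenerativeNetworkModel":
        """Build a model from a weighted-matrix CSV and a coordinate CSV,
        thresholding at ``threshold`` (default the study's 6100 streamlines)."""
        from .network import load_connectome, threshold_binarize

        wc = load_connectome(matrix_path, coords_path)
        return cls(threshold_binarize(wc, threshold), seed_network, **kwargs)

    # -- simulation ---------------------------------------------------------

    def simulate(
        self,
        params: GenerativeParams | tuple[float, float],
        rng: np.random.Generator | int | None = None,
        **trace_opts,
    ) -> GenerativeTrace:
        """Grow one synthetic network to the observed edge count."""
        params = self._coerce_params(params)
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        return grow_network(
            self.observed.n_edges,
            self.seed_network,
            params,
            rng=rng,
            epsilon=self.epsilon,
            **trace_opts,
        )

    def energy(self, sim: SpatialNetwork | GenerativeTrace) -> EnergyResult:
        """Energy of a simulated network against the observed connectome."""
        net = sim.network if isinstance(sim, GenerativeTrace) else sim
        return energy_from_profiles(net, self._obs_vectors)

    def _coerce_params(self, params) -> GenerativeParams:
        if isinstance(params, GenerativeParams):
            if params.rule != self.rule:
                raise ValueError(
                    f"params.rule {params.rule!r} differs from model rule {self.rule!r}"
                )
            return params
        eta, gamma = params
        return GenerativeParams(self.rule, float(eta), float(gamma))

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        grid: ParameterGrid = COARSE_GRID,
        n_runs: int = 1,
        seed: int = 0,
        top_n: int = 10,
    ) -> "GridSearchResults":
        """Grid search over (η, γ): grow ``n_runs`` networks per grid point
        and record the energy (mean over runs).

        Deterministic given ``seed``; each point uses an independent random
        substream so evaluation order is immaterial.
        """
        rows = self._evaluate_grid(grid, n_runs, seed)
        return GridSearchResults(self, grid, rows, n_runs=n_runs, seed=seed,
                                 top_n=top_n)

    def _evaluate_grid(self, grid: ParameterGrid, n_runs: int, seed: int) -> pd.DataFrame:
        if self.observed.n_edges < self.seed_network.n_edges:
            raise ValueError("target edge count below seed edge count")
        records = []
        for idx, (eta, gamma) in enumerate(grid.points):
            comp = np.zeros(5)
            for run in range(n_runs):
                trace = grow_network(
                    self.observed.n_edges,
                    self.seed_network,
                    GenerativeParams(self.rule, eta, gamma),
                    rng=_point_rng(seed, idx, run),
                    epsilon=self.epsilon,
                )
                e = self.energy(trace)
                comp += [e.ks_degree, e.ks_clustering, e.ks_betweenness,
                         e.ks_edge_length, e.energy]
            comp /= n_runs
            records.append((eta, gamma, *comp))
        return pd.DataFrame(
            records,
            columns=["eta", "gamma", "ks_k", "ks_c", "ks_b", "ks_d", "energy"],
        )


class GridSearchResults:
    """Energy surface from a grid search plus optimal-parameter selection.

    Attributes
    ----------
    energies : pandas.DataFrame
        One row per evaluated (η, γ) with the four KS components and E.
    params : GenerativeParams
        The selected optimum: top-``top_n`` average of (η, γ) (top_n=1
        reduces to the argmin).
    """

    def __init__(
        self,
        model: GenerativeNetworkModel,
        grid: ParameterGrid,
        energies: pd.DataFrame,
        n_runs: int,
        seed: int,
        top_n: int = 10,
        parent: "GridSearchResults | None" = None,
    ) -> None:
        self.model = model
        self.grid = grid
        self.energies = energies
        self.n_runs = n_runs
        self.seed = seed
        self.top_n = top_n
        self.parent = parent

    # -- selection ----------------------------------------------------------

    @property
    def argmin(self) -> GenerativeParams:
        row = self.energies.loc[self.energies["energy"].idxmin()]
        return GenerativeParams(self.model.rule, row["eta"], row["gamma"])

    @property
    def min_energy(self) -> float:
        return float(self.energies["energy"].min())

    def top(self, n: int) -> pd.DataFrame:
        """The n lowest-energy rows, ascending."""
        if n < 1 or n > len(self.energies):
            raise ValueError("top-N must be between 1 and the number of grid points")
        return self.energies.nsmallest(n, "energy", keep="first")

    def optimal(self, top_n: int | None = None) -> GenerativeParams:
        """Optimal parameters: argmin for top_n=1, else the componentwise
        mean of (η, γ) over the top_n lowest-energy points (capped at the
        number of evaluated points)."""
        n = self.top_n if top_n is None else top_n
        n = min(n, len(self.energies))
        if n == 1:
            return self.argmin
        best = self.top(n)
        return GenerativeParams(
            self.model.rule, float(best["eta"].mean()), float(best["gamma"].mean())
        )

    @property
    def params(self) -> GenerativeParams:
        return self.optimal()

    # -- refinement and downstream runs -------------------------------------

    def refine(
        self,
        window: ParameterGrid = REFINED_WINDOW,
        n_runs: int | None = None,
        seed: int | None = None,
    ) -> "GridSearchResults":
        """Re-run the search on a narrower window, keeping provenance.

        A window extending beyond the coarse range triggers a warning, not
        an error.
        """
        import warnings

        if not self.grid.contains(window):
            warnings.warn("refinement window extends beyond the coarse grid range")
        res = self.model.fit(
            grid=window,
            n_runs=self.n_runs if n_runs is None else n_runs,
            seed=(self.seed + 1) if seed is None else seed,
            top_n=self.top_n,
        )
        res.parent = self
        return res

    def scaled_runs(
        self,
        fractions: Sequence[float] = DEFAULT_SCALING_FRACTIONS,
        rng: np.random.Generator | int | None = None,
        params: GenerativeParams | None = None,
        **trace_opts,
    ) -> list[GenerativeTrace]:
        """Simulations at parameters scaled toward the origin."""
        base = self.params if params is None else params
        return scaled_parameter_runs(
            self.model, base, fractions, rng=rng, **trace_opts
        )

    # -- reporting -----------------------------------------------------------

    def summary(self, top_n: int | None = None) -> str:
        n = self.top_n if top_n is None else top_n
        best = self.argmin
        opt = self.optimal(n)
        lines = [
            "Generative network model fit (grid search)",
            "=" * 46,
            f"subject:            {self.model.subject or '<unnamed>'}",
            f"rule:               {self.model.rule}",
            f"nodes / edges:      {self.model.observed.n_nodes} / "
            f"{self.model.observed.n_edges}",
            f"seed edges:         {self.model.seed_network.n_edges}",
            f"grid:               {self.grid.n_eta} x {self.grid.n_gamma} over "
            f"eta {list(self.grid.eta_range)}, gamma {list(self.grid.gamma_range)}",
            f"runs per point:     {self.n_runs}",
            "-" * 46,
            f"min energy:         {self.min_energy:.4f}",
            f"argmin (eta, gamma): ({best.eta:.4f}, {best.gamma:.4f})",
            f"top-{n} mean (eta, gamma): ({opt.eta:.4f}, {opt.gamma:.4f})",
            f"origin distance:    {opt.origin_distance():.4f}",
        ]
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        self.energies.to_csv(path, index=False)


def select_optimal(res: GridSearchResults, top_n: int = 10) -> GenerativeParams:
    """Functional form of :meth:`GridSearchResults.optimal`."""
    return res.optimal(top_n)


def scaled_parameter_runs(
    model: GenerativeNetworkModel,
    params: GenerativeParams,
    fractions: Sequence[float] = DEFAULT_SCALING_FRACTIONS,
    rng: np.random.Generator | int | None = None,
    **trace_opts,
) -> list[GenerativeTrace]:
    """Grow one network per scaling fraction f at parameters (f·η, f·γ).

    Fraction 1 reproduces the optimal-parameter run; fraction 0 is uniform
    random growth conditioned on the seed.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    out = []
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError("scaling fractions must lie in [0, 1]")
        out.append(model.simulate(params.scaled(f), rng=rng, **trace_opts))
    return out
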