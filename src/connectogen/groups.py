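"""Group-level statistics for fitted generative models.

Implements the statistical layer of a two-group connectome study:

* Shapiro-gated global comparisons (ANOVA when residuals look normal,
  two-sample KS otherwise);
* node-wise t-tests with Benjamini–Hochberg FDR correction;
* the origin-distance contrast on fitted (η, γ) — subjects whose parameters
  sit closer to the origin of the parameter space grew under weaker wiring
  constraints;
* PLS discriminant analysis with permutation tests and bootstrap CIs,
  probing whether the group difference reflects a single latent shift in
  both parameters;
* stochasticity analyses of growth traces (wiring-probability dispersion,
  variance over developmental time, degree kurtosis) and the randomness
  score (mean ΔTF to an ensemble of randomly wired networks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evaluation import TFMatrix, delta_tf, topological_fingerprint
from .generative import P_HIST_BINS, GenerativeParams, GenerativeTrace
from .network import (
    NODAL_MEASURES,
    NodalProfile,
    SpatialNetwork,
    random_wired_ensemble,
)

__all__ = [
    "GroupAssignment",
    "TestResult",
    "PLSResult",
    "gated_group_test",
    "nodewise_group_tests",
    "origin_distance",
    "pls_discriminant",
    "wiring_dispersion",
    "stochasticity_comparison",
    "StochasticityComparison",
    "randomness_score",
    "ensemble_internal_scores",
]


@dataclass(frozen=True)
class GroupAssignment:
    """Two-group labelling of subjects."""

    subjects: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.labels):
            raise ValueError("subjects and labels differ in length")
        if len(self.group_names) != 2:
            raise ValueError("exactly two non-empty groups are required")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "GroupAssignment":
        return cls(tuple(mapping.keys()), tuple(str(v) for v in mapping.values()))

    @property
    def group_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        labs = np.asarray(self.labels)
        a, b = self.group_names
        return labs == a, labs == b

    def indicator(self) -> np.ndarray:
        """0/1 coding: 0 for the first group name, 1 for the second."""
        return self.masks()[1].astype(float)


@dataclass
class TestResult:
    """Outcome of a single statistical comparison."""

    test: str
    statistic: float
    pvalue: float
    qvalue: float | None = None
    group_means: dict[str, float] = field(default_factory=dict)
    group_sds: dict[str, float] = field(default_factory=dict)
    shapiro_pvalue: float | None = None
    flags: tuple[str, ...] = ()


def _group_summary(x, y, groups: GroupAssignment):
    a, b = groups.group_names
    return (
        {a: float(np.mean(x)), b: float(np.mean(y))},
        {a: float(np.std(x, ddof=1)), b: float(np.std(y, ddof=1))},
    )


def gated_group_test(
    values: Sequence[float],
    groups: GroupAssignment,
    alpha: float = 0.05,
) -> TestResult:
    """Compare a per-subject quantity between two groups, gating the test
    choice on normality.

    A Shapiro–Wilk test on the pooled within-group residuals decides the
    branch: residuals consistent with normality (p ≥ ``alpha``) are compared
    by one-way ANOVA, otherwise by a two-sample KS test.
    """
    vals = np.asarray(values, dtype=float)
    ma, mb = groups.masks()
    x, y = vals[ma], vals[mb]
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 subjects")
    residuals = np.concatenate([x - x.mean(), y - y.mean()])
    means, sds = _group_summary(x, y, groups)
    if np.ptp(vals) == 0:
        # identical constant data in both groups: no evidence of any effect
        return TestResult("ANOVA", 0.0, 1.0, group_means=means, group_sds=sds,
                          shapiro_pvalue=1.0, flags=("constant",))
    if np.ptp(residuals) == 0:
        # each group constant but at different levels: perfect separation
        return TestResult("ANOVA", float("inf"), 0.0, group_means=means,
                          group_sds=sds, shapiro_pvalue=1.0,
                          flags=("zero_within_group_variance",))
    shapiro_p = float(stats.shapiro(residuals).pvalue)
    if shapiro_p >= alpha:
        f, p = stats.f_oneway(x, y)
        return TestResult("ANOVA", float(f), float(p), group_means=means,
                          group_sds=sds, shapiro_pvalue=shapiro_p)
    d, p = stats.ks_2samp(x, y)
    return TestResult("KS", float(d), float(p), group_means=means,
                      group_sds=sds, shapiro_pvalue=shapiro_p)


def nodewise_group_tests(
    profiles: Sequence[NodalProfile],
    groups: GroupAssignment,
    measures: Sequence[str] = ("degree", "betweenness", "clustering",
                               "local_efficiency"),
) -> pd.DataFrame:
    """Per-node two-sample t-tests per measure with BH-FDR within measure.

    Nodes where both groups have zero within-group variance are assigned
    p = 1 and flagged in the ``degenerate`` column.
    """
    if len(profiles) != len(groups.subjects):
        raise ValueError("one profile per subject is required")
    unknown = set(measures) - set(NODAL_MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    ma, mb = groups.masks()
    rows = []
    for measure in measures:
        data = np.stack([getattr(p, measure) for p in profiles])  # subj × nodes
        x, y = data[ma], data[mb]
        n_nodes = data.shape[1]
        tvals = np.zeros(n_nodes)
        pvals = np.ones(n_nodes)
        degenerate = np.zeros(n_nodes, dtype=bool)
        for node in range(n_nodes):
            if x[:, node].std(ddof=1) == 0 and y[:, node].std(ddof=1) == 0:
                degenerate[node] = True
                continue
            t, p = stats.ttest_ind(x[:, node], y[:, node])
            tvals[node], pvals[node] = t, p
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for node in range(n_nodes):
            rows.append(
                {
                    "measure": measure,
                    "node": node,
                    "t": tvals[node],
                    "p": pvals[node],
                    "q": qvals[node],
                    "mean_a": x[:, node].mean(),
                    "mean_b": y[:, node].mean(),
                    "degenerate": degenerate[node],
                }
            )
    return pd.DataFrame(rows)


def origin_distance(params: GenerativeParams | tuple[float, float]) -> float:
    """Distance √(η² + γ²) of fitted parameters from the origin.

    Smaller distances mean weaker wiring constraints and a more stochastic
    generative process.
    """
    if isinstance(params, GenerativeParams):
        return params.origin_distance()
    eta, gamma = params
    return float(np.hypot(eta, gamma))


# ---------------------------------------------------------------------------
# PLS discriminant analysis
# ---------------------------------------------------------------------------

def _pls_fit(x: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS with a single response column.

    Returns (weights, x_loadings, scores, component_correlations), columns
    per component. ``x`` must be centred/standardized, ``y`` centred.
    """
    n, p = x.shape
    xk = x.copy()
    weights = np.zeros((p, n_components))
    loadings = np.zeros((p, n_components))
    scores = np.zeros((n, n_components))
    corrs = np.zeros(n_components)
    for c in range(n_components):
        w = xk.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        t = xk @ w
        tt = t @ t
        if tt == 0:
            break
        pl = xk.T @ t / tt
        xk = xk - np.outer(t, pl)
        weights[:, c] = w
        loadings[:, c] = pl
        scores[:, c] = t
        if t.std() > 0 and y.std() > 0:
            corrs[c] = float(np.corrcoef(t, y)[0, 1])
    return weights, loadings, scores, corrs


@dataclass
class PLSResult:
    """PLS discriminant analysis of fitted parameters against group labels."""

    loadings: pd.DataFrame  # predictors × components
    loading_cis: pd.DataFrame  # rows (predictor, component) with lo/hi
    component_correlations: np.ndarray  # |r| of each X score with the response
    permutation_pvalues: np.ndarray
    scores: pd.DataFrame  # subjects × components
    score_test: TestResult  # group comparison of first-component scores
    excluded_predictors: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = ["PLS discriminant analysis", "=" * 40]
        for c in range(len(self.component_correlations)):
            lines.append(
                f"component {c + 1}: |r| = {self.component_correlations[c]:.3f}, "
                f"permutation p = {self.permutation_pvalues[c]:.4g}"
            )
        for pred in self.loadings.index:
            for c, col in enumerate(self.loadings.columns):
                lo, hi = self.loading_cis.loc[(pred, col)]
                lines.append(
                    f"  {pred} loading on {col}: {self.loadings.loc[pred, col]:.4f} "
                    f"[{lo:.4f}, {hi:.4f}]"
                )
        return "\n".join(lines)


def pls_discriminant(
    params_table: pd.DataFrame,
    groups: GroupAssignment,
    n_components: int = 2,
    n_perm: int = 100_000,
    n_boot: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> PLSResult:
    """PLS discriminant analysis of per-subject predictors (e.g. η and γ)
    against two-group membership.

    Predictors are standardized; the response is the 0/1 group indicator,
    centred. Component significance comes from permuting group labels
    (add-one convention (b+1)/(m+1)); loading CIs are percentile bootstrap
    over subjects, stratified by group, with bootstrap components
    sign-aligned to the observed ones.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x_raw = params_table.to_numpy(dtype=float)
    predictors = list(params_table.columns)
    keep = [i for i in range(x_raw.shape[1]) if x_raw[:, i].std() > 0]
    excluded = tuple(predictors[i] for i in range(x_raw.shape[1]) if i not in keep)
    if len(keep) < 2:
        raise ValueError("need at least two non-constant predictors")
    x_raw = x_raw[:, keep]
    predictors = [predictors[i] for i in keep]
    n_components = min(n_components, x_raw.shape[1])

    y = groups.indicator()
    y_c = y - y.mean()
    x = (x_raw - x_raw.mean(axis=0)) / x_raw.std(axis=0, ddof=0)

    w_obs, load_obs, scores, corr_obs = _pls_fit(x, y_c, n_components)
    abs_obs = np.abs(corr_obs)

    # permutation test on |component correlation|
    exceed = np.zeros(n_components)
    for _ in range(n_perm):
        yp = y_c[rng.permutation(y_c.size)]
        _, _, _, corr_p = _pls_fit(x, yp, n_components)
        exceed += np.abs(corr_p) >= abs_obs
    perm_p = (exceed + 1.0) / (n_perm + 1.0)

    # stratified bootstrap of loadings
    ma, mb = groups.masks()
    idx_a, idx_b = np.flatnonzero(ma), np.flatnonzero(mb)
    boot = np.zeros((n_boot, x.shape[1], n_components))
    for b in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(idx_a, size=idx_a.size, replace=True),
                rng.choice(idx_b, size=idx_b.size, replace=True),
            ]
        )
        xb = x_raw[take]
        sd = xb.std(axis=0, ddof=0)
        if np.any(sd == 0):
            boot[b] = np.nan
            continue
        xb = (xb - xb.mean(axis=0)) / sd
        yb = y[take]
        wb, lb, _, _ = _pls_fit(xb, yb - yb.mean(), n_components)
        for c in range(n_components):
            sign = np.sign(wb[:, c] @ w_obs[:, c]) or 1.0
            boot[b, :, c] = sign * lb[:, c]
    lo = np.nanpercentile(boot, 2.5, axis=0)
    hi = np.nanpercentile(boot, 97.5, axis=0)

    comp_cols = [f"LV{c + 1}" for c in range(n_components)]
    ci_index = pd.MultiIndex.from_product([predictors, comp_cols])
    ci = pd.DataFrame(
        {
            "lo": lo.reshape(-1, order="C").ravel(),
            "hi": hi.reshape(-1, order="C").ravel(),
        },
        index=ci_index,
    )
    score_test = gated_group_test(scores[:, 0], groups)
    return PLSResult(
        loadings=pd.DataFrame(load_obs, index=predictors, columns=comp_cols),
        loading_cis=ci,
        component_correlations=abs_obs,
        permutation_pvalues=perm_p,
        scores=pd.DataFrame(scores, index=list(groups.subjects), columns=comp_cols),
        score_test=score_test,
        excluded_predictors=excluded,
    )


# ---------------------------------------------------------------------------
# Stochasticity of growth
# ---------------------------------------------------------------------------

def wiring_dispersion(trace: GenerativeTrace) -> dict[str, float]:
    """Dispersion summaries of a trace's wiring-probability distribution.

    ``contender_fraction`` — mean over growth steps of the share of eligible
    pairs whose probability exceeds the uniform level 1/m: the fraction of
    serious contenders for the next edge. Flat (weak-constraint)
    probability landscapes spread mass over many contenders, so this rises
    as parameters shrink toward the origin.

    ``effective_fraction`` — exp(Shannon entropy)/m of the step-averaged
    distribution: effective contender number as a fraction of eligible pairs.

    ``mean_variance`` — mean over steps of the variance of the eligible
    normalized probabilities (large when a few pairs dominate; note this
    moves opposite to the two flatness measures).
    """
    hist = trace.p_histograms
    if hist.size == 0:
        raise ValueError("trace has no recorded probability summaries")
    dens = hist / hist.sum(axis=1, keepdims=True)
    centers = (P_HIST_BINS[:-1] + P_HIST_BINS[1:]) / 2.0
    contender = float(dens[:, centers > 1.0].sum(axis=1).mean())
    pooled = dens.mean(axis=0)
    nz = pooled[pooled > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return {
        "contender_fraction": contender,
        "effective_fraction": float(np.exp(entropy) / pooled.size),
        "mean_variance": float(trace.p_variance.mean()),
    }


def _pooled_density(traces: Sequence[GenerativeTrace]) -> tuple[np.ndarray, float]:
    """Step-averaged wiring-probability histogram pooled over traces; also
    returns the total observation count behind it."""
    dens = []
    count = 0.0
    for tr in traces:
        h = tr.p_histograms
        dens.append((h / h.sum(axis=1, keepdims=True)).mean(axis=0))
        count += h.sum() / h.shape[0]  # eligible pairs per step, averaged
    return np.mean(dens, axis=0), count


def _ks_binned(da: np.ndarray, na: float, db: np.ndarray, nb: float) -> TestResult:
    """Two-sample KS on binned distributions with asymptotic p-value."""
    d = float(np.max(np.abs(np.cumsum(da) - np.cumsum(db))))
    ne = na * nb / (na + nb)
    p = float(stats.kstwobign.sf(max(np.sqrt(ne), 1.0) * d))
    return TestResult("KS", d, p)


def _rescale(y: np.ndarray, n_points: int = 100) -> np.ndarray:
    x = np.linspace(0.0, 1.0, y.size)
    return np.interp(np.linspace(0.0, 1.0, n_points), x, y)


@dataclass
class StochasticityComparison:
    """Group contrast of generative-process stochasticity."""

    p_distribution_test: TestResult  # KS on pooled wiring-probability values
    dispersion_test: TestResult  # gated test on per-subject contender fraction
    kurtosis_test: TestResult  # KS on per-subject degree kurtosis
    variance_curves: pd.DataFrame  # 100 time points × groups (mean P variance)
    dispersion: pd.Series  # per-subject contender fraction
    kurtosis: pd.Series  # per-subject excess degree kurtosis


def stochasticity_comparison(
    traces: Mapping[str, GenerativeTrace],
    groups: GroupAssignment,
) -> StochasticityComparison:
    """Compare the stochasticity of growth between two groups of subjects.

    Pooled step-averaged wiring-probability value distributions (relative
    scale, multiples of uniform) are compared by KS; per-subject dispersion
    (contender fraction) by the Shapiro-gated test; per-subject excess
    (Fisher) kurtosis of the final degree distribution by two-sample KS —
    kurtosis closer to 0 means a degree distribution closer to normal,
    i.e. more randomized topology. Group-mean variance-over-developmental-
    time curves (rescaled to 100 points) are returned for inspection.
    """
    missing = set(groups.subjects) - set(traces)
    if missing:
        raise ValueError(f"missing traces for subjects: {sorted(missing)}")
    ma, mb = groups.masks()
    name_a, name_b = groups.group_names
    subj = np.asarray(groups.subjects)
    tr_a = [traces[s] for s in subj[ma]]
    tr_b = [traces[s] for s in subj[mb]]

    da, na = _pooled_density(tr_a)
    db, nb = _pooled_density(tr_b)
    p_test = _ks_binned(da, na, db, nb)

    disp = pd.Series(
        {s: wiring_dispersion(traces[s])["contender_fraction"] for s in subj}
    )
    disp_test = gated_group_test(disp.to_numpy(), groups)
    disp_test.group_means = {
        name_a: float(disp[subj[ma]].mean()),
        name_b: float(disp[subj[mb]].mean()),
    }

    kurt = pd.Series(
        {
            s: float(stats.kurtosis(traces[s].network.degrees, fisher=True))
            for s in subj
        }
    )
    d, p = stats.ks_2samp(kurt[subj[ma]], kurt[subj[mb]])
    kurt_test = TestResult(
        "KS", float(d), float(p),
        group_means={name_a: float(kurt[subj[ma]].mean()),
                     name_b: float(kurt[subj[mb]].mean())},
    )

    curves = pd.DataFrame(
        {
            name_a: np.mean([_rescale(t.p_variance) for t in tr_a], axis=0),
            name_b: np.mean([_rescale(t.p_variance) for t in tr_b], axis=0),
        },
        index=np.linspace(0.0, 1.0, 100),
    )
    return StochasticityComparison(
        p_distribution_test=p_test,
        dispersion_test=disp_test,
        kurtosis_test=kurt_test,
        variance_curves=curves,
        dispersion=disp,
        kurtosis=kurt,
    )


# ---------------------------------------------------------------------------
# Randomness scoring
# ---------------------------------------------------------------------------

def _ensemble_tfs(
    net: SpatialNetwork, n_random: int, rng: np.random.Generator | None
) -> list[TFMatrix]:
    return [
        topological_fingerprint(r)
        for r in random_wired_ensemble(net, n=n_random, rng=rng)
    ]


def randomness_score(
    net: SpatialNetwork,
    n_random: int = 1000,
    rng: np.random.Generator | int | None = None,
    ensemble_tfs: Sequence[TFMatrix] | None = None,
) -> float:
    """Mean ΔTF between a network and randomly wired same-density networks.

    High scores mean structured (non-random) local organisation; a network
    indistinguishable from the ensemble scores near the ensemble-internal
    mean. Pass ``ensemble_tfs`` to reuse one ensemble across many networks.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if ensemble_tfs is None:
        ensemble_tfs = _ensemble_tfs(net, n_random, rng)
    tf = topological_fingerprint(net)
    return float(np.mean([delta_tf(tf, r) for r in ensemble_tfs]))


def ensemble_internal_scores(
    net: SpatialNetwork,
    n_random: int = 1000,
    rng: np.random.Generator | int | None = None,
    ensemble_tfs: Sequence[TFMatrix] | None = None,
) -> tuple[float, float, list[TFMatrix]]:
    """(mean, SD) of each ensemble member's mean ΔTF to the other members.

    The baseline against which a network's randomness score is judged: a
    genuinely random network scores within the ensemble's internal spread.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if ensemble_tfs is None:
        ensemble_tfs = _ensemble_tfs(net, n_random, rng)
    tfs = list(ensemble_tfs)
    m = len(tfs)
    dmat = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dmat[i, j] = dmat[j, i] = delta_tf(tfs[i], tfs[j])
    per_member = dmat.sum(axis=1) / (m - 1)
    return float(per_member.mean()), float(per_member.std(ddof=1)), tfs
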