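# Methods

This note records the scientific model connectogen implements, the choices
that were genuinely open, and what the synthetic-data validation does and
does not establish.

## The generative model

A subject's connectome is modelled as the endpoint of a stochastic growth
process on a fixed spatial layout. Growth starts from a sparse **seed
network** shared by all subjects (in real cohorts: the strongest
connections present in every subject, ~10% of the final edge count; in
pure synthesis: the shortest-distance pairs, which emulate the dense local
core that survives consistency thresholding). One edge is added per step
until the simulation reaches the observed edge count. The probability
that unconnected regions i, j wire at a given step is

    P_ij ∝ (D_ij)^η · (K_ij + ε)^γ

* `D_ij` — Euclidean distance between region centroids, in the units of
  the coordinate table (the synthetic layouts use mm-like units on an
  ellipsoid with semi-axes 5.5 × 4.0 × 3.0).
* `η ≤ 0` — cost exponent; more negative values penalize long projections
  more severely. Typical fitted values for homophily rules: −3.5 … −1.5.
* `K_ij ≥ 0` — topological value under the chosen generative rule;
  thirteen rules are implemented (spatial, i.e. K ≡ 1; common-neighbour
  count; matching index; avg/min/max/|diff|/product of clustering
  coefficients or of degrees).
* `γ ≥ 0` — value exponent; typical fitted values 0.2 … 0.6.
* `ε = 1e−5` — regularization added to K before exponentiation so that
  zero-value pairs (no common neighbours early in growth) keep a nonzero
  wiring probability; without it the homophily rules could assign zero
  probability everywhere outside existing triangles. The spatial rule
  uses a value factor of exactly 1, and a zero exponent disables its
  factor entirely (0⁰ := 1).

Probabilities are renormalized over eligible (unconnected, off-diagonal)
pairs at every step; once a pair connects its probability is identically
zero. The sampler is a single categorical draw per step; with a fixed
`numpy.random.Generator` the whole trace is bit-reproducible, and the edge
sequence does not depend on which optional summaries are recorded.

## Model fit and fingerprints

The energy of a simulation against its observed network is
`E = max(KS_k, KS_c, KS_b, KS_d)`: two-sample KS statistics on nodal
degree, nodal clustering, nodal betweenness, and the lengths of realized
edges. The KS statistic is the exact ECDF sup-difference (no asymptotics).
Note the edge-length component compares per-edge length distributions;
the *nodal* total incident edge length appears only in fingerprints and
spatial-layout analyses.

The topological fingerprint (TF) is the 6×6 Pearson correlation matrix of
six nodal measures: degree, clustering, betweenness, total incident edge
length, local efficiency, mean matching index. For a cohort, per-network
correlation matrices are averaged elementwise (the alternative —
correlating cohort-averaged nodal vectors — answers a different question
about the average brain rather than the average subject). Zero-variance
measures (e.g. constant degree in a lattice) get correlation 0 and a
flag, keeping ΔTF defined for degenerate simulations. ΔTF is the
Frobenius norm of a TF difference.

Spatial-error maps compare cohort-averaged nodal vectors node by node
(error = empirical − synthetic). The per-node absolute error sums the
*absolute values* of the six Z-scored errors; a signed variant (plain sum,
allowing cancellation) is exposed for sensitivity analysis but is not the
default, since cancellation across measures would understate discrepancy.

## Graph-metric conventions

Binary undirected graphs throughout. Betweenness is the raw Brandes count
(each unordered pair counted once), computed with igraph and cross-checked
against networkx and brute-force path enumeration in the tests. Clustering
and local efficiency are 0 for nodes of degree < 2. Global efficiency uses
the convention that unreachable pairs contribute zero inverse distance;
for disconnected graphs the characteristic path length entering
small-worldness is the inverse of global efficiency (harmonic mean), and
the profile carries a `connected` flag. Small-worldness
σ = (C/C_rand)/(L/L_rand) against a degree-preserving null ensemble
(double-edge swaps, 10·|E| attempted swaps per member, default 500
members). Maximum modularity Q is the best of 10 Louvain restarts with
fixed seeds (3 restarts inside per-step growth trajectories, where Q is
evaluated hundreds of times per trace). Long-distance edges are those
longer than mean + 2 SD of a reference length set — a single network's own
edges by default, or pooled cohort lengths for group comparisons.

## Parameter fitting

Fitting is grid search: grow one network per (η, γ) combination, score its
energy, and select the optimum. The study-scale presets are a 400×400
grid over −10 ≤ η ≤ 0, 0 ≤ γ ≤ 10 and a 200×200 refinement window over
−3.75 ≤ η ≤ −1.75, 0.2 ≤ γ ≤ 0.6; desk-scale analyses use 11×11 to 21×21
grids over the refinement-scale window. The default selected optimum is
the componentwise mean of (η, γ) over the 10 lowest-energy points, which
is considerably more stable than the raw argmin. Each grid point draws
its randomness from a substream seeded by (base seed, point index, run),
so energy surfaces are reproducible and independent of evaluation order.

A caveat established quantitatively during validation: KS-energy grid
fitting is a minimum-distance estimator with appreciable bias and
variance at small network sizes. At 60 nodes / 150 edges, the *expected*
energy surface (25 runs per point) is not minimized at the generating
parameters — simulations from stronger-cost / weaker-value regions vary
less between replicates and therefore sit closer, in KS terms, to any
single observed draw than replicates of the true process do (KS on
betweenness between true-process replicates averages ≈ 0.34 at this
size). Recovered optima scatter with SD ≈ 0.26 in η and land within a
±0.25 × ±0.06 box around the truth for only ~half of subjects. Group
*differences* in origin distance survive this (the bias is shared), but
per-subject point estimates should be treated as noisy; this is the
known limitation that newer likelihood-based estimators address.

## Group analysis

Wherever two groups are compared on a scalar, a Shapiro–Wilk test on the
pooled within-group residuals (α = 0.05) gates the choice between one-way
ANOVA and a two-sample KS test. Pooling residuals rather than testing each
group separately keeps the gate well-defined at small group sizes. Node-
wise comparisons are two-sample t-tests with Benjamini–Hochberg FDR within
each measure; nodes with zero variance in both groups get p = 1 and a
flag.

The PLS discriminant analysis regresses the standardized (η, γ) table on
the centred 0/1 group indicator (NIPALS, 2 components; the numpy
implementation is validated against scikit-learn's PLSRegression and
exists because 100,000-permutation testing needs a ~10 µs fit). Component
significance is the permutation p-value of the |score–response
correlation| with the add-one convention (b+1)/(m+1); loading CIs are
percentile bootstrap over subjects, stratified by group, with bootstrap
components sign-aligned to the observed ones. Defaults are 100,000
permutations/bootstraps; desk-scale analyses run 2,000–5,000.

## Stochasticity of growth

Fitted parameters closer to the origin mean weaker constraints: more pairs
are serious contenders for each new edge, and the realized topology is
closer to random. Three families of read-outs:

* **Wiring-probability dispersion.** Per-step probability values are
  summarized on the relative scale p·m (multiples of the uniform
  probability over the m eligible pairs; fixed 200-bin histogram on
  [0, 20]). The headline dispersion measure is the **contender
  fraction** — the share of eligible pairs above the uniform level —
  which rises monotonically as parameters are scaled toward the origin
  (≈ 0.08 at full strength to ≈ 0.78 at zero in the default cohort); an
  entropy-based effective-contender fraction behaves identically. The
  *variance* of the probability values is also reported per step
  (it rises over developmental time in weak-parameter regimes) but moves
  in the opposite direction under parameter scaling — a normalized
  distribution's value-variance is minimized, not maximized, at uniform —
  so it is not used as the scaling-monotonicity statistic.
* **Randomness score.** Mean ΔTF between a network and 1000 (default)
  randomly wired networks of identical size and density. Structured
  networks score high; at fully attenuated parameters the score falls
  within the random ensemble's own internal spread.
* **Degree kurtosis.** Excess (Fisher) kurtosis of the final degree
  distribution per subject, compared between groups by KS; values closer
  to 0 indicate a more normal (more randomized) degree distribution.

Integration/segregation trajectories (global efficiency and maximum Q per
step) are linearly interpolated onto 100 equal fractions of developmental
time so that subjects with different edge counts are comparable.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes: a
bilaterally mirrored layout of region centroids in an ellipsoid (with a
minimum-separation constraint, since parcellation centroids are never
arbitrarily close), a shared shortest-distance seed, and two groups of
subjects grown under the common-neighbours rule at ground-truth (η, γ)
drawn around group means placed on the empirical η–γ anti-correlation
axis (r = −0.574) at origin distances 2.79 (control-like) and 2.63
(stress-like), with SDs of 0.21 in η and 0.06 in γ. The desk preset is
60 regions at 7% density (124 edges, 13-edge seed, 10 + 10 subjects) —
chosen so a full grid search per subject takes under a second; the
study-scale preset is 130 regions at 3.5% density (294 edges, 30-edge seed,
25 + 24 subjects), matching the scale of the motivating study design.

What the synthetic validation shows: the full pipeline — growth, energy,
fingerprints, fitting, group statistics — is internally consistent and
recovers the *direction* of a built-in group shift in wiring constraints
in the large majority of replicate cohorts. What it does not show:
anything about tractography artifacts, parcellation identity, hemispheric
asymmetries, weighted connectivity, or the anatomical location of effects
in real data — the generator produces none of that structure, and
weighted synthetic matrices (distance-decaying streamline-count mimics)
exist only to exercise thresholding and seed construction.

## Numerical details

* Distances are always recomputed from coordinates; files never carry a
  distance matrix.
* Connectivity matrices are symmetrized by elementwise max and the
  diagonal is zeroed on load; thresholding is strict (weight > t).
* CSV round trips are bit-exact (`%.17g` on write, round-trip float
  parsing on read).
* Degenerate inputs: empty graphs yield all-zero nodal profiles; global
  metrics require at least one edge; two identical constant groups
  compare as "no effect" (F = 0, p = 1); zero-variance predictors are
  excluded from PLS with a flag.
* The histograms behind probability summaries clip at 20× uniform; mass
  above that (possible only under extreme concentration) accumulates in
  the top bin.
* All ensemble sizes (nulls, random wirings, permutations, bootstraps)
  are arguments with study-scale defaults; tests and the acceptance
  script run them at 40–5,000 to keep a full validation pass within
  minutes on one CPU.
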