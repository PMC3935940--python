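# Methods

This note records the statistical model, the conventions and numerical
choices behind `gridrisk`, and what the synthetic-data checks do and do not
demonstrate.

## Neighborhood construction

Households carry projected metric coordinates; inputs that look geographic
(all |x| ≤ 180 and |y| ≤ 90) are rejected rather than silently reprojected.
Cells are half-open squares `[lower, upper)` anchored at the bounding-box
minimum corner (the anchor is configurable for grid-placement sensitivity
checks), so cell assignment is a partition: a point on a shared edge belongs
to the higher-index cell.

A cell enters the analysis when it has at least `min_households` (default 4)
households — ecological covariates from fewer observations are too noisy —
and at least one occupant of the stratum sex.  Covariates are aggregated
over **all** households in the cell for both sex strata, because they
describe the neighborhood environment rather than the stratum; deaths,
population and person-time are stratum specific.  "Schooled household head"
means ≥ 5 years of schooling.

Contiguity is queen (8-neighbor) by default — the standard choice for
square-grid disease mapping, and the one that maximizes borrowing of
strength — with rook available.  Order-k neighborhoods extend queen
contiguity to Chebyshev distance ≤ k (rook to Manhattan distance ≤ k).
Isolated cells are retained with empty neighbor lists and flagged.

## Moran's I

The statistic uses binary contiguity weights; row-standardized weights are
reserved for the multiple-membership model (both schemes are available, and
the choice is recorded in results).  It is computed on crude stratum rates
(deaths / person-years) per cell by default; empirical-Bayes smoothed rates
are offered for sparse data.  Inference is by Monte-Carlo permutation:
values are shuffled across cells and

    p = (1 + #{I_perm ≥ I_obs}) / (n_perm + 1),

one-sided for positive autocorrelation by default (clustering is the
alternative of epidemiological interest), two-sided by flag.  The smallest
attainable p is 1/(n_perm + 1).

## The multiple-membership Poisson model

For included cell j,

    y_j ~ Poisson(μ_j),  μ_j = E_j exp(x_j'β + u_j + s_j),
    u_j ~ N(0, σ²_u),    s_j = Σ_{l ∈ neigh(j)} v_l / |neigh(j)|,  v_l ~ N(0, σ²_v).

The likelihood family is Poisson with an offset — the standard disease-
mapping choice for rare-event counts — with expected counts by internal
standardization, E_j = person-years_j × (total deaths / total person-years),
so exp(linear predictor) is a relative risk and the person-time-weighted
mean SSRR is calibrated near 1.  A custom offset (e.g. raw person-years)
can be supplied to work on the absolute-rate scale instead.

The structured term is the multiple-membership construction with equal
weights 1/|neigh(j)| — not an intrinsic CAR — matching the model class the
package implements throughout.  An isolated cell has s_j = 0; this keeps
the weight rows of non-isolated cells summing to 1 and gives isolated
cells an unstructured effect only.

Priors: flat (improper uniform) on each fixed effect; Gamma(0.001, 0.001)
on each precision, i.e. inverse-gamma(0.001, 0.001) on σ²_u and σ²_v —
the conventional diffuse disease-mapping prior.  With few deaths these
variances are weakly identified and the prior matters; see Limitations.

### Sampler

Metropolis-within-Gibbs:

* **β** — componentwise Gaussian random-walk Metropolis.
* **u** — all m cells proposed and accepted in one vectorized block; valid
  because each u_j enters only its own cell's likelihood, so single-site
  decisions are mutually independent.
* **v** — member effects interact only when two cells share a neighbor,
  which on the grid requires Chebyshev distance ≤ 2k.  Cells are colored
  with a (2k+1)×(2k+1) periodic pattern; within one color class the
  single-site proposals are mutually independent and are evaluated as one
  vectorized block.  This is exact single-site Metropolis at vectorized
  cost (the block structure is asserted at build time).
* **σ²_u, σ²_v** — conjugate Gibbs draws: precision ~ Gamma(a + m/2,
  b + Σe²/2) given the current effects.

Proposal scales (one per β component, one per cell for u and v) adapt
toward 44% acceptance — the scalar random-walk optimum — by Robbins–Monro
updates with step t^(−0.6) during burn-in only; adaptation freezes at the
end of burn-in so the kept chain is a time-homogeneous Markov chain.
Acceptance rates over the kept phase are reported and should sit in
roughly [0.2, 0.6]; persistent rates outside that window indicate the
burn-in was too short for adaptation to settle.  All draws flow from a
single `numpy` Generator seeded by `ModelSpec.seed`, so chains are
bit-reproducible.  Initial values: β₀ = log(Σy/ΣE), everything else 0,
variances 0.1.  A non-finite deviance aborts with diagnostics.

Chain defaults are 20,000 burn-in and 50,000 kept draws (thin 1, float64
storage); the pipeline's working profile uses 2,000 / 5,000, which the
verification experiments below show is adequate at a few hundred cells.

### Summaries

* Fixed effects: posterior mean, SD, and a two-sided Bayesian tail
  probability 2·min(P(θ>0), P(θ<0)), floored at 2/(n_draws+1); a
  Wald-style 2Φ(−|mean/SE|) is available by flag.
* σ²_s — the structured-variance summary — is the posterior mean of the
  per-iteration empirical variance of the realized s vector across cells.
  The marginal variance of s_j under the MM construction is cell-dependent
  (σ²_v/|neigh(j)| for iid v), so the realized-field variance is the
  comparable scalar.  ρ (spatial share) is the posterior mean of
  var(s)/(var(s)+var(u)) with both variances empirical per iteration.
* DIC = D̄ + pD with pD = D̄ − D(θ̄), the deviance evaluated at the
  posterior means of β, u and v.  A degenerate chain gives pD = 0 exactly.
* Neighbor order is chosen by refitting the null model at each candidate
  order and taking the DIC argmin.

## SSRR and classification

SSRR_j is the posterior mean of exp(x_j'β + u_j + s_j) over kept draws —
covariates included, since the maps of interest are covariate-model maps;
a residual-risk mode (β₀ + u + s only) is available.  Values are rounded
half-up to two decimals (explicit floor(100v + 0.5), avoiding float
half-even surprises) and then classified into ≤0.50 / 0.51–1.00 /
1.01–1.50 (moderate) / ≥1.51 (high), which makes the printed-style labels
an exhaustive partition of (0, ∞).  Cell squares are exported as GeoJSON
polygons with SSRR, class and 95% credible interval as properties.

## Descriptive tables

Cause-of-death tables report counts and within-column percentages
(round-half-up, applied once at presentation), rows sorted by total count
with alphabetical tie-break.  A validator checks row/column/footer
consistency and the percentage arithmetic, and rejects internally
inconsistent rows such as occur in some published tabulations; the bundled
reference counts (92 male + 23 female = 115 deaths) carry one such
correction, noted where they are defined.  Age-sex rates are per 1000
person-years in 5-year bands; empty strata are reported missing, never 0.

## Synthetic data

The generator emulates a two-year surveillance study: Neyman–Scott
clustered household points (Poisson parents, Gaussian-scattered children,
default spread 300 m) over a rectangular region, household covariates with
west-east spatial gradients (tap water declining, schooling rising), a
mid-region river line and a single health facility for the distance
covariates, Poisson household sizes (default mean 2 prime-age occupants),
uniform ages in [15, 45), and per-cell deaths from exactly the model the
package fits, with causes drawn from the bundled reference distribution.
The default baseline rate is 1.2 per 1000 person-years — between typical
prime-age male (≈1.6–1.8) and female (≈0.5–0.7) per-1000 rates — over a
10 × 10 km region with 20,000 households.

Deaths are attributed to randomly chosen stratum occupants of the cell and
only in analysis-eligible (included) cells, so region-wide crude rates run
a little below the nominal baseline when many households sit in excluded
cells; counts are capped at the stratum population.  What the generator
does **not** emulate: age-dependent hazards (age is uniform and deaths are
age-independent; rate tables exercise bookkeeping, not demography),
household-level risk correlation, migration, and multi-household GPS
points.  Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the assumed model, not robustness to the
misspecifications real surveillance data carry.

## Verification experiments and problem sizes

The test suite verifies, at sizes chosen to keep the default run a few
minutes long:

* Moran's I against a brute-force dense double-loop oracle to 1e−12 (50
  random grids up to ~200 cells), the checkerboard identity I = −1, and
  permutation type-I error at α = 0.05 within 3 binomial SE over 500 null
  datasets at 199 permutations.
* The Gibbs precision update against its analytic Gamma posterior (KS test)
  and every stored deviance against an independent per-cell log-likelihood
  oracle on a 20-cell fit.
* Fixed-effect recovery: 40 replicate studies of ~300 included cells
  (13,000 households over 9 × 9 km), chains 2,000 / 5,000; 95% credible
  intervals must cover each true coefficient in ≥ 90% of fits.  Variance
  posteriors must fall below 0.05 when the generating variances are 0.
* DIC: pD = 0 on a degenerate chain; a generating covariate lowers DIC
  relative to the null model; a pure-noise covariate moves DIC by < 5; the
  generating neighbor order (1) wins the DIC comparison against order 2 in
  ≥ 80% of 25 replicates under strong spatial structure (σ²_v = 1.0).
* SSRR: exact identity at 1 when all effects are zero, exact band
  boundaries, person-time-weighted mean within 0.1 of 1 under internal
  standardization, and recovery of a known doubled-risk cell to within
  [1.5, 2.5] after shrinkage.

## Known limitations

* With very sparse counts (expected deaths per cell ≪ 1) the random-effect
  variances are prior-sensitive: σ²_u tends to shrink toward 0 while the
  weakly-identified v field can inflate var(s), overstating ρ.  Interpret
  ρ qualitatively in sparse settings.
* The MM structured term is not an intrinsic CAR; σ²_v is not directly
  comparable to a BYM spatial variance.  The empirical var(s) summary is
  the intended cross-model comparable quantity.
* DIC differences of a few units are within Monte-Carlo noise at the
  working chain lengths; order selection is only reliable when spatial
  structure is strong.
* Single-chain inference: convergence is assessed by the acceptance-rate
  window, deviance finiteness and the recovery experiments, not by
  multi-chain diagnostics.
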