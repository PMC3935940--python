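# gridrisk

Grid-based Bayesian spatial analysis of small-area mortality.

`gridrisk` is for epidemiologists and biostatisticians who have georeferenced
household records, person-time and death records from a demographic
surveillance site, and who want to (1) test whether mortality clusters in
space, (2) estimate neighborhood-level ("socio-ecological") risk factors
while properly accounting for spatial dependence, and (3) map where risk is
elevated.  It was built around the analysis style used for prime-age
(15 to <45 years) adult mortality in coastal Vietnamese surveillance sites,
but nothing in it is specific to that setting.

## What it computes

**Neighborhoods.** The study region is split into square grid cells
(default 500 m × 500 m).  A cell is an analysis neighborhood when it holds
at least 4 households and at least one occupant of the sex stratum being
analysed.  Cell covariates (percent male household heads, percent heads
with ≥5 years of schooling, percent using tap water, mean distances to
river and health facility) are aggregated from all households in the cell;
deaths and person-time are sex specific.

**Clustering test.** Global Moran's I on crude cell rates,

    I = (n/S0) · Σᵢⱼ wᵢⱼ (xᵢ − x̄)(xⱼ − x̄) / Σᵢ (xᵢ − x̄)²,

with queen contiguity weights and Monte-Carlo permutation inference
(default 9999 permutations; expectation under no clustering is −1/(n−1)).

**Spatial model.** A Poisson log-linear model with two sets of neighborhood
random effects, fitted by a bespoke Metropolis-within-Gibbs sampler:

    yⱼ ~ Poisson(Eⱼ exp(xⱼ'β + uⱼ + sⱼ)),
    uⱼ ~ N(0, σ²ᵤ),      sⱼ = Σ_{l∈neigh(j)} v_l / |neigh(j)|,   v_l ~ N(0, σ²ᵥ),

the multiple-membership construction: each neighborhood's structured effect
is the equal-weight average of its neighbors' member effects, which makes
estimates "borrow strength" from adjacent cells.  Expected counts Eⱼ use
internal standardization (person-time × study-wide rate), so
exp(xⱼ'β + uⱼ + sⱼ) is a relative risk.  Priors are flat on β and
inverse-gamma(0.001, 0.001) on both variances.  Models are compared by DIC,
and the proportion of neighborhood variance that is spatially structured
(ρ) is reported.

**Risk map.** The spatially smoothed relative risk of each neighborhood,
SSRR_j = posterior mean of exp(xⱼ'β + uⱼ + sⱼ), classified into four bands
(≤0.50, 0.51–1.00, 1.01–1.50 moderate, ≥1.51 high) and exported as GeoJSON
plus a choropleth.

**Descriptives.** A cause-of-death table (counts with within-column
percentages) and age-sex mortality rates per 1000 person-years.

Because real surveillance databases of this kind are rarely public, the
package ships a synthetic-data module that generates clustered household
points, occupants and deaths from exactly the model above with known
parameters, so every stage can be verified against ground truth.

## Worked example

```python
import numpy as np
from gridrisk import ModelSpec, run_mcmc, summarize, ssrr, permutation_test
from gridrisk.synthetic_data import SimConfig, simulate_dataset

cfg = SimConfig(
    seed=7, n_households=13_000, region_km=(9.0, 9.0),
    persons_per_household=3.0,
    beta={"intercept": float(np.log(0.02)), "pct_head_schooled": -0.03},
    sigma2_u=0.05, sigma2_v=0.6,
)
data = simulate_dataset(cfg)
nbhd = data["neighborhoods"]["male"]
inc = nbhd[nbhd["included"]]

rates = inc["deaths"].to_numpy(float) / inc["person_years"].to_numpy(float)
res = permutation_test(rates, data["weights"]["male"], n_perm=999, seed=1)

spec = ModelSpec(covariate_names=["pct_head_schooled"],
                 burn_in=2000, n_keep=5000, seed=2)
sample = run_mcmc(nbhd, spec)
summ = summarize(sample)
surface = ssrr(sample)
```

Printing the sizes, the Moran result, `summ.fixed` and the class counts
gives:

```
361 neighborhoods, 352 included, 112 deaths
Moran's I = 0.072, permutation p = 0.014
                     mean      se  p_value
intercept          1.1310  0.6071    0.088
pct_head_schooled -0.0217  0.0087    0.038
sigma2_u = 0.023, sigma2_s = 0.579, rho_spatial = 0.96, DIC = 439.9
risk_class
0.51-1.00    177
<=0.50        65
>=1.51        57
1.01-1.50     53
```

Reading this: mortality clusters spatially (permutation p = 0.014); each
additional percentage point of schooled household heads in the neighborhood
multiplies the death rate by exp(−0.022) ≈ 0.98 (the generating value was
−0.03, inside the credible interval); most neighborhood variation is
spatially structured; 57 of 352 neighborhoods fall in the high-risk band
(SSRR ≥ 1.51).

A full pipeline run (grid → Moran → null and covariate fits → maps →
tables, both sexes, with a manifest of checksums) is one call:

```bash
gridrisk run --seed 3 --out results/
```

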