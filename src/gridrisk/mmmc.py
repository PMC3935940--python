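"""Bayesian Poisson log-linear model with multiple-membership spatial effects.

Model
-----
For included cell j with death count y_j and expected count E_j:

    y_j ~ Poisson(mu_j),   mu_j = E_j exp(x_j' beta + u_j + s_j)

* ``u_j ~ N(0, sigma2_u)`` — exchangeable (unstructured) heterogeneity;
* ``s_j = sum_{l in neigh(j)} v_l / |neigh(j)|`` with member effects
  ``v_l ~ N(0, sigma2_v)`` — the multiple-membership construction: each
  cell's structured effect is the equal-weight average of its neighbors'
  member effects, which induces spatial smoothing ("borrowing strength").
  An isolated cell gets s_j = 0.

Priors: flat on beta; inverse-gamma(a, b) with a = b = 0.001 on both
variances (equivalently Gamma(a, b) on the precisions).

By default E_j is computed by internal standardization,
``E_j = person_years_j * (total deaths / total person-years)``, so
``exp(x_j' beta + u_j + s_j)`` is the risk of cell j relative to the
study-wide rate.

Sampler
-------
Metropolis-within-Gibbs: fixed effects and both random-effect vectors move by
adaptive random-walk Metropolis; the precisions are conjugate Gibbs draws.
The u_j are conditionally independent given the rest and are updated as one
vectorized block.  The v_l interact only within Chebyshev distance 2k on the
grid, so the cells are colored with a (2k+1) x (2k+1) periodic pattern and
each color class is updated as a vectorized block of mutually independent
single-site moves — exact single-site Metropolis at vectorized cost.
Proposal scales adapt toward 44% acceptance during burn-in only, so the kept
chain is a valid Markov chain.  All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .geo_grid import SpatialWeights, build_weights

__all__ = [
    "ModelSpec",
    "PosteriorSample",
    "ModelSummary",
    "internal_standardized_offset",
    "log_likelihood",
    "run_mcmc",
    "dic",
    "summarize",
    "select_neighbor_order",
    "draw_precision",
]

ADAPT_TARGET = 0.44  # single-site random-walk optimum


@dataclass
class ModelSpec:
    """Configuration of one model fit.

    ``covariate_names`` are columns of the neighborhood table (empty list =
    null model, intercept plus random effects only).  ``offset`` overrides
    the internally standardized expected counts when given (e.g. raw
    person-years to work on the absolute-rate scale).
    """

    covariate_names: list[str] = field(default_factory=list)
    offset: np.ndarray | None = None
    order: int = 1
    contiguity: str = "queen"
    prior_a: float = 0.001
    prior_b: float = 0.001
    burn_in: int = 20_000
    n_keep: int = 50_000
    thin: int = 1
    seed: int = 0
    include_u: bool = True
    include_v: bool = True

    def __post_init__(self) -> None:
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("inverse-gamma prior parameters must be positive")
        if self.burn_in < 0 or self.n_keep <= 0 or self.thin < 1:
            raise ValueError("invalid chain lengths")


@dataclass
class PosteriorSample:
    """Kept MCMC draws plus the data needed to evaluate them."""

    beta: np.ndarray  # (n_keep, p)
    u: np.ndarray  # (n_keep, m)
    v: np.ndarray  # (n_keep, m)
    sigma2_u: np.ndarray  # (n_keep,)
    sigma2_v: np.ndarray  # (n_keep,)
    deviance: np.ndarray  # (n_keep,)
    covariate_names: list[str]
    cell_ids: list[tuple[int, int]]
    y: np.ndarray
    E: np.ndarray
    X: np.ndarray
    weights: SpatialWeights
    accept_rates: dict

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def s_draws(self) -> np.ndarray:
        """Structured effects s = W v for every kept draw, (n_keep, m)."""
        W = self.weights.to_sparse()
        return self.v @ W.T.toarray() if self.v.shape[1] else self.v


@dataclass
class ModelSummary:
    fixed: pd.DataFrame  # index = intercept + covariates; mean, se, p_value
    sigma2_u: float
    sigma2_u_se: float
    sigma2_s: float
    sigma2_s_se: float
    rho_spatial: float
    dic: float
    pd: float


def internal_standardized_offset(neighborhoods: pd.DataFrame) -> np.ndarray:
    """E_j = person_years_j * (total deaths / total person-years)."""
    inc = neighborhoods[neighborhoods["included"]]
    py = inc["person_years"].to_numpy(float)
    deaths = inc["deaths"].to_numpy(float)
    if py.sum() <= 0 or deaths.sum() <= 0:
        raise ValueError("internal standardization needs positive totals")
    return py * (deaths.sum() / py.sum())


def _design_matrix(inc: pd.DataFrame, covariate_names: list[str]) -> np.ndarray:
    missing = [c for c in covariate_names if c not in inc.columns]
    if missing:
        raise ValueError(f"unknown covariate columns: {missing}")
    X = np.column_stack(
        [np.ones(len(inc))] + [inc[c].to_numpy(float) for c in covariate_names]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def log_likelihood(
    y: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    weights: SpatialWeights,
) -> float:
    """Poisson log likelihood of the multiple-membership model.

    ``sum_j [y_j log mu_j - mu_j - log y_j!]`` with
    ``mu_j = E_j exp(x_j' beta + u_j + s_j)`` and ``s = W v`` under the
    row-normalized multiple-membership weights.
    """
    y = np.asarray(y, float)
    E = np.asarray(E, float)
    if (E <= 0).any():
        raise ValueError("offset E must be strictly positive")
    s = _mm_smooth(weights, np.asarray(v, float))
    eta = X @ np.asarray(beta, float) + np.asarray(u, float) + s
    mu = E * np.exp(eta)
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _mm_smooth(weights: SpatialWeights, v: np.ndarray) -> np.ndarray:
    """s = W v with equal MM weights 1/|neigh(j)|; isolated cells get 0."""
    s = np.zeros(weights.n)
    for j, nb in enumerate(weights.neighbors):
        if len(nb):
            s[j] = v[nb].mean()
    return s


def draw_precision(
    rng: np.random.Generator, a: float, b: float, effects: np.ndarray
) -> float:
    """Conjugate Gibbs draw of a precision given its Normal(0, 1/tau) effects.

    Posterior is Gamma(a + m/2, rate = b + sum(effects^2)/2).  This is the
    exact update the sampler uses for both 1/sigma2_u and 1/sigma2_v.
    """
    m = len(effects)
    shape = a + 0.5 * m
    rate = b + 0.5 * float(np.sum(np.square(effects)))
    return float(rng.gamma(shape, 1.0 / rate))


def _color_blocks(weights: SpatialWeights) -> list[dict]:
    """Partition cells into color classes safe for simultaneous v updates.

    Two member effects v_l, v_m interact only if some cell has both l and m
    in its neighbor set, which requires Chebyshev(l, m) <= 2k; a periodic
    (2k+1) x (2k+1) coloring therefore separates them.  For each color we
    precompute the affected likelihood rows, their MM weight W_jl and the
    position ("owner") of the unique updated l they belong to.
    """
    P = 2 * weights.order + 1
    deg = np.array([len(nb) for nb in weights.neighbors], dtype=float)
    colors: dict[int, list[int]] = {}
    for i, (r, c) in enumerate(weights.cell_ids):
        colors.setdefault((r % P) * P + (c % P), []).append(i)

    blocks = []
    for _, idx in sorted(colors.items()):
        idx = np.array(idx, dtype=np.int64)
        rows, owner = [], []
        for pos, l in enumerate(idx):
            for j in weights.neighbors[l]:  # symmetric: l in neigh(j) <=> j in neigh(l)
                rows.append(int(j))
                owner.append(pos)
        rows = np.array(rows, dtype=np.int64)
        owner = np.array(owner, dtype=np.int64)
        if len(rows) != len(set(rows.tolist())):
            raise AssertionError("coloring violated: a row is hit twice in one block")
        blocks.append(
            {"idx": idx, "rows": rows, "owner": owner, "w": 1.0 / deg[rows] if len(rows) else np.empty(0)}
        )
    return blocks


def run_mcmc(neighborhoods: pd.DataFrame, spec: ModelSpec) -> PosteriorSample:
    """Fit the model by Metropolis-within-Gibbs MCMC.

    Only rows with ``included`` True are modelled.  Fully reproducible under
    ``spec.seed``; proposal-scale adaptation stops at the end of burn-in.
    """
    inc = neighborhoods[neighborhoods["included"]].reset_index(drop=True)
    m = len(inc)
    if m < 10:
        raise ValueError(f"need at least 10 included cells, got {m}")

    y = inc["deaths"].to_numpy(float)
    E = (
        np.asarray(spec.offset, float)
        if spec.offset is not None
        else internal_standardized_offset(neighborhoods)
    )
    if len(E) != m or (E <= 0).any():
        raise ValueError("offset must be positive with one entry per included cell")
    X = _design_matrix(inc, spec.covariate_names)
    p = X.shape[1]

    weights = build_weights(
        inc, order=spec.order, scheme="row_normalized", contiguity=spec.contiguity
    )
    blocks = _color_blocks(weights) if spec.include_v else []

    rng = np.random.default_rng(spec.seed)
    n_iter = spec.burn_in + spec.n_keep * spec.thin

    beta = np.zeros(p)
    beta[0] = np.log(y.sum() / E.sum()) if y.sum() > 0 else 0.0
    u = np.zeros(m)
    v = np.zeros(m)
    s = np.zeros(m)
    sigma2_u, sigma2_v = 0.1, 0.1

    eta = X @ beta + u + s
    mu = E * np.exp(eta)
    const_ll = float(np.sum(gammaln(y + 1.0)))

    # per-component / per-cell adaptive log proposal scales
    lscale_beta = np.full(p, np.log(0.1))
    lscale_u = np.full(m, np.log(0.5))
    lscale_v = np.full(m, np.log(0.5))

    keep_beta = np.empty((spec.n_keep, p))
    keep_u = np.empty((spec.n_keep, m))
    keep_v = np.empty((spec.n_keep, m))
    keep_s2u = np.empty(spec.n_keep)
    keep_s2v = np.empty(spec.n_keep)
    keep_dev = np.empty(spec.n_keep)

    acc_beta = np.zeros(p)
    acc_u = np.zeros(m)
    acc_v = np.zeros(m)
    n_post = 0

    for t in range(n_iter):
        adapting = t < spec.burn_in
        gamma = 1.0 / (1.0 + t) ** 0.6 if adapting else 0.0

        # --- fixed effects: componentwise random walk ---
        for c in range(p):
            delta = np.exp(lscale_beta[c]) * rng.standard_normal()
            d_eta = X[:, c] * delta
            mu_new = mu * np.exp(d_eta)
            log_alpha = float(np.sum(y * d_eta) - np.sum(mu_new - mu))
            accepted = np.log(rng.random()) < log_alpha
            if accepted:
                beta[c] += delta
                eta += d_eta
                mu = mu_new
            if adapting:
                lscale_beta[c] += gamma * (float(accepted) - ADAPT_TARGET)
            elif not adapting:
                acc_beta[c] += float(accepted)

        # --- unstructured effects: one vectorized block (conditionally indep.) ---
        if spec.include_u:
            delta = np.exp(lscale_u) * rng.standard_normal(m)
            exp_d = np.exp(delta)
            d_ll = y * delta - mu * (exp_d - 1.0)
            d_prior = -(2.0 * u * delta + delta**2) / (2.0 * sigma2_u)
            mask = np.log(rng.random(m)) < d_ll + d_prior
            u[mask] += delta[mask]
            eta[mask] += delta[mask]
            mu[mask] *= exp_d[mask]
            if adapting:
                lscale_u += gamma * (mask.astype(float) - ADAPT_TARGET)
            else:
                acc_u += mask

        # --- member effects: colored vectorized single-site Metropolis ---
        if spec.include_v:
            for blk in blocks:
                idx, rows, owner, w = blk["idx"], blk["rows"], blk["owner"], blk["w"]
                delta = np.exp(lscale_v[idx]) * rng.standard_normal(len(idx))
                if len(rows):
                    d_s = w * delta[owner]
                    exp_ds = np.exp(d_s)
                    d_ll_rows = y[rows] * d_s - mu[rows] * (exp_ds - 1.0)
                    d_ll = np.bincount(owner, weights=d_ll_rows, minlength=len(idx))
                else:
                    d_ll = np.zeros(len(idx))
                d_prior = -(2.0 * v[idx] * delta + delta**2) / (2.0 * sigma2_v)
                mask = np.log(rng.random(len(idx))) < d_ll + d_prior
                v[idx[mask]] += delta[mask]
                if len(rows):
                    row_acc = mask[owner]
                    hit = rows[row_acc]
                    d_s_acc = d_s[row_acc]
                    s[hit] += d_s_acc
                    eta[hit] += d_s_acc
                    mu[hit] *= exp_ds[row_acc]
                if adapting:
                    lscale_v[idx] += gamma * (mask.astype(float) - ADAPT_TARGET)
                else:
                    acc_v[idx] += mask

        # --- variances: conjugate Gibbs on the precisions ---
        if spec.include_u:
            sigma2_u = 1.0 / draw_precision(rng, spec.prior_a, spec.prior_b, u)
        if spec.include_v:
            sigma2_v = 1.0 / draw_precision(rng, spec.prior_a, spec.prior_b, v)

        if not adapting:
            n_post += 1
            k = t - spec.burn_in
            if (k + 1) % spec.thin == 0:
                i = k // spec.thin
                dev = -2.0 * float(np.sum(y * np.log(mu)) - np.sum(mu) - const_ll)
                if not np.isfinite(dev):
                    raise FloatingPointError(
                        "divergent chain: non-finite deviance "
                        f"(iteration {t}, beta={beta}, sigma2_u={sigma2_u:.3g}, "
                        f"sigma2_v={sigma2_v:.3g})"
                    )
                keep_beta[i] = beta
                keep_u[i] = u
                keep_v[i] = v
                keep_s2u[i] = sigma2_u
                keep_s2v[i] = sigma2_v
                keep_dev[i] = dev

    accept_rates = {
        "beta": acc_beta / max(n_post, 1),
        "u": float(acc_u.mean() / max(n_post, 1)) if spec.include_u else None,
        "v": float(acc_v.mean() / max(n_post, 1)) if spec.include_v else None,
    }
    return PosteriorSample(
        beta=keep_beta,
        u=keep_u,
        v=keep_v,
        sigma2_u=keep_s2u,
        sigma2_v=keep_s2v,
        deviance=keep_dev,
        covariate_names=list(spec.covariate_names),
        cell_ids=weights.cell_ids,
        y=y,
        E=E,
        X=X,
        weights=weights,
        accept_rates=accept_rates,
    )


def dic(sample: PosteriorSample) -> tuple[float, float]:
    """Deviance information criterion and effective number of parameters.

    ``Dbar`` is the posterior mean deviance; ``D(thetabar)`` evaluates the
    deviance at the posterior means of beta, u and v; ``pD = Dbar -
    D(thetabar)`` and ``DIC = Dbar + pD``.
    """
    if sample.n_draws == 0:
        raise ValueError("empty chain")
    d_bar = float(sample.deviance.mean())
    ll_at_mean = log_likelihood(
        sample.y,
        sample.E,
        sample.X,
        sample.beta.mean(axis=0),
        sample.u.mean(axis=0),
        sample.v.mean(axis=0),
        sample.weights,
    )
    d_hat = -2.0 * ll_at_mean
    p_d = d_bar - d_hat
    return d_bar + p_d, p_d


def _tail_p(draws: np.ndarray) -> float:
    """Two-sided Bayesian tail probability, floored at 2/(n_draws + 1)."""
    n = len(draws)
    lo = (1 + int(np.sum(draws <= 0.0))) / (n + 1)
    hi = (1 + int(np.sum(draws >= 0.0))) / (n + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def summarize(sample: PosteriorSample, p_value_method: str = "bayes_tail") -> ModelSummary:
    """Posterior summaries in the layout of a disease-mapping results table.

    Fixed effects get posterior mean, SE (posterior SD) and a two-sided
    p-value: the Bayesian tail probability 2*min(P(theta>0), P(theta<0)) by
    default, or a Wald-style 2*Phi(-|mean/SE|) with
    ``p_value_method="wald"``.  The structured variance sigma2_s is the
    posterior mean of the per-iteration empirical variance of the composite
    s_j across cells (the MM marginal variance is cell-dependent, so the
    realized-field variance is the comparable scalar), and rho_spatial is
    the posterior mean of sigma2_s / (sigma2_s + sigma2_u_emp) with both
    variances empirical per iteration.
    """
    if sample.n_draws == 0:
        raise ValueError("empty chain")
    if p_value_method not in ("bayes_tail", "wald"):
        raise ValueError("p_value_method must be 'bayes_tail' or 'wald'")
    names = ["intercept"] + sample.covariate_names
    mean = sample.beta.mean(axis=0)
    se = sample.beta.std(axis=0, ddof=1)
    if p_value_method == "bayes_tail":
        pvals = [_tail_p(sample.beta[:, j]) for j in range(sample.beta.shape[1])]
    else:
        z = np.abs(mean) / np.where(se > 0, se, np.inf)
        pvals = (2.0 * norm.sf(z)).tolist()
    fixed = pd.DataFrame({"mean": mean, "se": se, "p_value": pvals}, index=names)

    s = sample.s_draws()
    var_s = s.var(axis=1, ddof=1)
    var_u = sample.u.var(axis=1, ddof=1)
    denom = var_s + var_u
    rho = float(np.mean(np.divide(var_s, denom, out=np.zeros_like(denom), where=denom > 0)))

    dic_val, p_d = dic(sample)
    return ModelSummary(
        fixed=fixed,
        sigma2_u=float(sample.sigma2_u.mean()),
        sigma2_u_se=float(sample.sigma2_u.std(ddof=1)),
        sigma2_s=float(var_s.mean()),
        sigma2_s_se=float(var_s.std(ddof=1)),
        rho_spatial=rho,
        dic=dic_val,
        pd=p_d,
    )


def select_neighbor_order(
    neighborhoods: pd.DataFrame,
    orders: list[int],
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Refit the null model at each candidate neighbor order; compare by DIC.

    Returns a table with one row per order (DIC, pD) and a ``selected``
    column marking the argmin.  A single candidate is returned as selected
    trivially.
    """
    if len(orders) == 0:
        raise ValueError("orders must be non-empty")
    base = spec if spec is not None else ModelSpec()
    rows = []
    for k in orders:
        spec_k = ModelSpec(
            covariate_names=[],
            offset=base.offset,
            order=k,
            contiguity=base.contiguity,
            prior_a=base.prior_a,
            prior_b=base.prior_b,
            burn_in=base.burn_in,
            n_keep=base.n_keep,
            thin=base.thin,
            seed=base.seed,
        )
        sample = run_mcmc(neighborhoods, spec_k)
        dic_val, p_d = dic(sample)
        rows.append({"order": k, "dic": dic_val, "pd": p_d})
    out = pd.DataFrame(rows)
    out["selected"] = out["dic"] == out["dic"].min()
    return out
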