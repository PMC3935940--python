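"""Global Moran's I with Monte-Carlo permutation inference.

Moran's I measures spatial autocorrelation of a per-cell variable x:

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S0 = sum_ij w_ij.  Under no spatial structure E[I] = -1/(n-1).
Significance is assessed by randomly permuting the values across cells and
comparing the observed statistic to the permutation distribution; the default
is the one-sided upper tail (positive autocorrelation, i.e. clustering).

The statistic defaults to binary contiguity weights; row-standardized weights
are available through the ``SpatialWeights`` scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .geo_grid import SpatialWeights


@dataclass
class MoranResult:
    I: float
    expected_I: float
    p_perm: float
    n_perm: int
    n: int
    alternative: str = "greater"

    def to_dict(self) -> dict:
        return asdict(self)


def _check_inputs(x: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != weights.n:
        raise ValueError(
            f"x must be 1-d with one value per cell ({weights.n}), got shape {x.shape}"
        )
    if not np.isfinite(x).all():
        raise ValueError("x contains non-finite values")
    non_isolated = (~weights.isolated).sum()
    if non_isolated == 0:
        raise ValueError("all cells are isolated; Moran's I is undefined")
    if non_isolated < 3:
        raise ValueError("need at least 3 non-isolated cells")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; Moran's I denominator is zero")
    return x


def morans_i(x: np.ndarray, weights: SpatialWeights) -> float:
    """Moran's I of per-cell values ``x`` under ``weights``."""
    x = _check_inputs(x, weights)
    W = weights.to_sparse()
    return _morans_i_sparse(x, W)


def _morans_i_sparse(x: np.ndarray, W) -> float:
    n = len(x)
    z = x - x.mean()
    s0 = W.sum()
    num = float(z @ (W @ z))
    den = float(z @ z)
    return (n / s0) * (num / den)


def permutation_test(
    x: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    alternative: str = "greater",
) -> MoranResult:
    """Permutation test for Moran's I.

    Values are shuffled uniformly at random across cells ``n_perm`` times and

        p = (1 + #{I_perm at least as extreme as I_obs}) / (n_perm + 1)

    so the smallest attainable p is 1/(n_perm+1).  ``alternative`` is
    ``"greater"`` (clustering; default), ``"less"`` or ``"two-sided"``
    (extremity measured as |I - E[I]|).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
    x = _check_inputs(x, weights)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    W = weights.to_sparse()
    n = len(x)
    i_obs = _morans_i_sparse(x, W)
    e_i = -1.0 / (n - 1)

    i_perm = np.empty(n_perm)
    for k in range(n_perm):
        i_perm[k] = _morans_i_sparse(x[rng.permutation(n)], W)

    if alternative == "greater":
        extreme = i_perm >= i_obs
    elif alternative == "less":
        extreme = i_perm <= i_obs
    else:
        extreme = np.abs(i_perm - e_i) >= abs(i_obs - e_i)
    p = (1.0 + int(extreme.sum())) / (n_perm + 1.0)

    return MoranResult(
        I=float(i_obs),
        expected_I=e_i,
        p_perm=float(p),
        n_perm=n_perm,
        n=n,
        alternative=alternative,
    )


def empirical_bayes_rates(
    deaths: np.ndarray, person_years: np.ndarray
) -> np.ndarray:
    """Empirical-Bayes (method-of-moments) smoothed rates.

    Shrinks crude per-cell rates toward the global rate in proportion to
    person-time, stabilising small-denominator cells before autocorrelation
    testing.  Optional alternative to crude rates.
    """
    deaths = np.asarray(deaths, float)
    py = np.asarray(person_years, float)
    if (py <= 0).any():
        raise ValueError("person_years must be positive")
    m = deaths.sum() / py.sum()
    crude = deaths / py
    # moment estimate of between-cell variance of the true rates
    a = np.average((crude - m) ** 2, weights=py) - m / py.mean()
    a = max(a, 0.0)
    shrink = a / (a + m / py)
    return m + shrink * (crude - m)
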