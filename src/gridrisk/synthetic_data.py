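"""Synthetic household / person / death tables with known ground truth.

Emulates the structure of a two-year demographic-surveillance dataset over a
rectangular coastal study area: households are georeferenced points from a
clustered (Neyman-Scott) point process, prime-age occupants (15 to <45 years)
are attached to households, and per-cell death counts are drawn from the same
Poisson log-linear model the inference modules fit —

    deaths_j ~ Poisson(E_j * exp(x_j' beta + u_j + s_j))

with E_j = person-years x baseline rate, unstructured effects
u_j ~ N(0, sigma2_u), and structured effects s_j built by the
multiple-membership rule from member effects v_l ~ N(0, sigma2_v)
(isolated cells get s_j = 0).  Every generator parameter is therefore a
known truth for parameter-recovery and calibration tests downstream.

Household covariates carry spatial gradients (tap-water use declining
eastward, schooling rising eastward, river distance from a mid-region river
line) so that aggregated neighborhood covariates vary in space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_grid import SEXES, SpatialWeights, assign_cells, build_neighborhoods, build_weights

__all__ = ["SimConfig", "simulate_households", "simulate_persons", "simulate_deaths", "simulate_dataset"]

#: Total-column cause-of-death distribution used for simulated causes
#: (reference two-site tabulation; see the tables module for the full counts).
DEFAULT_CAUSE_DISTRIBUTION = {
    "Traffic accident": 49 / 115,
    "Drowning": 12 / 115,
    "Cardiovascular disease (CVD)": 8 / 115,
    "Suicide": 7 / 115,
    "Cancer": 7 / 115,
    "Others": 6 / 115,
    "Fall from height": 5 / 115,
    "Sudden death, unknown cause": 5 / 115,
    "Respiratory disease": 5 / 115,
    "Hepatic failure": 3 / 115,
    "Intracranial injury": 3 / 115,
    "Food poisoning": 1 / 115,
    "Diabetes mellitus": 1 / 115,
    "Inflammatory polyneuropathy": 1 / 115,
    "Intracerebral haemorrhage": 1 / 115,
    "Tetanus": 1 / 115,
}

#: Projected-CRS offset so simulated coordinates resemble UTM eastings /
#: northings and never look geographic.
COORD_OFFSET = (600_000.0, 1_200_000.0)


@dataclass
class SimConfig:
    """Generator settings.

    ``beta`` maps covariate names (columns of the neighborhood table) to
    log-linear coefficients; ``"intercept"`` is the log baseline death rate
    per person-year.  The default baseline of 1.2 per 1000 person-years sits
    between typical prime-age male (1.6-1.8) and female (0.5-0.7) rates per
    1000, giving realistically sparse counts.  The default observation
    window is two years.
    """

    seed: int = 0
    region_km: tuple[float, float] = (10.0, 10.0)
    n_households: int = 20_000
    persons_per_household: float = 2.0
    years: float = 2.0
    beta: dict[str, float] = field(
        default_factory=lambda: {"intercept": float(np.log(0.0012))}
    )
    sigma2_u: float = 0.0
    sigma2_v: float = 0.0
    cell_size_m: float = 500.0
    min_households: int = 4
    order: int = 1
    cause_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAUSE_DISTRIBUTION)
    )
    cluster_density_per_km2: float = 3.0
    cluster_sd_m: float = 300.0

    def __post_init__(self) -> None:
        if self.sigma2_u < 0 or self.sigma2_v < 0:
            raise ValueError("variances must be non-negative")
        total = sum(self.cause_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cause probabilities must sum to 1, got {total}")
        if "intercept" not in self.beta:
            raise ValueError("beta must contain an 'intercept' entry")


def simulate_households(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Clustered household points with spatially graded covariates.

    Neyman-Scott process: Poisson-distributed parent locations, households
    scattered around a uniformly chosen parent with isotropic Gaussian
    spread, then clipped to the region.  This makes grid-cell household
    counts heterogeneous, as in real settlements.
    """
    if cfg.n_households <= 0:
        raise ValueError("n_households must be positive")
    if cfg.region_km[0] <= 0 or cfg.region_km[1] <= 0:
        raise ValueError("region dimensions must be positive")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    wx, wy = cfg.region_km[0] * 1000.0, cfg.region_km[1] * 1000.0
    area_km2 = cfg.region_km[0] * cfg.region_km[1]
    n_parents = max(1, rng.poisson(cfg.cluster_density_per_km2 * area_km2))
    px = rng.uniform(0, wx, n_parents)
    py = rng.uniform(0, wy, n_parents)

    parent = rng.integers(0, n_parents, cfg.n_households)
    x = np.clip(px[parent] + rng.normal(0, cfg.cluster_sd_m, cfg.n_households), 0, wx)
    y = np.clip(py[parent] + rng.normal(0, cfg.cluster_sd_m, cfg.n_households), 0, wy)

    xf = x / wx  # 0..1 west->east, drives the covariate gradients
    head_male = rng.random(cfg.n_households) < 0.75
    schooling = rng.poisson(4.0 + 4.0 * xf)
    p_tap = np.clip(0.85 - 0.55 * xf, 0.05, 0.95)
    is_tap = rng.random(cfg.n_households) < p_tap
    others = rng.choice(["well", "pump", "vendor", "river", "other"], cfg.n_households)
    water = np.where(is_tap, "tap", others)

    river_y = wy / 2.0
    dist_river = np.abs(y - river_y) / 1000.0
    hx, hy = wx * 0.4, wy * 0.6  # single health facility
    dist_health = np.hypot(x - hx, y - hy) / 1000.0

    return pd.DataFrame(
        {
            "household_id": np.arange(cfg.n_households),
            "x": x + COORD_OFFSET[0],
            "y": y + COORD_OFFSET[1],
            "head_sex": np.where(head_male, "male", "female"),
            "head_schooling_years": schooling,
            "water_source": water,
            "dist_river_km": dist_river,
            "dist_health_km": dist_health,
        }
    )


def simulate_persons(
    households: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Prime-age occupants per household; Poisson household sizes, uniform
    ages in [15, 45), full observation window of person-time, no deaths yet."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    sizes = rng.poisson(cfg.persons_per_household, len(households))
    hh_ids = np.repeat(households["household_id"].to_numpy(), sizes)
    n = len(hh_ids)
    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "household_id": hh_ids,
            "sex": rng.choice(SEXES, n),
            "age_years": rng.integers(15, 45, n),
            "person_years": np.full(n, float(cfg.years)),
            "died": np.zeros(n, dtype=bool),
            "cause": pd.array([None] * n, dtype="string"),
        }
    )


def simulate_deaths(
    neighborhoods: pd.DataFrame,
    weights: SpatialWeights,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Per-cell death counts from the Poisson log-linear ground truth.

    Only included cells receive a positive intensity.  Returns the death
    counts aligned with the included rows of ``neighborhoods`` plus a truth
    dictionary (u, v, s, linear predictor, expected counts) for recovery
    tests.  Counts are capped at the stratum population.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    inc = neighborhoods[neighborhoods["included"]].reset_index(drop=True)
    m = len(inc)
    if weights.n != m:
        raise ValueError("weights do not match the included cells")

    u = rng.normal(0.0, np.sqrt(cfg.sigma2_u), m) if cfg.sigma2_u > 0 else np.zeros(m)
    v = rng.normal(0.0, np.sqrt(cfg.sigma2_v), m) if cfg.sigma2_v > 0 else np.zeros(m)
    s = np.zeros(m)
    for j, nb in enumerate(weights.neighbors):
        if len(nb):
            s[j] = v[nb].mean()

    eta = np.full(m, cfg.beta["intercept"])
    for name, coef in cfg.beta.items():
        if name == "intercept":
            continue
        if name not in inc.columns:
            raise ValueError(f"beta refers to unknown covariate column '{name}'")
        eta = eta + coef * inc[name].to_numpy(float)
    E = inc["person_years"].to_numpy(float)
    lam = E * np.exp(eta + u + s)
    deaths = rng.poisson(lam)
    deaths = np.minimum(deaths, inc["population"].to_numpy(int))
    truth = {
        "u": u,
        "v": v,
        "s": s,
        "eta_fixed": eta,
        "lambda": lam,
        "E": E,
        "cell_ids": list(weights.cell_ids),
    }
    return deaths, truth


def _attribute_deaths(
    persons: pd.DataFrame,
    households: pd.DataFrame,
    sex: str,
    cell_ids: list[tuple[int, int]],
    deaths: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mark randomly chosen stratum occupants of each cell as deceased and
    draw their causes from the configured distribution."""
    persons = persons.copy()
    merged = persons.merge(
        households[["household_id", "cell_row", "cell_col"]], on="household_id"
    )
    causes = list(cfg.cause_distribution)
    probs = np.array([cfg.cause_distribution[c] for c in causes])
    by_cell = merged[merged["sex"] == sex].groupby(["cell_row", "cell_col"])
    groups = {k: g["person_id"].to_numpy() for k, g in by_cell}
    chosen_all: list[np.ndarray] = []
    for cid, k in zip(cell_ids, deaths):
        if k == 0:
            continue
        pool = groups[cid]
        chosen_all.append(rng.choice(pool, size=min(int(k), len(pool)), replace=False))
    if chosen_all:
        chosen = np.concatenate(chosen_all)
        pos = persons.index[persons["person_id"].isin(chosen)]
        persons.loc[pos, "died"] = True
        persons.loc[pos, "cause"] = rng.choice(causes, size=len(pos), p=probs)
    return persons


def simulate_dataset(cfg: SimConfig) -> dict:
    """Full synthetic study: households, occupants, sex-stratified
    neighborhoods with simulated deaths, contiguity weights and truth.

    Returns a dict with keys ``households`` (cell-assigned), ``persons``
    (death flags and causes set), ``neighborhoods``/``weights``/``truth``
    (each a per-sex dict).  Deterministic under ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_h, rng_p, rng_m, rng_f = (np.random.default_rng(c) for c in ss.spawn(4))

    households = simulate_households(cfg, rng_h)
    households = assign_cells(households, cfg.cell_size_m)
    persons = simulate_persons(households, cfg, rng_p)

    neighborhoods: dict[str, pd.DataFrame] = {}
    weights: dict[str, SpatialWeights] = {}
    truth: dict[str, dict] = {}
    for sex, rng in (("male", rng_m), ("female", rng_f)):
        nbhd = build_neighborhoods(households, persons, sex, cfg.min_households)
        w = build_weights(nbhd, order=cfg.order, scheme="row_normalized")
        deaths, tr = simulate_deaths(nbhd, w, cfg, rng)
        persons = _attribute_deaths(
            persons, households, sex, w.cell_ids, deaths, cfg, rng
        )
        # re-aggregate so cell death counts reflect the attributed persons
        nbhd = build_neighborhoods(households, persons, sex, cfg.min_households)
        neighborhoods[sex] = nbhd
        weights[sex] = w
        truth[sex] = tr
    return {
        "households": households,
        "persons": persons,
        "neighborhoods": neighborhoods,
        "weights": weights,
        "truth": truth,
        "config": cfg,
    }
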