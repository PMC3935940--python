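import numpy as np
import pandas as pd
import pytest

from gridrisk import ModelSpec, run_mcmc
from gridrisk.synthetic_data import SimConfig, simulate_dataset


def make_grid_cells(shape=(3, 3), included=None):
    """Fabricate a neighborhood table covering a full rows x cols grid."""
    rows, cols = shape
    recs = []
    for r in range(rows):
        for c in range(cols):
            recs.append(
                {
                    "cell_row": r,
                    "cell_col": c,
                    "included": True if included is None else included[(r, c)],
                }
            )
    return pd.DataFrame(recs)


def make_poisson_cells(
    shape=(10, 10),
    mean_E=8.0,
    beta0=0.0,
    seed=0,
    rate_bump: dict | None = None,
):
    """Fabricate included cells with Poisson deaths at relative risk exp(beta0).

    ``rate_bump`` maps cell ids to an additive log-risk offset (e.g. log 2
    to double one cell's intensity).  Returns a table ready for run_mcmc,
    with person_years such that internal standardization gives E ~ mean_E.
    """
    rng = np.random.default_rng(seed)
    cells = make_grid_cells(shape)
    m = len(cells)
    py = rng.uniform(0.6, 1.4, m) * mean_E
    eta = np.full(m, beta0)
    if rate_bump:
        for cid, bump in rate_bump.items():
            i = cells.index[
                (cells.cell_row == cid[0]) & (cells.cell_col == cid[1])
            ][0]
            eta[i] += bump
    deaths = rng.poisson(py * np.exp(eta))
    cells["person_years"] = py
    cells["deaths"] = deaths
    cells["population"] = np.maximum(deaths, 1) * 10
    cells["n_households"] = 10
    return cells


POWERED_CONFIG = SimConfig(
    seed=5,
    n_households=15_000,
    region_km=(8.0, 8.0),
    persons_per_household=3.0,
    beta={"intercept": float(np.log(0.02)), "pct_head_schooled": -0.02},
    sigma2_u=0.05,
    sigma2_v=0.2,
)


@pytest.fixture(scope="session")
def powered_dataset():
    """Well-powered synthetic study (~270 included cells, ~1 death/cell)."""
    return simulate_dataset(POWERED_CONFIG)


@pytest.fixture(scope="session")
def fitted_sample(powered_dataset):
    """Covariate-model fit on the powered dataset, adequate chain length."""
    nbhd = powered_dataset["neighborhoods"]["male"]
    spec = ModelSpec(
        covariate_names=["pct_head_schooled"],
        burn_in=4_000,
        n_keep=4_000,
        seed=11,
    )
    return run_mcmc(nbhd, spec)
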