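"""Grid neighborhoods from georeferenced household points.

Households located by projected (metric) coordinates are binned into square
grid cells ("neighborhoods"), person-level records are aggregated per cell and
sex stratum, and an order-k contiguity structure is built over the included
cells.  The areal unit produced here is what every downstream stage (Moran's I,
the multiple-membership model, the risk map) operates on.

Conventions
-----------
* Cells are half-open intervals ``[lower, upper)`` in both axes, anchored at
  the bounding-box minimum corner by default, so cell assignment is a
  partition of the points.
* A cell is *included* in the analysis when it holds at least
  ``min_households`` households and at least one person of the stratum sex;
  cells below the threshold are kept in the table with ``included = False``
  so exclusion is transparent.
* Cell-level covariates are aggregated over **all** households in the cell,
  while deaths, population and person-time are stratum specific.
* Contiguity is queen (8-neighbor, Chebyshev distance 1) by default; rook
  (4-neighbor) is available.  Order-k extends queen contiguity to Chebyshev
  distance <= k and rook to Manhattan distance <= k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

HOUSEHOLD_COLUMNS = (
    "household_id",
    "x",
    "y",
    "head_sex",
    "head_schooling_years",
    "water_source",
    "dist_river_km",
    "dist_health_km",
)

PERSON_COLUMNS = (
    "person_id",
    "household_id",
    "sex",
    "age_years",
    "person_years",
    "died",
)

#: Cell-level covariates produced by :func:`build_neighborhoods`.
COVARIATE_COLUMNS = (
    "pct_male_head",
    "pct_head_schooled",
    "pct_tap_water",
    "mean_dist_river_km",
    "mean_dist_health_km",
)

SEXES = ("male", "female")
WATER_SOURCES = ("tap", "well", "pump", "vendor", "river", "other")

#: Schooling-years threshold treated as a literate household head.
SCHOOLING_LITERACY_YEARS = 5

#: Analysis age window, years (inclusive lower, exclusive upper).
AGE_WINDOW = (15, 45)


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing columns: {missing}")


def validate_households(households: pd.DataFrame) -> None:
    """Check the household table invariants; raise ``ValueError`` on breach."""
    _require_columns(households, HOUSEHOLD_COLUMNS, "household")
    if households["household_id"].duplicated().any():
        raise ValueError("household_id values must be unique")
    xy = households[["x", "y"]].to_numpy(float)
    if not np.isfinite(xy).all():
        raise ValueError("household coordinates must be finite")
    for col in ("dist_river_km", "dist_health_km"):
        if (households[col] < 0).any():
            raise ValueError(f"{col} must be non-negative")
    bad_sex = set(households["head_sex"].unique()) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown head_sex values: {sorted(bad_sex)}")


def validate_persons(persons: pd.DataFrame, households: pd.DataFrame) -> None:
    """Check the person table invariants against its household table."""
    _require_columns(persons, PERSON_COLUMNS, "person")
    if len(persons) == 0:
        raise ValueError("person table is empty")
    if (persons["person_years"] <= 0).any():
        raise ValueError("person_years must be positive")
    lo, hi = AGE_WINDOW
    ages = persons["age_years"]
    if ((ages < lo) | (ages >= hi)).any():
        raise ValueError(f"age_years must lie in [{lo}, {hi})")
    unknown = ~persons["household_id"].isin(households["household_id"])
    if unknown.any():
        raise ValueError(
            f"{int(unknown.sum())} persons reference unknown household_id values"
        )


def assign_cells(
    households: pd.DataFrame,
    cell_size_m: float = 500.0,
    origin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Assign each household to a grid cell.

    Parameters
    ----------
    households
        Table with projected metric ``x``/``y`` coordinates.
    cell_size_m
        Cell edge length in meters (default 500 m).
    origin
        Optional ``(x0, y0)`` grid anchor; defaults to the bounding-box
        minimum corner.  Exposed for grid-placement sensitivity checks.

    Returns
    -------
    A copy of ``households`` with integer ``cell_row`` and ``cell_col``
    columns, ``cell_row = floor((y - y0)/cell_size_m)`` and likewise for
    columns.  Cells are half-open, so a point on a shared edge belongs to the
    higher-index cell and the assignment is a partition.
    """
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be positive")
    _require_columns(households, ("x", "y"), "household")
    x = households["x"].to_numpy(float)
    y = households["y"].to_numpy(float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("household coordinates must be finite")
    if len(x) and np.abs(x).max() <= 180.0 and np.abs(y).max() <= 90.0:
        raise ValueError(
            "coordinates look geographic (|x| <= 180, |y| <= 90); "
            "a projected CRS in meters is required"
        )
    if origin is None:
        origin = (float(x.min()), float(y.min())) if len(x) else (0.0, 0.0)
    x0, y0 = origin
    out = households.copy()
    out["cell_row"] = np.floor((y - y0) / cell_size_m).astype(np.int64)
    out["cell_col"] = np.floor((x - x0) / cell_size_m).astype(np.int64)
    return out


def build_neighborhoods(
    households: pd.DataFrame,
    persons: pd.DataFrame,
    sex: str,
    min_households: int = 4,
) -> pd.DataFrame:
    """Aggregate households and persons of one sex stratum into grid cells.

    ``households`` must already carry ``cell_row``/``cell_col`` (see
    :func:`assign_cells`).  One record is produced per cell with at least one
    household.  ``included`` is False when the cell has fewer than
    ``min_households`` households or no occupant of the stratum sex.

    Covariates (percent male household head, percent heads with >=
    ``SCHOOLING_LITERACY_YEARS`` years of schooling, percent of households on
    tap water, mean distances to river and health facility) are computed from
    all households in the cell; ``population``, ``person_years`` and
    ``deaths`` come from the stratum only.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    _require_columns(households, ("cell_row", "cell_col"), "household")
    validate_households(households.drop(columns=["cell_row", "cell_col"]))
    validate_persons(persons, households)

    hh = households.set_index("household_id")
    p = persons.merge(
        households[["household_id", "cell_row", "cell_col"]],
        on="household_id",
        how="left",
    )

    key = ["cell_row", "cell_col"]
    hh_g = households.groupby(key)
    agg = pd.DataFrame(
        {
            "n_households": hh_g.size(),
            "pct_male_head": 100.0 * hh_g["head_sex"].agg(lambda s: (s == "male").mean()),
            "pct_head_schooled": 100.0
            * hh_g["head_schooling_years"].agg(
                lambda s: (s >= SCHOOLING_LITERACY_YEARS).mean()
            ),
            "pct_tap_water": 100.0 * hh_g["water_source"].agg(lambda s: (s == "tap").mean()),
            "mean_dist_river_km": hh_g["dist_river_km"].mean(),
            "mean_dist_health_km": hh_g["dist_health_km"].mean(),
        }
    )

    stratum = p[p["sex"] == sex]
    s_g = stratum.groupby(key)
    agg["population"] = s_g.size().reindex(agg.index, fill_value=0).astype(int)
    agg["person_years"] = s_g["person_years"].sum().reindex(agg.index, fill_value=0.0)
    agg["deaths"] = (
        s_g["died"].sum().reindex(agg.index, fill_value=0).astype(int)
    )
    agg["sex_stratum"] = sex
    agg["included"] = (agg["n_households"] >= min_households) & (agg["population"] > 0)

    agg = agg.reset_index()
    cols = [
        "cell_row",
        "cell_col",
        "sex_stratum",
        "n_households",
        "population",
        "person_years",
        "deaths",
        *COVARIATE_COLUMNS,
        "included",
    ]
    return agg[cols]


@dataclass
class SpatialWeights:
    """Order-k grid contiguity over the included cells.

    ``cell_ids`` fixes the cell ordering used by every vector quantity
    downstream; ``neighbors[i]`` holds indices (into ``cell_ids``) of the
    neighbors of cell i.  ``scheme`` is ``"binary"`` (w_ij = 1) or
    ``"row_normalized"`` (w_ij = 1/|neigh(i)|, the multiple-membership
    weighting).  Isolated cells are retained with empty neighbor lists.
    """

    cell_ids: list[tuple[int, int]]
    neighbors: list[np.ndarray]
    order: int
    scheme: str
    contiguity: str = "queen"
    isolated: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.isolated = np.array([len(nb) == 0 for nb in self.neighbors])

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    def weight_row(self, i: int) -> np.ndarray:
        nb = self.neighbors[i]
        if self.scheme == "row_normalized" and len(nb):
            return np.full(len(nb), 1.0 / len(nb))
        return np.ones(len(nb))

    def to_sparse(self) -> sparse.csr_matrix:
        """Weights as an n x n CSR matrix in the ``cell_ids`` ordering."""
        rows, cols, vals = [], [], []
        for i, nb in enumerate(self.neighbors):
            rows.extend([i] * len(nb))
            cols.extend(nb.tolist())
            vals.extend(self.weight_row(i).tolist())
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n, self.n), dtype=float
        )

    def edge_list(self) -> pd.DataFrame:
        """Sparse edge list (i_row, i_col, j_row, j_col, w) for CSV export."""
        recs = []
        for i, nb in enumerate(self.neighbors):
            w = self.weight_row(i)
            for j, wij in zip(nb, w):
                recs.append((*self.cell_ids[i], *self.cell_ids[int(j)], wij))
        return pd.DataFrame(
            recs, columns=["i_row", "i_col", "j_row", "j_col", "w"]
        )


def build_weights(
    cells: pd.DataFrame,
    order: int = 1,
    scheme: str = "binary",
    contiguity: str = "queen",
) -> SpatialWeights:
    """Build order-k contiguity weights over the included cells.

    Queen contiguity links cells at Chebyshev distance <= ``order`` (8
    neighbors at order 1 on a full grid); rook uses Manhattan distance
    (4 neighbors at order 1).  Only rows of ``cells`` with ``included`` True
    participate; isolated cells keep an empty neighbor list and are flagged.
    """
    if order < 1:
        raise ValueError("order must be a positive integer")
    if scheme not in ("binary", "row_normalized"):
        raise ValueError("scheme must be 'binary' or 'row_normalized'")
    if contiguity not in ("queen", "rook"):
        raise ValueError("contiguity must be 'queen' or 'rook'")

    inc = cells[cells["included"]] if "included" in cells.columns else cells
    ids = [
        (int(r), int(c))
        for r, c in zip(inc["cell_row"].to_numpy(), inc["cell_col"].to_numpy())
    ]
    index = {cid: i for i, cid in enumerate(ids)}
    if len(index) != len(ids):
        raise ValueError("duplicate cell ids among included cells")

    # enumerate the order-k stencil once
    offsets = []
    for dr in range(-order, order + 1):
        for dc in range(-order, order + 1):
            if dr == 0 and dc == 0:
                continue
            dist = max(abs(dr), abs(dc)) if contiguity == "queen" else abs(dr) + abs(dc)
            if dist <= order:
                offsets.append((dr, dc))

    neighbors = []
    for r, c in ids:
        nb = [index[(r + dr, c + dc)] for dr, dc in offsets if (r + dr, c + dc) in index]
        neighbors.append(np.array(sorted(nb), dtype=np.int64))
    return SpatialWeights(
        cell_ids=ids, neighbors=neighbors, order=order, scheme=scheme, contiguity=contiguity
    )


def cell_polygon(
    cell_id: tuple[int, int], cell_size_m: float, origin: tuple[float, float]
) -> list[list[float]]:
    """Closed exterior ring of a cell square, GeoJSON coordinate order."""
    r, c = cell_id
    x0, y0 = origin
    xa, ya = x0 + c * cell_size_m, y0 + r * cell_size_m
    xb, yb = xa + cell_size_m, ya + cell_size_m
    return [[xa, ya], [xb, ya], [xb, yb], [xa, yb], [xa, ya]]
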