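"""Spatially smoothed relative risk (SSRR) surfaces and risk maps.

The SSRR of neighborhood j is the posterior mean of

    exp(x_j' beta + u_j + s_j)

over the kept MCMC draws.  Under internal standardization this is the risk
of cell j relative to the study-wide rate.  Surfaces are classified into the
four conventional 0.50-wide bands (<=0.50, 0.51-1.00, 1.01-1.50 moderate,
>=1.51 high) and exported as GeoJSON plus a static choropleth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geo_grid import cell_polygon
from .mmmc import PosteriorSample

RISK_CLASSES = ("<=0.50", "0.51-1.00", "1.01-1.50", ">=1.51")

#: Fixed 4-color legend (low -> high risk).
CLASS_COLORS = {
    "<=0.50": "#2c7bb6",
    "0.51-1.00": "#abd9e9",
    "1.01-1.50": "#fdae61",
    ">=1.51": "#d7191c",
}


def classify(values: np.ndarray) -> np.ndarray:
    """Assign each positive SSRR to one of the four 0.50-wide risk bands.

    Values are rounded half-up to two decimals first (explicit
    floor(100 v + 0.5) rule, avoiding float half-even rounding), so the
    interval labels 0.51-1.00 etc. partition (0, inf) exhaustively:
    1.004 -> 1.00 -> "0.51-1.00"; 1.006 -> 1.01 -> "1.01-1.50" (moderate);
    1.51 and above -> ">=1.51" (high).
    """
    v = np.atleast_1d(np.asarray(values, dtype=float))
    if (v <= 0).any() or not np.isfinite(v).all():
        raise ValueError("SSRR values must be positive and finite")
    r = np.floor(100.0 * v + 0.5) / 100.0  # round half up to 2 decimals
    out = np.empty(v.shape, dtype=object)
    out[r <= 0.50] = RISK_CLASSES[0]
    out[(r > 0.50) & (r <= 1.00)] = RISK_CLASSES[1]
    out[(r > 1.00) & (r <= 1.50)] = RISK_CLASSES[2]
    out[r > 1.50] = RISK_CLASSES[3]
    return out


def ssrr(
    sample: PosteriorSample,
    include_covariates: bool = True,
    ci: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Per-cell SSRR with credible interval and risk class.

    ``include_covariates=False`` maps residual risk only
    (exp(beta0 + u + s)), leaving the covariate contribution out.
    """
    if sample.n_draws == 0:
        raise ValueError("empty chain")
    if include_covariates:
        lin = sample.beta @ sample.X.T  # (n_keep, m)
    else:
        lin = np.outer(sample.beta[:, 0], np.ones(len(sample.cell_ids)))
    rr = np.exp(lin + sample.u + sample.s_draws())
    lo, hi = np.percentile(rr, ci, axis=0)
    out = pd.DataFrame(
        {
            "cell_row": [c[0] for c in sample.cell_ids],
            "cell_col": [c[1] for c in sample.cell_ids],
            "ssrr": rr.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
        }
    )
    out["risk_class"] = classify(out["ssrr"].to_numpy())
    return out


def export_map(
    surface: pd.DataFrame,
    cell_size_m: float,
    origin: tuple[float, float],
    geojson_path: str | Path | None = None,
    png_path: str | Path | None = None,
) -> dict:
    """Write the risk surface as a GeoJSON FeatureCollection and a choropleth.

    Each included cell becomes one square Polygon feature carrying ssrr,
    risk_class and the credible interval.  Returns the FeatureCollection
    dict; files are only written for the paths given.
    """
    features = []
    for rec in surface.to_dict("records"):
        cid = (int(rec["cell_row"]), int(rec["cell_col"]))
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [cell_polygon(cid, cell_size_m, origin)],
                },
                "properties": {
                    "cell_row": cid[0],
                    "cell_col": cid[1],
                    "ssrr": float(rec["ssrr"]),
                    "ci_low": float(rec["ci_low"]),
                    "ci_high": float(rec["ci_high"]),
                    "risk_class": rec["risk_class"],
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if geojson_path is not None:
        Path(geojson_path).write_text(json.dumps(collection))
    if png_path is not None:
        _plot_choropleth(surface, cell_size_m, origin, png_path)
    return collection


def _plot_choropleth(
    surface: pd.DataFrame,
    cell_size_m: float,
    origin: tuple[float, float],
    png_path: str | Path,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch, Rectangle

    fig, ax = plt.subplots(figsize=(7, 6))
    for rec in surface.to_dict("records"):
        ring = cell_polygon(
            (int(rec["cell_row"]), int(rec["cell_col"])), cell_size_m, origin
        )
        ax.add_patch(
            Rectangle(
                ring[0],
                cell_size_m,
                cell_size_m,
                facecolor=CLASS_COLORS[rec["risk_class"]],
                edgecolor="white",
                linewidth=0.2,
            )
        )
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_xlabel("easting (m)")
    ax.set_ylabel("northing (m)")
    handles = [Patch(facecolor=CLASS_COLORS[c], label=c) for c in RISK_CLASSES]
    ax.legend(handles=handles, title="SSRR", loc="upper right", fontsize=8)
    fig.savefig(png_path, dpi=150, metadata={"Title": "SSRR " + ",".join(RISK_CLASSES)})
    plt.close(fig)


def load_map(geojson_path: str | Path) -> pd.DataFrame:
    """Read an exported risk map back into a surface table."""
    data = json.loads(Path(geojson_path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError("not a GeoJSON FeatureCollection")
    rows = [f["properties"] for f in data["features"]]
    return pd.DataFrame(rows)
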