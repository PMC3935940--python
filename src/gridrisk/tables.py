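"""Descriptive outputs: cause-of-death tabulation and age-sex rate tables.

``cause_table`` reproduces the layout of a standard surveillance
cause-of-death table — counts and within-column percentages for males,
females and the total, rows sorted by total count — and
``rate_by_age_sex`` computes mortality rates per 1000 person-years by
5-year age band and sex.  Percentages use round-half-up, applied once at
presentation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geo_grid import SEXES

__all__ = [
    "REFERENCE_CAUSE_COUNTS",
    "cause_table",
    "validate_cause_table",
    "reference_death_records",
    "rate_by_age_sex",
    "to_markdown",
]

#: Reference male/female cause-of-death counts from a two-site Vietnamese
#: prime-age mortality surveillance tabulation (92 male + 23 female = 115
#: deaths with a recorded cause).  The published food-poisoning row was
#: internally inconsistent (2 + 0 printed against a total of 1); the male
#: count is 1 here so the column totals hold.
REFERENCE_CAUSE_COUNTS: dict[str, tuple[int, int]] = {
    "Traffic accident": (42, 7),
    "Drowning": (11, 1),
    "Cardiovascular disease (CVD)": (6, 2),
    "Suicide": (3, 4),
    "Cancer": (4, 3),
    "Others": (5, 1),
    "Fall from height": (5, 0),
    "Sudden death, unknown cause": (1, 4),
    "Respiratory disease": (4, 1),
    "Hepatic failure": (3, 0),
    "Intracranial injury": (3, 0),
    "Food poisoning": (1, 0),
    "Diabetes mellitus": (1, 0),
    "Inflammatory polyneuropathy": (1, 0),
    "Intracerebral haemorrhage": (1, 0),
    "Tetanus": (1, 0),
}


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round to the nearest integer with halves rounded up (floor(x + 0.5)).

    Intended for non-negative percentages; avoids float half-even rounding.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def cause_table(deaths: pd.DataFrame) -> pd.DataFrame:
    """Tabulate deaths by cause and sex with within-column percentages.

    ``deaths`` needs ``cause`` (non-empty label) and ``sex`` columns, one
    row per death.  Percentages are round-half-up integers of
    100 * n / column_total.  Rows are sorted by total count descending,
    ties broken alphabetically; a ``Total`` footer row closes the table.
    """
    if len(deaths) == 0:
        raise ValueError("no deaths to tabulate")
    for col in ("cause", "sex"):
        if col not in deaths.columns:
            raise ValueError(f"deaths table needs a '{col}' column")
    if deaths["cause"].isna().any() or (deaths["cause"].astype(str) == "").any():
        raise ValueError("every death needs a non-empty cause label")
    bad = set(deaths["sex"].unique()) - set(SEXES)
    if bad:
        raise ValueError(f"unknown sex values: {sorted(bad)}")

    counts = (
        deaths.groupby(["cause", "sex"]).size().unstack("sex", fill_value=0)
    )
    for sex in SEXES:
        if sex not in counts.columns:
            counts[sex] = 0
    tab = pd.DataFrame(
        {
            "male_n": counts["male"],
            "female_n": counts["female"],
        }
    )
    tab["total_n"] = tab["male_n"] + tab["female_n"]
    # alphabetical pass first so the stable count sort breaks ties by label
    tab = tab.sort_index(key=lambda s: s.str.lower()).sort_values(
        "total_n", ascending=False, kind="stable"
    )
    totals = tab.sum()
    for col, tot in (("male", totals["male_n"]), ("female", totals["female_n"]), ("total", totals["total_n"])):
        n = tab[f"{col}_n"]
        tab[f"{col}_pct"] = (
            round_half_up(100.0 * n / tot).astype(int) if tot > 0 else 0
        )
    footer = pd.DataFrame(
        {
            "male_n": [int(totals["male_n"])],
            "female_n": [int(totals["female_n"])],
            "total_n": [int(totals["total_n"])],
            "male_pct": [100 if totals["male_n"] else 0],
            "female_pct": [100 if totals["female_n"] else 0],
            "total_pct": [100],
        },
        index=["Total"],
    )
    out = pd.concat([tab, footer])
    out.index.name = "cause"
    return out[["male_n", "male_pct", "female_n", "female_pct", "total_n", "total_pct"]]


def validate_cause_table(table: pd.DataFrame) -> None:
    """Check internal consistency of a counts/percentages table.

    Requires a ``Total`` footer row; every count column must sum to its
    footer, every row's total must equal male + female, and percentages
    must be the round-half-up of 100 n / column_total.  Raises
    ``ValueError`` naming the first offending row (useful for externally
    supplied tables, whose printed rows are sometimes inconsistent).
    """
    if "Total" not in table.index:
        raise ValueError("table has no 'Total' footer row")
    body = table.drop(index="Total")
    foot = table.loc["Total"]
    for cause, row in body.iterrows():
        if row["male_n"] + row["female_n"] != row["total_n"]:
            raise ValueError(f"row '{cause}': male + female != total")
    for col in ("male_n", "female_n", "total_n"):
        if body[col].sum() != foot[col]:
            raise ValueError(
                f"column {col} sums to {body[col].sum()}, footer says {foot[col]}"
            )
    for cause, row in body.iterrows():
        for col in ("male", "female", "total"):
            tot = foot[f"{col}_n"]
            if tot > 0:
                expect = int(round_half_up(100.0 * row[f"{col}_n"] / tot))
                if row[f"{col}_pct"] != expect:
                    raise ValueError(
                        f"row '{cause}': {col}_pct {row[f'{col}_pct']} != {expect}"
                    )


def reference_death_records() -> pd.DataFrame:
    """Expand :data:`REFERENCE_CAUSE_COUNTS` into one row per death."""
    rows = []
    for cause, (n_m, n_f) in REFERENCE_CAUSE_COUNTS.items():
        rows.extend({"cause": cause, "sex": "male"} for _ in range(n_m))
        rows.extend({"cause": cause, "sex": "female"} for _ in range(n_f))
    return pd.DataFrame(rows)


def rate_by_age_sex(persons: pd.DataFrame, bin_width: int = 5) -> pd.DataFrame:
    """Mortality rate per 1000 person-years by sex and age band.

    Bands are [15, 15+w), [15+w, 15+2w), ... up to 45.  Empty strata yield
    a missing (NaN) rate, never zero.
    """
    if (persons["person_years"] <= 0).any():
        raise ValueError("person_years must be positive")
    edges = np.arange(15, 45 + bin_width, bin_width)
    labels = [f"[{a},{b})" for a, b in zip(edges[:-1], edges[1:])]
    p = persons.copy()
    p["sex"] = pd.Categorical(p["sex"], categories=list(SEXES))
    p["age_band"] = pd.cut(
        p["age_years"], bins=edges, right=False, labels=labels
    )
    g = p.groupby(["sex", "age_band"], observed=False)
    out = pd.DataFrame(
        {
            "deaths": g["died"].sum().astype(int),
            "person_years": g["person_years"].sum(),
        }
    ).reset_index()
    out["rate_per_1000"] = np.where(
        out["person_years"] > 0,
        1000.0 * out["deaths"] / out["person_years"],
        np.nan,
    )
    return out


def to_markdown(table: pd.DataFrame, path: str | Path | None = None) -> str:
    """Render a counts/percentages table as GitHub-style Markdown."""
    header = "| " + " | ".join([table.index.name or ""] + list(table.columns)) + " |"
    sep = "|" + "---|" * (len(table.columns) + 1)
    lines = [header, sep]
    for idx, row in table.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [str(x) for x in row]) + " |")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
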