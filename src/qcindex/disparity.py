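"""Gender/age disparity metrics and reporting arithmetic on QCI tables.

Rounding convention: ratios and changes are chained on unrounded values and
rounded half-up only at the presentation layer (the returned report
columns), which reproduces published-table arithmetic such as
0.86 - 0.68 = 0.18 without double-rounding drift.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .io import PanelValidationError, normalize_weights

__all__ = [
    "round_half_up",
    "compute_gdr",
    "net_change",
    "rank_locations",
    "age_gradient",
    "correlate_reference",
]

#: coarse age partition used for age-gradient summaries
DEFAULT_AGE_BINS = {
    "15-49": ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"],
    "50-74": ["50-54", "55-59", "60-64", "65-69", "70-74"],
    "75+": ["75-79", "80-84", "85+"],
}


def round_half_up(x, places: int):
    """Decimal round-half-up (0.925 -> 0.93 at 2 places), NaN-safe."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.nan
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def compute_gdr(scores: pd.DataFrame, rounding: int = 2) -> pd.DataFrame:
    """Gender Disparity Ratio: female QCI / male QCI per stratum.

    ``scores`` is a QCITable with female and male rows sharing
    (location, year, age_group) keys.  GDR near 1 means gender-equal care;
    it is missing (with a reason) where either score is missing or the
    male score is zero.

    Returns a GDRTable with columns location, year, age_group,
    qci_female, qci_male, gdr_raw (unrounded), gdr (rounded half-up to
    ``rounding`` places) and missing_reason.
    """
    keys = [c for c in ("location", "year", "age_group") if c in scores.columns]
    sub = scores[scores["sex"].isin(["female", "male"])]
    wide = sub.pivot_table(index=keys, columns="sex", values="qci", aggfunc="first")
    wide = wide.reindex(columns=["female", "male"]).reset_index()
    if len(wide.dropna(subset=["female", "male"])) == 0:
        raise PanelValidationError("no shared (location, year, age_group) keys across sexes")

    f = wide["female"].to_numpy(float)
    m = wide["male"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where((m != 0) & ~np.isnan(m) & ~np.isnan(f), f / np.where(m != 0, m, 1.0), np.nan)

    reason = np.full(len(wide), "none", dtype=object)
    reason[np.isnan(f) | np.isnan(m)] = "missing_score"
    reason[(~np.isnan(m)) & (m == 0)] = "zero_male_qci"

    out = wide[keys].copy()
    out["qci_female"] = f
    out["qci_male"] = m
    out["gdr_raw"] = raw
    out["gdr"] = [round_half_up(v, rounding) for v in raw]
    out["missing_reason"] = reason
    return out


def net_change(
    series: pd.DataFrame,
    year_from: int,
    year_to: int,
    value_col: str | None = None,
    rounding: int | None = None,
) -> pd.DataFrame:
    """Net change value(year_to) - value(year_from) per group.

    ``series`` is a QCITable or GDRTable; the value column is auto-detected
    ("qci" or "gdr_raw"/"gdr") unless given.  Differences are taken on
    unrounded values and rounded half-up for the report (default 1 place
    for QCI, 2 for GDR).  Groups missing either year get a NaN change with
    a reason.
    """
    if value_col is None:
        value_col = next((c for c in ("qci", "gdr_raw", "gdr") if c in series.columns), None)
        if value_col is None:
            raise ValueError("no qci or gdr column found")
    metric = "qci" if value_col == "qci" else "gdr"
    if rounding is None:
        rounding = 1 if metric == "qci" else 2

    group_cols = [c for c in ("location", "sex", "age_group") if c in series.columns]
    if not group_cols:
        raise ValueError("series has no grouping columns")
    wide = series.pivot_table(
        index=group_cols, columns="year", values=value_col, aggfunc="first"
    ).reset_index()
    for y in (year_from, year_to):
        if y not in wide.columns:
            wide[y] = np.nan

    change = wide[year_to].to_numpy(float) - wide[year_from].to_numpy(float)
    out = wide[group_cols].copy()
    out["metric"] = metric
    out["year_from"] = year_from
    out["year_to"] = year_to
    out["net_change_raw"] = change
    out["net_change"] = [round_half_up(v, rounding) for v in change]
    out["missing_reason"] = np.where(
        np.isnan(wide[year_from].to_numpy(float)) | np.isnan(wide[year_to].to_numpy(float)),
        "missing_year",
        "none",
    )
    return out


def rank_locations(
    scores: pd.DataFrame,
    year: int,
    top_n: int | None = None,
    bottom_n: int | None = None,
    age_group: str = "age-standardized",
    sex: str | None = "both",
) -> pd.DataFrame:
    """Rank locations by QCI (descending) in one year.

    Ties are broken by location label ascending.  When ``top_n`` /
    ``bottom_n`` are given, the result is restricted to those slices (a
    "group" column says which); counts larger than the number of locations
    clamp to the full list.
    """
    sub = scores[scores["year"] == year]
    if "age_group" in sub.columns and age_group is not None:
        sub = sub[sub["age_group"] == age_group]
    if "sex" in sub.columns and sex is not None:
        sub = sub[sub["sex"] == sex]
    sub = sub.dropna(subset=["qci"])
    if len(sub) == 0:
        raise PanelValidationError(f"no scores for year {year}")

    ranked = sub.sort_values(
        ["qci", "location"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranked = ranked[["rank", "location", "qci"]]

    if top_n is None and bottom_n is None:
        return ranked
    parts = []
    if top_n is not None:
        parts.append(ranked.head(min(top_n, len(ranked))).assign(group="top"))
    if bottom_n is not None:
        parts.append(ranked.tail(min(bottom_n, len(ranked))).assign(group="bottom"))
    return pd.concat(parts, ignore_index=True).drop_duplicates(subset=["rank", "group"])


def age_gradient(
    scores: pd.DataFrame,
    weights: pd.DataFrame,
    bins: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Age profile of QCI: per five-year band, and coarse-bin summaries.

    Coarse-bin values are standard-population-weighted means of the member
    bands' QCI (weights renormalized within each bin).

    Returns ``(band_table, coarse_table)``: the band table pivots qci by
    (group columns, age band); the coarse table has one row per
    (group, coarse bin).
    """
    bins = bins or DEFAULT_AGE_BINS
    w = normalize_weights(weights).set_index("age_group")["weight"]
    group_cols = [c for c in ("location", "year", "sex") if c in scores.columns]

    bands = scores[scores["age_group"].isin(w.index)].dropna(subset=["qci"])
    if len(bands) == 0:
        raise PanelValidationError("no age-specific scores to aggregate")
    band_table = bands[group_cols + ["age_group", "qci"]].copy()

    rows = []
    for label, members in bins.items():
        members = [b for b in members if b in w.index]
        if not members:
            raise PanelValidationError(f"age bin {label!r} has no weighted bands")
        sub = band_table[band_table["age_group"].isin(members)].copy()
        if len(sub) == 0:
            continue
        sub["w"] = sub["age_group"].map(w)
        agg = sub.groupby(group_cols, as_index=False).apply(
            lambda g: pd.Series({"qci": np.average(g["qci"], weights=g["w"])}),
            include_groups=False,
        )
        agg["age_bin"] = label
        rows.append(agg)
    coarse = pd.concat(rows, ignore_index=True)[group_cols + ["age_bin", "qci"]]
    return band_table, coarse


def correlate_reference(scores: pd.DataFrame, reference: pd.DataFrame) -> tuple[float, int]:
    """Pearson correlation between QCI and an external reference index
    (e.g. a healthcare access and quality index) over shared
    (location, year) keys.  Returns (r, n); requires >= 3 shared pairs.
    """
    keys = [c for c in ("location", "year") if c in scores.columns and c in reference.columns]
    if not keys:
        raise ValueError("scores and reference share no key columns")
    ref_col = next(c for c in reference.columns if c not in keys)
    merged = scores.merge(reference, on=keys, how="inner").dropna(subset=["qci", ref_col])
    n = len(merged)
    if n < 3:
        raise ValueError(f"need >= 3 shared (location, year) pairs, got {n}")
    r, _ = stats.pearsonr(merged["qci"], merged[ref_col])
    return float(r), n
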