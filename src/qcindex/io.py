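"""Reading, validating and writing GBD-results-style burden panels.

The canonical in-memory representation of a burden panel ("EpiPanel") is a
pandas DataFrame in long format with columns::

    location   str    location label (country, region, SDI quintile, ...)
    year       int    calendar year
    sex        str    one of {"female", "male", "both"}
    age_group  str    canonical five-year band "15-19" ... "80-84", "85+",
                      or the aggregates "all-ages" / "age-standardized"
    measure    str    one of {"incidence", "prevalence", "deaths",
                              "dalys", "ylls", "ylds"}
    metric     str    "number" or "rate_per_100k"
    value      float  non-negative
    population float  optional; person-count of the stratum (used for
                      number <-> rate conversion)

One (location, year, sex, age_group) tuple is a *stratum*; a stratum may
carry each measure in either or both metrics, but never twice in the same
metric.  Exports of the IHME results tool differ in column names ("val" vs
"value", presence of a "cause" column) and in dash characters inside age
labels; :func:`read_panel` normalizes all of that through a configurable
schema map.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MEASURES",
    "SEXES",
    "METRICS",
    "FIVE_YEAR_BANDS",
    "AGE_GROUPS",
    "STRATUM_COLS",
    "SchemaError",
    "PanelValidationError",
    "canonical_age",
    "canonical_sex",
    "canonical_measure",
    "canonical_metric",
    "read_panel",
    "validate_panel",
    "rates_from_counts",
    "counts_from_rates",
    "read_weights",
    "normalize_weights",
    "write_table",
]

MEASURES = ("incidence", "prevalence", "deaths", "dalys", "ylls", "ylds")
SEXES = ("female", "male", "both")
METRICS = ("number", "rate_per_100k")

#: analysis bands: five-year intervals from 15 up to the open-ended 85+ band
FIVE_YEAR_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(15, 85, 5)) + ("85+",)
AGE_GROUPS = FIVE_YEAR_BANDS + ("all-ages", "age-standardized")

STRATUM_COLS = ["location", "year", "sex", "age_group"]

_DEFAULT_SCHEMA = {
    "location": ("location", "location_name"),
    "year": ("year", "year_id"),
    "sex": ("sex", "sex_name"),
    "age_group": ("age", "age_group", "age_name"),
    "measure": ("measure", "measure_name"),
    "metric": ("metric", "metric_name"),
    "value": ("val", "value"),
    "population": ("population", "pop"),
}

_MEASURE_SYNONYMS = {
    "incidence": "incidence",
    "prevalence": "prevalence",
    "deaths": "deaths",
    "death": "deaths",
    "mortality": "deaths",
    "dalys": "dalys",
    "dalys (disability-adjusted life years)": "dalys",
    "ylls": "ylls",
    "ylls (years of life lost)": "ylls",
    "ylds": "ylds",
    "ylds (years lived with disability)": "ylds",
}

_METRIC_SYNONYMS = {
    "number": "number",
    "rate": "rate_per_100k",
    "rate_per_100k": "rate_per_100k",
    "rate per 100,000": "rate_per_100k",
}


class SchemaError(ValueError):
    """A required column is absent or the schema map is malformed."""


class PanelValidationError(ValueError):
    """Panel content violates a vocabulary or consistency invariant."""


def canonical_age(label: str) -> str:
    """Canonicalize an age-group label.

    Accepts the dialects found in results-tool exports — "15 to 19",
    "15-19", "15–19" (en dash), "85 plus", "85+ years", "All ages",
    "Age-standardized" — and returns the canonical vocabulary form.
    Raises :class:`PanelValidationError` for labels outside the vocabulary.
    """
    s = str(label).strip().lower()
    for dash in ("–", "—", "−"):
        s = s.replace(dash, "-")
    s = s.replace(" years", "").replace(" to ", "-").replace(" plus", "+")
    s = s.replace("age standardized", "age-standardized")
    s = s.replace("all ages", "all-ages")
    s = s.replace(" ", "")
    if s in AGE_GROUPS:
        return s
    raise PanelValidationError(f"unknown age_group label: {label!r}")


def canonical_sex(label: str) -> str:
    s = str(label).strip().lower()
    if s in SEXES:
        return s
    raise PanelValidationError(f"unknown sex label: {label!r}")


def canonical_measure(label: str) -> str:
    s = str(label).strip().lower()
    try:
        return _MEASURE_SYNONYMS[s]
    except KeyError:
        raise PanelValidationError(f"unknown measure label: {label!r}") from None


def canonical_metric(label: str) -> str:
    s = str(label).strip().lower()
    try:
        return _METRIC_SYNONYMS[s]
    except KeyError:
        raise PanelValidationError(f"unknown metric label: {label!r}") from None


def _resolve_columns(columns, schema_map):
    """Map canonical field -> source column, honoring user overrides."""
    resolved = {}
    for field, candidates in _DEFAULT_SCHEMA.items():
        if schema_map and field in schema_map:
            candidates = (schema_map[field],)
        hit = next((c for c in candidates if c in columns), None)
        if hit is None and field != "population":
            raise SchemaError(
                f"required column for {field!r} not found "
                f"(looked for {', '.join(map(repr, candidates))})"
            )
        resolved[field] = hit
    return resolved


def read_panel(path, schema_map: dict | None = None, strict: bool = True) -> pd.DataFrame:
    """Read a long-format burden panel from CSV and validate it.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    schema_map : dict, optional
        Canonical field name -> source column name, overriding the default
        results-tool column guesses (e.g. ``{"value": "mean_est"}``).
    strict : bool
        If True (default) vocabulary violations raise; if False offending
        rows are dropped with a warning listing their row numbers.

    Returns
    -------
    DataFrame in the canonical panel schema (see module docstring),
    validated by :func:`validate_panel`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    cols = _resolve_columns(raw.columns, schema_map)

    out = pd.DataFrame(
        {
            "location": raw[cols["location"]].astype(str),
            "year": raw[cols["year"]],
            "sex": raw[cols["sex"]],
            "age_group": raw[cols["age_group"]],
            "measure": raw[cols["measure"]],
            "metric": raw[cols["metric"]],
            "value": raw[cols["value"]],
        }
    )
    if cols["population"] is not None:
        out["population"] = pd.to_numeric(raw[cols["population"]])

    bad_rows: list[tuple[int, str]] = []

    def _map(col, fn):
        mapped = []
        for i, v in zip(out.index, out[col]):
            try:
                mapped.append(fn(v))
            except PanelValidationError as exc:
                bad_rows.append((i + 2, str(exc)))  # +2: header + 1-based
                mapped.append(None)
        out[col] = mapped

    _map("age_group", canonical_age)
    _map("sex", canonical_sex)
    _map("measure", canonical_measure)
    _map("metric", canonical_metric)

    if bad_rows:
        msg = "; ".join(f"row {r}: {m}" for r, m in bad_rows[:20])
        if strict:
            raise PanelValidationError(f"{len(bad_rows)} invalid row(s): {msg}")
        warnings.warn(f"dropping {len(bad_rows)} invalid row(s): {msg}", stacklevel=2)
        out = out.dropna(subset=["age_group", "sex", "measure", "metric"])

    out["year"] = out["year"].astype(int)
    out["value"] = pd.to_numeric(out["value"]).astype(float)
    return validate_panel(out.reset_index(drop=True))


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check panel invariants; return the panel unchanged if valid.

    Raises :class:`PanelValidationError` on negative values or duplicate
    (stratum, measure, metric) keys; emits a consistency warning when a
    stratum carries both a number and a rate that disagree with its
    population beyond 1e-6 relative.
    """
    missing = [c for c in STRATUM_COLS + ["measure", "metric", "value"] if c not in panel.columns]
    if missing:
        raise SchemaError(f"panel is missing columns: {missing}")

    neg = panel[panel["value"] < 0]
    if len(neg):
        strata = neg[STRATUM_COLS + ["measure"]].to_dict("records")[:10]
        raise PanelValidationError(f"negative values for strata: {strata}")

    key = STRATUM_COLS + ["measure", "metric"]
    dup = panel.duplicated(subset=key)
    if dup.any():
        strata = panel.loc[dup, key].to_dict("records")[:10]
        raise PanelValidationError(f"duplicate (stratum, measure, metric) rows: {strata}")

    if "population" in panel.columns:
        wide = panel.pivot_table(
            index=STRATUM_COLS + ["measure", "population"],
            columns="metric",
            values="value",
            aggfunc="first",
        ).reset_index()
        if "number" in wide.columns and "rate_per_100k" in wide.columns:
            both = wide.dropna(subset=["number", "rate_per_100k"])
            both = both[both["population"] > 0]
            implied = both["number"] / both["population"] * 1e5
            scale = np.maximum(np.abs(both["rate_per_100k"]), np.abs(implied))
            off = np.abs(both["rate_per_100k"] - implied) > 1e-6 * np.maximum(scale, 1e-300)
            if off.any():
                bad = both.loc[off, STRATUM_COLS + ["measure"]].to_dict("records")[:10]
                warnings.warn(
                    f"number/rate inconsistent with population for strata: {bad}",
                    stacklevel=2,
                )
    return panel


def _require_population(panel: pd.DataFrame, need: pd.DataFrame, what: str):
    if "population" not in panel.columns or need["population"].isna().any():
        missing = need.loc[
            need["population"].isna() if "population" in need.columns else slice(None),
            STRATUM_COLS,
        ]
        strata = missing.drop_duplicates().to_dict("records")[:10]
        raise PanelValidationError(f"population required to {what}; missing for strata: {strata}")


def rates_from_counts(panel: pd.DataFrame) -> pd.DataFrame:
    """Append rate_per_100k rows for every (stratum, measure) that has only
    a number row: rate = number / population * 100000.  Number rows are
    preserved; existing rate rows are kept untouched.
    """
    if "population" not in panel.columns:
        raise PanelValidationError("population required to convert counts to rates")
    numbers = panel[panel["metric"] == "number"]
    have_rate = panel.loc[panel["metric"] == "rate_per_100k", STRATUM_COLS + ["measure"]]
    key = STRATUM_COLS + ["measure"]
    todo = numbers.merge(have_rate.assign(_h=1), on=key, how="left")
    todo = todo[todo["_h"].isna()].drop(columns="_h")
    _require_population(panel, todo, "convert counts to rates")
    new = todo.copy()
    new["metric"] = "rate_per_100k"
    new["value"] = new["value"] / new["population"] * 1e5
    return pd.concat([panel, new], ignore_index=True)


def counts_from_rates(panel: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`rates_from_counts`: number = rate * population / 1e5."""
    if "population" not in panel.columns:
        raise PanelValidationError("population required to convert rates to counts")
    rates = panel[panel["metric"] == "rate_per_100k"]
    have_num = panel.loc[panel["metric"] == "number", STRATUM_COLS + ["measure"]]
    key = STRATUM_COLS + ["measure"]
    todo = rates.merge(have_num.assign(_h=1), on=key, how="left")
    todo = todo[todo["_h"].isna()].drop(columns="_h")
    _require_population(panel, todo, "convert rates to counts")
    new = todo.copy()
    new["metric"] = "number"
    new["value"] = new["value"] * new["population"] / 1e5
    return pd.concat([panel, new], ignore_index=True)


def normalize_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Validate an age-weights table (columns age_group, weight) and return
    a copy with canonical age labels and weights normalized to sum to 1."""
    missing = [c for c in ("age_group", "weight") if c not in weights.columns]
    if missing:
        raise SchemaError(f"weights table missing columns: {missing}")
    w = weights.copy()
    w["age_group"] = [canonical_age(a) for a in w["age_group"]]
    if w["age_group"].duplicated().any():
        raise PanelValidationError("duplicate age_group in weights table")
    w["weight"] = pd.to_numeric(w["weight"]).astype(float)
    if (w["weight"] <= 0).any():
        raise PanelValidationError("weights must be positive")
    w["weight"] = w["weight"] / w["weight"].sum()
    return w.reset_index(drop=True)


def read_weights(path) -> pd.DataFrame:
    """Read a standard-population weights CSV (age_group, weight)."""
    return normalize_weights(pd.read_csv(path))


def write_table(table: pd.DataFrame, path) -> None:
    """Write any pipeline table to CSV.

    Column order is preserved as given; floats are written with Python repr
    precision so a read-back is exact to the last bit for finite values.
    Missing values become empty cells.  Empty tables are refused.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty table")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
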