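"""Secondary care-quality indices and direct age-standardization.

From the six burden measures of a stratum, four ratio indices are formed:

* ``prev_inc``   prevalence / incidence   (higher = better care)
* ``mir``        deaths / incidence       (mortality-to-incidence ratio,
  higher = worse care)
* ``daly_prev``  DALYs / prevalence       (higher = worse care)
* ``yll_yld``    YLLs / YLDs              (higher = worse care)

All four are ratios of two quantities measured on the same population, so
they are identical whether computed from counts or from rates — the
denominators cancel.  Zero denominators are handled by policy: the default
flags the stratum as missing (with the reason recorded) rather than
inflating the denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import (
    FIVE_YEAR_BANDS,
    MEASURES,
    STRATUM_COLS,
    PanelValidationError,
    normalize_weights,
)

__all__ = [
    "INDEX_COLS",
    "compute_indices",
    "age_standardize",
    "world_standard_weights",
]

INDEX_COLS = ["prev_inc", "mir", "daly_prev", "yll_yld"]

#: numerator/denominator measures per index, in missing-reason priority order
_RATIOS = {
    "prev_inc": ("prevalence", "incidence"),
    "mir": ("deaths", "incidence"),
    "daly_prev": ("dalys", "prevalence"),
    "yll_yld": ("ylls", "ylds"),
}

_ZERO_REASON = {
    "incidence": "zero_incidence",
    "prevalence": "zero_prevalence",
    "ylds": "zero_yld",
}

# WHO World Standard population (2000-2025) proportions for the analysis
# bands, renormalized over 15+ at load time.  A documented synthetic
# stand-in for a world standard population weight table.
_WHO_WORLD_STANDARD_15PLUS = {
    "15-19": 8.47, "20-24": 8.22, "25-29": 7.93, "30-34": 7.61,
    "35-39": 7.15, "40-44": 6.59, "45-49": 6.04, "50-54": 5.37,
    "55-59": 4.55, "60-64": 3.72, "65-69": 2.96, "70-74": 2.21,
    "75-79": 1.52, "80-84": 0.91, "85+": 0.63,
}


def world_standard_weights() -> pd.DataFrame:
    """Standard-population weights for the 15-85+ analysis bands.

    Synthetic stand-in built from the WHO World Standard population
    proportions, restricted to ages 15+ and normalized to sum to 1.
    """
    w = pd.DataFrame(
        {"age_group": list(FIVE_YEAR_BANDS),
         "weight": [_WHO_WORLD_STANDARD_15PLUS[a] for a in FIVE_YEAR_BANDS]}
    )
    return normalize_weights(w)


def compute_indices(
    panel: pd.DataFrame,
    metric: str = "rate_per_100k",
    epsilon_policy: str = "missing",
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Compute the four secondary indices per stratum.

    Parameters
    ----------
    panel : DataFrame
        Canonical long-format burden panel.
    metric : {"rate_per_100k", "number"}
        Which metric to compute ratios from; the result is the same for
        consistent number/rate pairs (denominators cancel).
    epsilon_policy : {"missing", "epsilon"}
        "missing" flags an index as missing when its denominator is zero,
        recording the reason; "epsilon" adds ``epsilon`` to the denominator.
    epsilon : float
        Denominator inflation used under the "epsilon" policy.

    Returns
    -------
    IndexTable: one row per stratum with columns
    location, year, sex, age_group, prev_inc, mir, daly_prev, yll_yld,
    missing_reason, is_missing.
    """
    if metric not in ("rate_per_100k", "number"):
        raise ValueError(f"unknown metric {metric!r}")
    if epsilon_policy not in ("missing", "epsilon"):
        raise ValueError(f"unknown epsilon_policy {epsilon_policy!r}")

    sub = panel[panel["metric"] == metric]
    if len(sub) == 0:
        raise PanelValidationError(f"panel has no rows in metric {metric!r}")
    wide = sub.pivot_table(
        index=STRATUM_COLS, columns="measure", values="value", aggfunc="first"
    ).reset_index()
    for m in MEASURES:
        if m not in wide.columns:
            wide[m] = np.nan

    out = wide[STRATUM_COLS].copy()
    reason = pd.Series("none", index=wide.index, dtype=object)

    absent = wide[list(MEASURES)].isna().any(axis=1)
    reason[absent] = "absent_measure"

    for name, (num, den) in _RATIOS.items():
        n = wide[num].to_numpy(float)
        d = wide[den].to_numpy(float)
        if epsilon_policy == "epsilon":
            vals = n / (d + epsilon)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.where(d > 0, n / np.where(d > 0, d, 1.0), np.nan)
            zero_den = (d == 0) & ~np.isnan(d)
            # first applicable reason wins; absent_measure outranks zeros
            newly = zero_den & (reason == "none").to_numpy()
            reason[newly] = _ZERO_REASON[den]
        out[name] = vals

    out["missing_reason"] = reason.to_numpy()
    out.loc[out[INDEX_COLS].isna().any(axis=1) & (out["missing_reason"] == "none"),
            "missing_reason"] = "absent_measure"
    out["is_missing"] = out["missing_reason"] != "none"

    if not (~out["is_missing"]).any():
        raise PanelValidationError("no stratum has all four indices computable")
    bad = out.loc[~out["is_missing"], INDEX_COLS]
    if (bad.to_numpy() < 0).any():
        raise PanelValidationError("negative index values; input panel invalid")
    return out


def age_standardize(
    panel: pd.DataFrame,
    weights: pd.DataFrame,
    measures=None,
) -> pd.DataFrame:
    """Append age-standardized rate rows via direct standardization.

    For each (location, year, sex, measure) with rate rows covering every
    weighted age band, a new row with ``age_group = "age-standardized"`` is
    appended whose rate is the weight-normalized sum ``sum_a w_a * rate_a``.
    Original rows are untouched.

    Raises PanelValidationError naming (location, year, sex, measure, band)
    when a required band is absent.
    """
    w = normalize_weights(weights)
    bands = list(w["age_group"])
    measures = list(measures) if measures is not None else list(MEASURES)

    rates = panel[
        (panel["metric"] == "rate_per_100k")
        & panel["measure"].isin(measures)
        & panel["age_group"].isin(bands)
    ]
    if len(rates) == 0:
        raise PanelValidationError("no age-specific rate rows to standardize")

    group_cols = ["location", "year", "sex", "measure"]
    counts = rates.groupby(group_cols)["age_group"].agg(["count", lambda s: set(s)])
    incomplete = counts[counts["count"] < len(bands)]
    if len(incomplete):
        g, present = next(iter(incomplete.iterrows()))
        missing_band = sorted(set(bands) - present["<lambda_0>"])[0]
        raise PanelValidationError(
            f"age band {missing_band!r} missing for (location, year, sex, measure) = {g}"
        )

    merged = rates.merge(w, on="age_group")
    std = (
        merged.assign(wv=merged["value"] * merged["weight"])
        .groupby(group_cols, as_index=False)["wv"]
        .sum()
        .rename(columns={"wv": "value"})
    )
    std["age_group"] = "age-standardized"
    std["metric"] = "rate_per_100k"
    extra = [c for c in panel.columns if c not in std.columns]
    for c in extra:
        std[c] = np.nan
    return pd.concat([panel, std[panel.columns]], ignore_index=True)
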