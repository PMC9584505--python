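"""End-to-end orchestration: panel -> indices -> QCI -> disparity reports.

A run is driven by a plain config mapping (typically loaded from YAML)::

    simulate: {...SimConfig fields...}     # or
    input: {path: panel.csv, schema_map: {...}}
    weights: builtin | path/to/weights.csv
    indices: {metric: rate_per_100k, epsilon_policy: missing, epsilon: 1e-6}
    qci: {pool: location-year-sex | location-year-sex-age,
          lower_q: 0.0, upper_q: 1.0}
    report: {net_change: [1990, 2019], rank: 5}

Every artifact is written to the run directory (indices.csv, model.yaml,
qci.csv, gdr.csv, changes.csv, ranking.csv, config.yaml, run.log) and the
log reconciles row counts and dropped-stratum reasons per stage.  Identical
config and inputs yield byte-identical numeric outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml
from scipy import stats

from . import disparity, indices as indices_mod, io as io_mod, qci as qci_mod
from .simulate import SimConfig, generate_panel, truth_join

__all__ = ["ConfigError", "run_pipeline"]

log = logging.getLogger("qcindex")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


_POOLS = ("location-year-sex", "location-year-sex-age")


def _validate_config(config: dict) -> dict:
    cfg = {
        "indices": {"metric": "rate_per_100k", "epsilon_policy": "missing", "epsilon": 1e-6},
        "qci": {"pool": "location-year-sex", "lower_q": 0.0, "upper_q": 1.0},
        "report": {},
        **(config or {}),
    }
    if ("simulate" in cfg) == ("input" in cfg):
        raise ConfigError("config must contain exactly one of 'simulate' or 'input'")
    if "input" in cfg and not Path(cfg["input"]["path"]).exists():
        raise ConfigError(f"input panel not found: {cfg['input']['path']}")
    if cfg["qci"].get("pool", "location-year-sex") not in _POOLS:
        raise ConfigError(f"qci.pool must be one of {_POOLS}")
    weights = cfg.get("weights")
    if weights not in (None, "builtin") and not Path(weights).exists():
        raise ConfigError(f"weights file not found: {weights}")
    return cfg


def _load_weights(cfg: dict, needed: bool):
    weights = cfg.get("weights")
    if weights == "builtin":
        return indices_mod.world_standard_weights()
    if weights is not None:
        return io_mod.read_weights(weights)
    if needed:
        raise ConfigError(
            "age-standardization requested (qci.pool = location-year-sex) but no "
            "'weights' configured; set weights: builtin or a weights.csv path"
        )
    return None


def run_pipeline(config: dict, outdir) -> Path:
    """Run the full pipeline; returns the run directory path."""
    cfg = _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(cfg.get("log_level", "INFO"))
    try:
        return _run(cfg, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: dict, outdir: Path) -> Path:
    pool_kind = cfg["qci"].get("pool", "location-year-sex")

    truth = None
    if "simulate" in cfg:
        sim = SimConfig(**cfg["simulate"])
        panel, truth = generate_panel(sim)
        io_mod.write_table(panel, outdir / "panel.csv")
        io_mod.write_table(truth, outdir / "truth.csv")
        log.info("simulated panel: %d rows, %d strata", len(panel), len(truth))
    else:
        panel = io_mod.read_panel(cfg["input"]["path"], cfg["input"].get("schema_map"))
        log.info("read panel: %d rows", len(panel))

    need_std = (
        pool_kind == "location-year-sex"
        and "age-standardized" not in set(panel["age_group"])
    )
    weights = _load_weights(cfg, needed=need_std)
    if need_std:
        panel = indices_mod.age_standardize(panel, weights)
        log.info("appended age-standardized rows; panel now %d rows", len(panel))

    idx = indices_mod.compute_indices(
        panel,
        metric=cfg["indices"].get("metric", "rate_per_100k"),
        epsilon_policy=cfg["indices"].get("epsilon_policy", "missing"),
        epsilon=cfg["indices"].get("epsilon", 1e-6),
    )
    io_mod.write_table(idx, outdir / "indices.csv")
    dropped = idx.loc[idx["is_missing"], "missing_reason"].value_counts().to_dict()
    log.info("index table: %d strata, dropped by reason: %s", len(idx), dropped or "{}")

    if pool_kind == "location-year-sex":
        pool = idx[idx["age_group"] == "age-standardized"]
    else:
        pool = idx[idx["age_group"].isin(io_mod.FIVE_YEAR_BANDS)]
    if len(pool) == 0:
        raise io_mod.PanelValidationError(f"empty fitting pool for {pool_kind!r}")

    model = qci_mod.fit_qci(
        pool,
        lower_q=cfg["qci"].get("lower_q", 0.0),
        upper_q=cfg["qci"].get("upper_q", 1.0),
    )
    qci_mod.model_to_yaml(model, outdir / "model.yaml")
    log.info(
        "fitted QCI on %d strata: loadings %s, explained variance ratio %.4f",
        model.fit_pool_size_,
        {f: round(float(v), 4) for f, v in zip(model.kept_features_, model.loadings_)},
        model.explained_variance_ratio_,
    )

    scores = qci_mod.score_qci(model, pool)
    io_mod.write_table(scores, outdir / "qci.csv")
    log.info("scored %d strata (%d missing)", len(scores), int(scores["qci"].isna().sum()))

    if truth is not None:
        rho = _recovery(scores, truth, weights, pool_kind)
        if rho is not None:
            log.info("latent-quality recovery Spearman: %.4f", rho)

    gdr = disparity.compute_gdr(scores)
    io_mod.write_table(gdr, outdir / "gdr.csv")

    years = sorted(scores["year"].unique())
    y_from, y_to = cfg["report"].get("net_change", (years[0], years[-1]))
    changes = pd.concat(
        [
            disparity.net_change(scores, y_from, y_to),
            disparity.net_change(gdr, y_from, y_to),
        ],
        ignore_index=True,
    )
    io_mod.write_table(changes, outdir / "changes.csv")
    log.info("net changes %s -> %s: %d rows", y_from, y_to, len(changes))

    ranking = _ranking(scores, years[-1], cfg["report"].get("rank"))
    io_mod.write_table(ranking, outdir / "ranking.csv")

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return outdir


def _ranking(scores: pd.DataFrame, year: int, n):
    """Rank locations in the given year; when no 'both'-sex scores exist,
    rank on the per-location mean across available sexes (logged)."""
    age = "age-standardized" if "age-standardized" in set(scores["age_group"]) else None
    sub = scores if age is None else scores[scores["age_group"] == age]
    if "both" in set(sub["sex"]):
        view = sub
        sex = "both"
    else:
        view = (
            sub[sub["year"] == year]
            .groupby(["location", "year"], as_index=False)["qci"]
            .mean()
        )
        sex = None
        log.info("no 'both'-sex scores; ranking on mean over sexes")
    return disparity.rank_locations(
        view, year, top_n=n, bottom_n=n, age_group=None, sex=sex
    )


def _recovery(scores, truth, weights, pool_kind):
    """Spearman correlation between scored QCI and latent quality."""
    if pool_kind == "location-year-sex":
        if weights is None:
            return None
        w = io_mod.normalize_weights(weights).set_index("age_group")["weight"]
        t = truth[truth["age_group"].isin(w.index)].copy()
        t["w"] = t["age_group"].map(w)
        t = (
            t.assign(wq=t["q"] * t["w"])
            .groupby(["location", "year", "sex"], as_index=False)[["wq", "w"]]
            .sum()
        )
        t["q"] = t["wq"] / t["w"]
        truth = t[["location", "year", "sex", "q"]]
    joined = truth_join(scores.dropna(subset=["qci"]), truth)
    if len(joined) < 3:
        return None
    return float(stats.spearmanr(joined["q"], joined["qci"]).statistic)
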