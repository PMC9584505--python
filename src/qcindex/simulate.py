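"""Synthetic burden-panel generator driven by a latent care-quality parameter.

The generator emulates a 1990-2019 multi-location, two-sex, 15-85+ burden
panel for a bladder-cancer-like disease whose six measures are mutually
consistent by construction.  Each stratum carries a latent quality
``q in [0, 1]`` (higher = better care) and the measures follow:

* incidence rate  ``I = baseline(age) * sex_ratio * noise`` — care quality
  does not affect who gets the disease;
* mortality-to-incidence ratio ``m(q) = mir_max - (mir_max - mir_min) * q``
  — better care, lower case fatality;
* deaths rate ``= I * m(q)``;
* prevalence rate ``= I * d(q)`` with survival duration
  ``d(q) = duration_min + (duration_max - duration_min) * q``
  (steady-state prevalence = incidence x duration);
* YLD rate ``= prevalence * disability_weight``;
* YLL rate ``= deaths * residual_life_expectancy(age)``;
* DALY rate ``= YLL + YLD`` exactly.

Noise is a single multiplicative lognormal factor on incidence, propagated
consistently downstream, so the DALY = YLL + YLD identity is exact and the
four care-quality ratio indices are deterministic functions of (q, age).
Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import FIVE_YEAR_BANDS, STRATUM_COLS, validate_panel

__all__ = ["QualityModel", "SimConfig", "generate_panel", "truth_join"]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class QualityModel:
    """Latent care quality q(location, year, sex, age), clamped to [0, 1].

    q = location base level (evenly spread on [base_min, base_max])
        + year_slope * (year - first year)
        + sex_gap / 2 for males, - sex_gap / 2 for females
        - age_decline * age-band position in [0, 1]
    """

    base_min: float = 0.15
    base_max: float = 0.85
    year_slope: float = 0.003
    sex_gap: float = 0.05
    age_decline: float = 0.15

    def q(self, loc_frac, year_offset, is_male, age_frac):
        base = self.base_min + (self.base_max - self.base_min) * loc_frac
        q = (
            base
            + self.year_slope * year_offset
            + np.where(is_male, self.sex_gap / 2.0, -self.sex_gap / 2.0)
            - self.age_decline * age_frac
        )
        return np.clip(q, 0.0, 1.0)


def _default_baseline():
    # female baseline incidence per 100k, rising steeply with age as is
    # typical of urothelial cancer: ~0.2 at 15-19 up to ~110 at 85+
    return {band: 0.2 * float(np.exp(0.45 * i)) for i, band in enumerate(FIVE_YEAR_BANDS)}


def _default_life_expectancy():
    # residual life expectancy at the band midpoint, ~65y down to ~5y
    n = len(FIVE_YEAR_BANDS)
    return {
        band: 65.0 - 60.0 * i / (n - 1) for i, band in enumerate(FIVE_YEAR_BANDS)
    }


@dataclass
class SimConfig:
    """Configuration of the synthetic burden panel.

    Defaults give 20 locations x 30 years (1990-2019) x 2 sexes x 15 age
    bands with a 5% coefficient-of-variation lognormal noise on incidence
    and a three-fold male/female incidence ratio.
    """

    n_locations: int = 20
    year_start: int = 1990
    year_end: int = 2019
    age_groups: tuple = FIVE_YEAR_BANDS
    sexes: tuple = ("female", "male")
    baseline_incidence_curve: dict = field(default_factory=_default_baseline)
    male_female_incidence_ratio: float = 3.0
    mir_min: float = 0.1
    mir_max: float = 0.9
    duration_min: float = 2.0
    duration_max: float = 12.0
    disability_weight: float = 0.05
    life_expectancy_curve: dict = field(default_factory=_default_life_expectancy)
    population_per_stratum: float = 1_000_000.0
    noise_cv: float = 0.05
    quality: QualityModel = field(default_factory=QualityModel)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.quality, dict):
            self.quality = QualityModel(**self.quality)
        if self.n_locations < 1:
            raise SimConfigError("n_locations must be >= 1")
        if self.year_end < self.year_start:
            raise SimConfigError("year_end must be >= year_start")
        if not self.age_groups or not self.sexes:
            raise SimConfigError("age_groups and sexes must be non-empty")
        if not (0.0 < self.mir_min < self.mir_max < 1.0):
            raise SimConfigError("need 0 < mir_min < mir_max < 1")
        if not (0.0 < self.duration_min < self.duration_max):
            raise SimConfigError("need 0 < duration_min < duration_max")
        if not (0.0 < self.disability_weight < 1.0):
            raise SimConfigError("disability_weight must be in (0, 1)")
        if self.noise_cv < 0:
            raise SimConfigError("noise_cv must be >= 0")
        missing = [a for a in self.age_groups if a not in self.baseline_incidence_curve]
        missing += [a for a in self.age_groups if a not in self.life_expectancy_curve]
        if missing:
            raise SimConfigError(f"age curves missing bands: {sorted(set(missing))}")

    @property
    def years(self):
        return range(self.year_start, self.year_end + 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_groups"] = list(self.age_groups)
        d["sexes"] = list(self.sexes)
        return d


def generate_panel(config: SimConfig | None = None, **overrides):
    """Generate a consistent synthetic burden panel and its latent truth.

    Returns
    -------
    panel : DataFrame
        Canonical long-format panel with all six measures in both metrics
        ("number" and "rate_per_100k") and a population column.
    truth : DataFrame
        One row per stratum with the latent quality ``q``.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig(**{**config.to_dict(), **overrides})

    rng = np.random.default_rng(config.seed)
    locations = [f"L{i:03d}" for i in range(config.n_locations)]
    years = np.array(list(config.years))
    ages = list(config.age_groups)
    n_age = len(ages)

    idx = pd.MultiIndex.from_product(
        [locations, years, list(config.sexes), ages],
        names=STRATUM_COLS,
    )
    strata = idx.to_frame(index=False)

    loc_pos = strata["location"].map({l: i for i, l in enumerate(locations)}).to_numpy()
    loc_frac = loc_pos / max(config.n_locations - 1, 1)
    year_offset = strata["year"].to_numpy() - config.year_start
    is_male = strata["sex"].to_numpy() == "male"
    age_pos = strata["age_group"].map({a: i for i, a in enumerate(ages)}).to_numpy()
    age_frac = age_pos / max(n_age - 1, 1)

    q = config.quality.q(loc_frac, year_offset, is_male, age_frac)

    baseline = strata["age_group"].map(config.baseline_incidence_curve).to_numpy(float)
    life_exp = strata["age_group"].map(config.life_expectancy_curve).to_numpy(float)

    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=len(strata)))
    else:
        noise = np.ones(len(strata))

    sex_factor = np.where(is_male, config.male_female_incidence_ratio, 1.0)
    incidence = baseline * sex_factor * noise
    mir = config.mir_max - (config.mir_max - config.mir_min) * q
    duration = config.duration_min + (config.duration_max - config.duration_min) * q

    rates = {
        "incidence": incidence,
        "deaths": incidence * mir,
        "prevalence": incidence * duration,
    }
    rates["ylds"] = rates["prevalence"] * config.disability_weight
    rates["ylls"] = rates["deaths"] * life_exp
    rates["dalys"] = rates["ylls"] + rates["ylds"]

    pop = config.population_per_stratum
    numbers = {m: r * pop / 1e5 for m, r in rates.items()}
    # keep DALY = YLL + YLD exact in both metrics (multiplication does not
    # distribute bitwise over the sum)
    numbers["dalys"] = numbers["ylls"] + numbers["ylds"]

    frames = []
    for measure in rates:
        for metric, value in (
            ("rate_per_100k", rates[measure]),
            ("number", numbers[measure]),
        ):
            frames.append(strata.assign(measure=measure, metric=metric, value=value))
    panel = pd.concat(frames, ignore_index=True)
    panel["population"] = pop

    truth = strata.assign(q=q)
    return validate_panel(panel), truth


def truth_join(panel_scores: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Inner-join scored strata with the latent truth on the stratum key.

    Raises ValueError when the key sets are disjoint.
    """
    keys = [c for c in STRATUM_COLS if c in panel_scores.columns and c in truth.columns]
    joined = panel_scores.merge(truth, on=keys, how="inner")
    if len(joined) == 0:
        raise ValueError("no shared strata between scores and truth")
    return joined
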