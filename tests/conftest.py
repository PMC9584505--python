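import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from qcindex import SimConfig, generate_panel, world_standard_weights

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def weights():
    return world_standard_weights()


@pytest.fixture(scope="session")
def small_sim():
    """Small but full-shape synthetic panel: 6 locations x 10 years."""
    cfg = SimConfig(n_locations=6, year_start=1990, year_end=1999, seed=7)
    panel, truth = generate_panel(cfg)
    return cfg, panel, truth


def build_panel(rows, population=None):
    """Build a canonical panel from dicts of
    (location, year, sex, age_group) -> {measure: rate_per_100k}."""
    recs = []
    for (loc, year, sex, age), measures in rows.items():
        for meas, val in measures.items():
            recs.append(
                dict(location=loc, year=year, sex=sex, age_group=age,
                     measure=meas, metric="rate_per_100k", value=float(val))
            )
    df = pd.DataFrame(recs)
    if population is not None:
        df["population"] = float(population)
    return df


#: one internally consistent stratum's six rates (deaths = 0.4 * incidence,
#: prevalence = incidence * 8, ylds = prevalence * 0.05, ylls = deaths * 20)
CONSISTENT_MEASURES = {
    "incidence": 10.0,
    "deaths": 4.0,
    "prevalence": 80.0,
    "ylds": 4.0,
    "ylls": 80.0,
    "dalys": 84.0,
}
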