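import numpy as np
import pandas as pd
import pytest

from toxmatch import SimConfig, simulate
from toxmatch.exposure import EARTH_RADIUS_KM


def km_to_deg_lat(km: float) -> float:
    """Degrees of latitude spanning ``km`` along a meridian."""
    return np.degrees(km / EARTH_RADIUS_KM)


def make_facilities(rows):
    return pd.DataFrame(rows, columns=["facility_id", "lon", "lat", "agent", "year", "modeled_hazard"])


def make_participants(rows):
    cols = ["participant_id", "lon", "lat", "visit_year", "cancer_type", "case",
            "age", "sex", "race", "ethnicity", "alcohol", "tobacco", "adi_std"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared by matching/pipeline tests."""
    cfg = SimConfig(
        seed=42, n_cases=60, n_controls=360,
        region=(-78.0, -76.8, 37.0, 38.0), years=(2017, 2019),
        agents=("chromium", "benzene"), facilities_per_agent=8,
        facility_persistence=0.9, cancer_type="lung",
    )
    facilities, participants, truth = simulate(cfg)
    return cfg, facilities, participants, truth


def random_toy_tables(rng, n_facilities=None, n_participants=None):
    """Random small facility/participant tables for oracle comparisons."""
    agents = ["chromium", "benzene", "nickel"]
    nf = n_facilities or int(rng.integers(1, 21))
    np_ = n_participants or int(rng.integers(5, 51))
    fac_rows = []
    for i in range(nf):
        agent = agents[int(rng.integers(len(agents)))]
        lon = float(rng.uniform(-77.8, -77.0))
        lat = float(rng.uniform(37.2, 37.8))
        for year in range(2010, 2020):
            if rng.random() < 0.5:
                fac_rows.append((f"F{i:02d}", lon, lat, agent, year,
                                 float(rng.lognormal(3, 1))))
    if not fac_rows:
        fac_rows.append(("F00", -77.5, 37.5, "chromium", 2015, 1.0))
    part_rows = []
    for j in range(np_):
        part_rows.append((f"P{j:03d}", float(rng.uniform(-77.8, -77.0)),
                          float(rng.uniform(37.2, 37.8)), int(rng.integers(2013, 2020)),
                          "none", int(rng.integers(0, 2)), 50.0, "female", "white",
                          "not_hispanic", "never", "never", 100.0))
    return make_facilities(fac_rows), make_participants(part_rows)
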