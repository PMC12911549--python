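import datetime as dt

import numpy as np
import pandas as pd
import pytest

from stormcohort import cohort as cohort_mod
from stormcohort import synthetic_data
from stormcohort.config import SimConfig


@pytest.fixture(scope="session")
def hand_track():
    """Straight meridian track: lat 25 -> 31 over 24 h (6-hourly), lon -95."""
    times = pd.date_range("2017-08-26 00:00", "2017-08-27 00:00", freq="6h")
    return pd.DataFrame(
        {"timestamp": times, "lat": np.linspace(25.0, 31.0, 5), "lon": -95.0}
    )


@pytest.fixture(scope="session")
def hand_areas():
    return pd.DataFrame(
        {
            "area_id": ["A1", "A2", "A3"],
            "lat": [29.0, 29.0, 31.5],
            "lon": [-95.0, -94.0, -91.0],
            "rurality": ["metro", "micro", "rural"],
        }
    )


@pytest.fixture(scope="session")
def hand_stations():
    return pd.DataFrame(
        {
            "station_id": ["S1", "S2", "S3", "S4"],
            "lat": [29.0, 29.0, 29.5, 31.0],
            "lon": [-95.0, -94.5, -94.0, -91.5],
        }
    )


@pytest.fixture(scope="session")
def hand_daily_rain():
    values = {
        "S1": [10, 40, 80, 30],
        "S2": [5, 30, 60, 20],
        "S3": [0, 20, 50, 10],
        "S4": [0, 5, 10, 5],
    }
    rows = [
        (sid, dt.date(2017, 8, 24 + k), mm)
        for sid, daily in values.items()
        for k, mm in enumerate(daily)
    ]
    return pd.DataFrame(rows, columns=["station_id", "date", "precip_mm"])


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions for fast end-to-end tests."""
    return SimConfig(n_areas=40, n_stations=30, n_beneficiaries=6000)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return synthetic_data.simulate_inputs(small_config, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    built = cohort_mod.build_cohort(
        small_bundle["beneficiaries"], small_bundle["survival"], small_bundle["exposure"]
    )
    return built.data
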