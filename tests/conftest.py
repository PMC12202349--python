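"""Shared fixtures: small deterministic environments for the simulator."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from manihotsim import Environment, Management, SoilProfile, WeatherSeries
from manihotsim import synthetic_data as syn


def make_flat_weather(
    n_days: int = 420,
    tmin: float = 20.0,
    tmax: float = 30.0,
    srad: float = 16.0,
    rain: float = 6.0,
    start: date = date(2019, 1, 1),
) -> WeatherSeries:
    """Constant daily weather (thermal time 13 degCd/day at the defaults)."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    return WeatherSeries(
        pd.DataFrame(
            {
                "date": dates,
                "tmin": tmin,
                "tmax": tmax,
                "srad": srad,
                "rain": rain,
                "rh2m": 80.0,
                "wind": 1.5,
            }
        )
    )


@pytest.fixture(scope="session")
def flat_weather() -> WeatherSeries:
    return make_flat_weather()


@pytest.fixture(scope="session")
def simple_soil() -> SoilProfile:
    return syn.gen_soil("SCL", seed=0)


@pytest.fixture(scope="session")
def simple_env(flat_weather, simple_soil) -> Environment:
    mgmt = Management(planting_date=date(2019, 1, 15), duration_days=300)
    return Environment("flat", flat_weather, simple_soil, mgmt)


@pytest.fixture(scope="session")
def study_envs() -> dict[str, Environment]:
    """Three realistic synthetic location-years (shared, read-only)."""
    return syn.make_study_environments(3, seed=7)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
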