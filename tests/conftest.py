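from datetime import date as Date

import numpy as np
import pandas as pd
import pytest

from chillpea import (
    CultivarConfig,
    SoilLayer,
    SoilProfile,
    SyntheticSpec,
    default_soil_profile,
)


@pytest.fixture
def cultivar():
    """Default fixture cultivar (photoperiod-insensitive)."""
    return CultivarConfig()


@pytest.fixture
def simple_soil():
    """Single 600 mm layer: LL15 60, DUL 160, SAT 200 mm of water."""
    return SoilProfile(layers=(SoilLayer(thickness=600, ll15=60, dul=160, sat=200),))


@pytest.fixture
def default_soil():
    return default_soil_profile()


@pytest.fixture
def default_spec():
    return SyntheticSpec(seed=1)


def make_weather(
    start: Date,
    n_days: int,
    tmin: float = 10.0,
    tmax: float = 20.0,
    rain: float = 0.0,
):
    """Constant-weather helper table."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame(
        {
            "date": dates,
            "tmin": np.full(n_days, float(tmin)),
            "tmax": np.full(n_days, float(tmax)),
            "rain": np.full(n_days, float(rain)),
            "radn": np.full(n_days, 15.0),
        }
    )


def make_soilwater(dates, soil: SoilProfile, fasw: float):
    """Per-layer soil-water table pinned at a uniform FASW."""
    dates = pd.DatetimeIndex(dates)
    data = {"date": dates}
    for i, layer in enumerate(soil.layers):
        sw = layer.ll15 + fasw * (layer.dul - layer.ll15)
        data[f"sw{i + 1}"] = np.full(len(dates), sw)
    return pd.DataFrame(data)


@pytest.fixture
def weather_factory():
    return make_weather


@pytest.fixture
def soilwater_factory():
    return make_soilwater
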