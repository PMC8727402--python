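"""Readers and writers for the weather CSV dialect, configs and results.

Weather CSVs carry the header ``date,tmin,tmax,rain,radn`` with ISO-8601
dates; the same dialect the synthetic generator writes.  Configuration is
YAML with key names matching the dataclass fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .phenology import CultivarConfig, SoilLayer, SoilProfile
from .synthetic_data import SyntheticSpec

__all__ = [
    "read_weather_csv",
    "write_weather_csv",
    "load_synthetic_spec",
    "load_soil_profile",
    "load_cultivar",
    "write_results",
]

WEATHER_COLUMNS = ["date", "tmin", "tmax", "rain", "radn"]


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    """Check column set, date contiguity and tmin <= tmax; returns df."""
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather table missing columns: {missing}")
    dates = pd.DatetimeIndex(df["date"])
    gaps = np.flatnonzero((dates[1:] - dates[:-1]) != pd.Timedelta(days=1))
    if len(gaps):
        missing = (dates[gaps[0]] + pd.Timedelta(days=1)).date()
        raise ValueError(
            f"weather dates not contiguous: missing calendar day {missing}"
        )
    bad = np.flatnonzero(df["tmin"].to_numpy() > df["tmax"].to_numpy())
    if len(bad):
        raise ValueError(
            f"tmin exceeds tmax at row {int(bad[0])} "
            f"(date {dates[bad[0]].date()})"
        )
    return df


def read_weather_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a daily weather CSV."""
    df = pd.read_csv(path, parse_dates=["date"])
    return validate_weather(df)


def write_weather_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write weather with ISO dates at full float precision.

    Full precision makes a write/read round trip reproduce the series
    exactly, and identical inputs produce byte-identical files.
    """
    out = df.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_results(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a results table deterministically (fixed float format)."""
    table.to_csv(path, index=False, float_format="%.6g")


def load_synthetic_spec(cfg: dict) -> SyntheticSpec:
    return SyntheticSpec(**cfg)


def load_soil_profile(cfg: dict) -> SoilProfile:
    layers = tuple(SoilLayer(**layer) for layer in cfg["layers"])
    return SoilProfile(layers=layers)


def load_cultivar(cfg: dict) -> CultivarConfig:
    return CultivarConfig(**cfg)


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
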