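"""Post-flowering frost events, yield penalties and frost-risk overlap.

A frost event is a day whose screen (1.5 m) minimum temperature is at or
below 0 degC.  Each post-flowering event removes about 5% of yield; the
default compounding is multiplicative (bounded below by zero), with an
additive mode for sensitivity analysis.  Frost risk at flowering is
summarised by the overlap coefficient of kernel-density estimates of frost
day-of-year and peak-flowering day-of-year across years.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "FrostSummary",
    "OverlapReport",
    "count_frost_events",
    "apply_frost_penalty",
    "flowering_frost_overlap",
]


@dataclass
class FrostSummary:
    events: int
    event_dates: list[Date]
    window: tuple[Date, Date]


@dataclass
class OverlapReport:
    overlap_coefficient: float
    n_frost_days: int
    n_years: int
    no_frost: bool = False


def count_frost_events(
    weather: pd.DataFrame, window: tuple[Date, Date], threshold: float = 0.0
) -> FrostSummary:
    """Count days with tmin <= threshold inside the closed window."""
    start, end = window
    if end < start:
        raise ValueError(f"empty frost window {start}..{end}")
    dates = pd.DatetimeIndex(weather["date"])
    if pd.Timestamp(start) < dates[0] or pd.Timestamp(end) > dates[-1]:
        raise ValueError(f"window {start}..{end} outside the weather span")
    mask = (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
    tmin = weather["tmin"].to_numpy()[mask]
    days = dates[mask]
    hits = tmin <= threshold
    return FrostSummary(
        events=int(hits.sum()),
        event_dates=[d.date() for d in days[hits]],
        window=(start, end),
    )


def apply_frost_penalty(
    potential_yield: float,
    events: int,
    loss_per_event: float = 0.05,
    mode: str = "multiplicative",
) -> float:
    """Frost-affected yield after ``events`` post-flowering frost events.

    multiplicative: YF = Y * (1 - loss)^events (default, never negative);
    additive:       YF = Y * max(0, 1 - loss * events).
    """
    if potential_yield < 0:
        raise ValueError("potential_yield must be >= 0")
    if events < 0:
        raise ValueError("events must be >= 0")
    if not 0.0 <= loss_per_event <= 1.0:
        raise ValueError(
            f"loss_per_event must lie in [0, 1], got {loss_per_event}"
        )
    if mode == "multiplicative":
        return potential_yield * (1.0 - loss_per_event) ** events
    if mode == "additive":
        return potential_yield * max(0.0, 1.0 - loss_per_event * events)
    raise ValueError(f"unknown penalty mode {mode!r}")


_DOY_GRID = np.arange(1, 367, dtype=float)


def _doy_kde(sample: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Silverman bandwidth) on the day-of-year grid.

    Degenerate samples (single point or zero spread) fall back to a fixed
    1-day-bandwidth Gaussian.
    """
    sample = np.asarray(sample, dtype=float)
    if len(sample) >= 2 and np.ptp(sample) > 0:
        return gaussian_kde(sample, bw_method="silverman")(_DOY_GRID)
    dens = np.zeros_like(_DOY_GRID)
    for x in sample:
        dens += np.exp(-0.5 * (_DOY_GRID - x) ** 2) / np.sqrt(2 * np.pi)
    return dens / len(sample)


def flowering_frost_overlap(
    peak_flowering_doys: Sequence[int], frost_doys: Sequence[int]
) -> OverlapReport:
    """Overlap coefficient of frost and peak-flowering day-of-year densities.

    Both samples are smoothed with a Gaussian KDE and evaluated on the day
    1..366 grid; the coefficient is sum(min(f_frost, f_peak)) * 1 day, in
    [0, 1].  An empty frost sample yields coefficient 0 with ``no_frost``
    set (the "absence of a blue line" case).  Wrap-around at the year
    boundary is ignored; both samples are expected mid-year.
    """
    peaks = np.asarray(list(peak_flowering_doys), dtype=float)
    frost = np.asarray(list(frost_doys), dtype=float)
    if len(peaks) == 0:
        raise ValueError("peak flowering sample must be non-empty")
    for arr, nm in ((peaks, "peak"), (frost, "frost")):
        if len(arr) and (arr.min() < 1 or arr.max() > 366):
            raise ValueError(f"{nm} day-of-year values must lie in [1, 366]")
    if len(frost) == 0:
        return OverlapReport(
            overlap_coefficient=0.0,
            n_frost_days=0,
            n_years=len(peaks),
            no_frost=True,
        )
    f_peak = _doy_kde(peaks)
    f_frost = _doy_kde(frost)
    coef = float(np.minimum(f_peak, f_frost).sum())
    return OverlapReport(
        overlap_coefficient=min(coef, 1.0),
        n_frost_days=len(frost),
        n_years=len(peaks),
    )
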