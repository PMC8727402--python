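"""Thermal-time phenology for chickpea with a soil-water modifier.

Stage progression is driven by accumulated daily thermal time (degC-days).
Above a fractional-available-soil-water (FASW) activation boundary, and once
the crop has emerged, the day's thermal time is multiplied by a linear factor
``intercept - FASW`` (1 at the boundary, minimal near field capacity), so wet
soil slows perceived thermal time and delays flowering.  A photoperiod factor
(linear ramp between a critical and a saturating day length) multiplies the
accumulated amount as well.

Daily thermal time follows the APSIM convention: the diurnal course is sampled
at eight three-hourly points interpolated between Tmin and Tmax, each point is
passed through a piecewise-linear temperature response (zero at the base
temperature, rising to a plateau at the optimum, falling to zero at the
maximum) and the eight responses are averaged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "SoilLayer",
    "SoilProfile",
    "CultivarConfig",
    "PhenoTrace",
    "SowingDecision",
    "daily_thermal_time",
    "compute_fasw",
    "fasw_series",
    "modify_thermal_time",
    "photoperiod_factor",
    "day_length",
    "choose_sowing_date",
    "run_phenology",
]


class Stage(IntEnum):
    """Phenological stages, ordered."""

    SOWING = 1
    GERMINATION = 2
    EMERGENCE = 3
    END_JUVENILE = 4
    FLOWERING = 5
    END_FLOWERING = 6
    END_PODFILL = 7
    MATURITY = 8


@dataclass(frozen=True)
class SoilLayer:
    """One soil layer: depth thickness (mm) and water contents (mm of water).

    ``ll15`` is the water held at 1.5 MPa suction (wilting point), ``dul`` the
    drained upper limit (field capacity) and ``sat`` saturation.
    """

    thickness: float
    ll15: float
    dul: float
    sat: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer thickness must be > 0, got {self.thickness}")
        if not (0 <= self.ll15 < self.dul <= self.sat):
            raise ValueError(
                f"layer requires 0 <= ll15 < dul <= sat, got "
                f"ll15={self.ll15}, dul={self.dul}, sat={self.sat}"
            )


@dataclass(frozen=True)
class SoilProfile:
    """Ordered soil layers, top first."""

    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("soil profile must contain at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.pawc <= 0:
            raise ValueError("profile PAWC must be > 0")

    @property
    def pawc(self) -> float:
        """Plant-available water holding capacity, sum(DUL - LL15) in mm."""
        return float(sum(l.dul - l.ll15 for l in self.layers))

    @property
    def depth(self) -> float:
        """Total profile depth in mm."""
        return float(sum(l.thickness for l in self.layers))

    def plant_available_water(self, sw: Sequence[float]) -> float:
        """Whole-profile plant-available water sum(sw - ll15), mm."""
        return float(sum(max(0.0, s - l.ll15) for s, l in zip(sw, self.layers)))


@dataclass
class CultivarConfig:
    """Cultivar phenology parameters.

    Thermal-time targets are in degC-days.  The juvenile-phase default of
    690 degCd is the calibrated PBA HatTrick value; the remaining targets are
    synthetic fixture values of realistic magnitude.  Cardinal temperatures
    default to 0/30/40 degC.
    """

    name: str = "PBA HatTrick"
    tt_sowing_to_emergence: float = 120.0
    tt_emergence_to_end_juvenile: float = 690.0
    tt_end_juvenile_to_flowering: float = 200.0
    tt_flowering_to_end_flowering: float = 250.0
    tt_flowering_to_end_podfill: float = 800.0
    base_temp: float = 0.0
    opt_temp: float = 30.0
    max_temp: float = 40.0
    photoperiod_critical: float = 10.5
    photoperiod_saturating: float = 14.0
    photoperiod_sensitivity: float = 0.0
    fasw_threshold: float = 0.65
    fasw_modifier_intercept: float = 1.65

    def __post_init__(self) -> None:
        if not (self.base_temp < self.opt_temp < self.max_temp):
            raise ValueError("require base_temp < opt_temp < max_temp")
        for attr in (
            "tt_sowing_to_emergence",
            "tt_emergence_to_end_juvenile",
            "tt_end_juvenile_to_flowering",
            "tt_flowering_to_end_flowering",
            "tt_flowering_to_end_podfill",
        ):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if self.tt_flowering_to_end_podfill <= self.tt_flowering_to_end_flowering:
            raise ValueError(
                "tt_flowering_to_end_podfill must exceed tt_flowering_to_end_flowering"
            )
        if not 0.0 <= self.fasw_threshold <= 1.0:
            raise ValueError("fasw_threshold must lie in [0, 1]")
        if self.fasw_modifier_intercept <= self.fasw_threshold:
            raise ValueError("fasw_modifier_intercept must exceed fasw_threshold")
        if not 0.0 <= self.photoperiod_sensitivity <= 1.0:
            raise ValueError("photoperiod_sensitivity must lie in [0, 1]")
        if not self.photoperiod_critical < self.photoperiod_saturating:
            raise ValueError("photoperiod_critical must be < photoperiod_saturating")


# Three-hourly interpolation fractions between Tmin and Tmax (APSIM convention),
# k = 1..8: f(k) = 0.92105 + 0.1140 k - 0.0703 k^2 + 0.0053 k^3.
_K = np.arange(1, 9, dtype=float)
_THREE_HOUR_FRACTIONS = 0.92105 + 0.1140 * _K - 0.0703 * _K**2 + 0.0053 * _K**3


def _temp_response(t: np.ndarray, cv: CultivarConfig) -> np.ndarray:
    """Piecewise-linear thermal-time response at temperature(s) ``t``."""
    t = np.asarray(t, dtype=float)
    rise = np.clip(t - cv.base_temp, 0.0, cv.opt_temp - cv.base_temp)
    fall = np.where(
        t > cv.opt_temp,
        (cv.opt_temp - cv.base_temp)
        * np.clip((cv.max_temp - t) / (cv.max_temp - cv.opt_temp), 0.0, 1.0),
        rise,
    )
    return fall


def daily_thermal_time(tmin: float, tmax: float, cv: CultivarConfig) -> float:
    """Daily thermal time (degCd) from screen Tmin/Tmax.

    Averages the piecewise-linear response over eight three-hourly
    temperatures interpolated between Tmin and Tmax.
    """
    if tmin > tmax:
        raise ValueError(f"tmin ({tmin}) must not exceed tmax ({tmax})")
    temps = tmin + _THREE_HOUR_FRACTIONS * (tmax - tmin)
    return float(np.mean(_temp_response(temps, cv)))


_DEPTH_WARNED: set[float] = set()


def _depth_weights(soil: SoilProfile, depth_limit: float) -> np.ndarray:
    """Per-layer inclusion weight for the top ``depth_limit`` mm of soil."""
    if depth_limit >= soil.depth:
        if depth_limit > soil.depth and depth_limit not in _DEPTH_WARNED:
            _DEPTH_WARNED.add(depth_limit)
            logger.warning(
                "depth limit %.0f mm exceeds profile depth %.0f mm; "
                "using the whole profile",
                depth_limit,
                soil.depth,
            )
        return np.ones(len(soil.layers))
    w = np.empty(len(soil.layers))
    top = 0.0
    for i, layer in enumerate(soil.layers):
        w[i] = np.clip((depth_limit - top) / layer.thickness, 0.0, 1.0)
        top += layer.thickness
    return w


def compute_fasw(
    sw: Sequence[float], soil: SoilProfile, depth_limit: float = 600.0
) -> float:
    """Fractional available soil water over the top ``depth_limit`` mm.

    FASW = sum(sw - ll15) / sum(dul - ll15) over the included layers (the
    layer straddling the depth limit is pro-rated), clipped to [0, 1]: 1 at
    field capacity, 0 at wilting point.
    """
    w = _depth_weights(soil, depth_limit)
    sw = np.asarray(sw, dtype=float)
    ll15 = np.array([l.ll15 for l in soil.layers])
    dul = np.array([l.dul for l in soil.layers])
    avail = float(np.sum(w * (sw - ll15)))
    capacity = float(np.sum(w * (dul - ll15)))
    return float(np.clip(avail / capacity, 0.0, 1.0))


def fasw_series(
    soilwater: pd.DataFrame, soil: SoilProfile, depth_limit: float = 600.0
) -> pd.Series:
    """Vectorised FASW for a daily per-layer soil-water table.

    ``soilwater`` has a ``date`` column and one ``sw<i>`` column per layer
    (start-of-day water, mm).
    """
    w = _depth_weights(soil, depth_limit)
    cols = [f"sw{i + 1}" for i in range(len(soil.layers))]
    sw = soilwater[cols].to_numpy(dtype=float)
    ll15 = np.array([l.ll15 for l in soil.layers])
    dul = np.array([l.dul for l in soil.layers])
    capacity = float(np.sum(w * (dul - ll15)))
    vals = np.clip((sw - ll15) @ w / capacity, 0.0, 1.0)
    return pd.Series(vals, index=pd.DatetimeIndex(soilwater["date"]), name="fasw")


def modify_thermal_time(
    tt_day: float, fasw: float, stage: int, cv: Optional[CultivarConfig] = None
) -> float:
    """Soil-water modification of the day's thermal time.

    Returns ``tt_day * (intercept - fasw)`` when ``fasw`` is at or above the
    activation boundary and the crop has emerged (stage >= 3); otherwise the
    thermal time is unchanged.  The multiplier is rounded to 12 decimal
    places to strip the binary representation error of the decimal constants
    (1.65, 0.65), so that the boundary identity TTm == TT holds exactly at
    ``fasw == threshold``.
    """
    if cv is None:
        cv = CultivarConfig()
    if tt_day < 0:
        raise ValueError("tt_day must be >= 0")
    if not 0.0 <= fasw <= 1.0:
        raise ValueError(f"fasw must lie in [0, 1], got {fasw}")
    if fasw >= cv.fasw_threshold and stage >= Stage.EMERGENCE:
        multiplier = float(np.round(cv.fasw_modifier_intercept - fasw, 12))
        return tt_day * multiplier
    return tt_day


def day_length(latitude: float, day_of_year: int) -> float:
    """Civil day length (hours) from the textbook sunrise equation.

    Solar declination: -23.44 deg * cos(2 pi (doy + 10) / 365.25).
    """
    if abs(latitude) >= 67.0:
        raise ValueError("polar latitudes (|lat| >= 67) are out of scope")
    decl = math.radians(-23.44) * math.cos(
        2.0 * math.pi * (day_of_year + 10) / 365.25
    )
    cos_h = -math.tan(math.radians(latitude)) * math.tan(decl)
    cos_h = min(1.0, max(-1.0, cos_h))
    return 24.0 / math.pi * math.acos(cos_h)


def photoperiod_factor(day_length_h: float, cv: CultivarConfig) -> float:
    """Linear photoperiod ramp multiplying the day's (modified) thermal time.

    1 at or above the saturating day length, ``1 - sensitivity`` at or below
    the critical day length, linear between.
    """
    if not 0.0 < day_length_h <= 24.0:
        raise ValueError("day length must lie in (0, 24] h")
    if day_length_h >= cv.photoperiod_saturating:
        return 1.0
    if day_length_h <= cv.photoperiod_critical:
        return 1.0 - cv.photoperiod_sensitivity
    frac = (day_length_h - cv.photoperiod_critical) / (
        cv.photoperiod_saturating - cv.photoperiod_critical
    )
    return 1.0 - cv.photoperiod_sensitivity * (1.0 - frac)


@dataclass
class SowingDecision:
    """Outcome of the sowing rule: the chosen date and whether it was forced."""

    date: Date
    forced: bool


def choose_sowing_date(
    weather: pd.DataFrame,
    soilwater: pd.DataFrame,
    soil: SoilProfile,
    window: tuple[Date, Date],
) -> SowingDecision:
    """First day in the window meeting the sowing rule, else the last day.

    Rule: trailing 7-day rainfall (inclusive) >= 25 mm AND whole-profile
    plant-available water > 80 mm.  If no day qualifies the last day of the
    window is returned with ``forced=True``.
    """
    start, end = window
    dates = pd.DatetimeIndex(weather["date"])
    if pd.Timestamp(start) < dates[0] or pd.Timestamp(end) > dates[-1]:
        raise ValueError(f"sowing window {start}..{end} outside the weather span")
    rain = pd.Series(weather["rain"].to_numpy(), index=dates)
    rain7 = rain.rolling(7, min_periods=1).sum()
    cols = [f"sw{i + 1}" for i in range(len(soil.layers))]
    sw = soilwater.set_index(pd.DatetimeIndex(soilwater["date"]))[cols]
    ll15 = np.array([l.ll15 for l in soil.layers])
    paw = (sw.to_numpy() - ll15).clip(min=0.0).sum(axis=1)
    paw = pd.Series(paw, index=sw.index)
    day = pd.Timestamp(start)
    while day <= pd.Timestamp(end):
        if rain7.loc[day] >= 25.0 and paw.loc[day] > 80.0:
            return SowingDecision(day.date(), forced=False)
        day += pd.Timedelta(days=1)
    return SowingDecision(end, forced=True)


@dataclass
class PhenoTrace:
    """Daily phenology trace plus the key stage dates.

    ``daily`` has one row per day from sowing: date, stage (end of day),
    tt_day, ttm_day (after the soil-water modifier), fasw (start of day) and
    cum_ttm (photoperiod-adjusted accumulation within the current phase).
    """

    daily: pd.DataFrame
    sowing_date: Date
    flowering_start: Optional[Date] = None
    flowering_end: Optional[Date] = None
    peak_flowering: Optional[Date] = None
    podfill_end: Optional[Date] = None
    complete: bool = False
    forced_sowing: bool = False

    @property
    def rp(self) -> Optional[tuple[Date, Date]]:
        """Reproductive period [flowering start, end of pod fill]."""
        if self.flowering_start is None or self.podfill_end is None:
            return None
        return (self.flowering_start, self.podfill_end)


def run_phenology(
    weather: pd.DataFrame,
    soilwater: pd.DataFrame,
    soil: SoilProfile,
    cv: CultivarConfig,
    sowing_date: Date,
    latitude: float = -35.0,
) -> PhenoTrace:
    """Run daily stage progression from sowing until end of pod fill.

    Each phase accumulates photoperiod-adjusted, soil-water-modified thermal
    time from the day after the phase starts; the next stage is entered on the
    day the phase target is met (any excess is discarded).  Germination is
    entered the day after sowing.  End of flowering and end of pod fill share
    one accumulator counted from the start of flowering.  If the weather ends
    before pod fill completes the trace is truncated and ``complete`` is
    False.
    """
    dates = pd.DatetimeIndex(weather["date"])
    sow = pd.Timestamp(sowing_date)
    if sow < dates[0] or sow > dates[-1]:
        raise ValueError(f"sowing date {sowing_date} outside the weather span")
    wx = weather.set_index(dates)
    fasw = fasw_series(soilwater, soil)

    stage = Stage.SOWING
    acc = 0.0
    rows = []
    flowering_start = flowering_end = podfill_end = None
    targets_after_flowering = (
        cv.tt_flowering_to_end_flowering,
        cv.tt_flowering_to_end_podfill,
    )

    for day in pd.date_range(sow, dates[-1], freq="D"):
        rec = wx.loc[day]
        f = float(fasw.loc[day]) if day in fasw.index else 0.0
        tt = daily_thermal_time(float(rec["tmin"]), float(rec["tmax"]), cv)
        if day == sow:
            rows.append((day, int(stage), tt, tt, f, 0.0))
            continue
        if stage == Stage.SOWING:
            stage = Stage.GERMINATION
        ttm = modify_thermal_time(tt, f, int(stage), cv)
        pp = photoperiod_factor(day_length(latitude, day.dayofyear), cv)
        acc += ttm * pp
        if stage == Stage.GERMINATION and acc >= cv.tt_sowing_to_emergence:
            stage, acc = Stage.EMERGENCE, 0.0
        elif stage == Stage.EMERGENCE and acc >= cv.tt_emergence_to_end_juvenile:
            stage, acc = Stage.END_JUVENILE, 0.0
        elif stage == Stage.END_JUVENILE and acc >= cv.tt_end_juvenile_to_flowering:
            stage, acc = Stage.FLOWERING, 0.0
            flowering_start = day.date()
        elif stage == Stage.FLOWERING and acc >= targets_after_flowering[0]:
            stage = Stage.END_FLOWERING  # accumulator keeps running to pod fill
            flowering_end = day.date()
        if stage == Stage.END_FLOWERING and acc >= targets_after_flowering[1]:
            stage = Stage.END_PODFILL
            podfill_end = day.date()
        rows.append((day, int(stage), tt, ttm, f, acc))
        if stage == Stage.END_PODFILL:
            break

    daily = pd.DataFrame(
        rows, columns=["date", "stage", "tt_day", "ttm_day", "fasw", "cum_ttm"]
    )
    peak = None
    if flowering_start is not None and flowering_end is not None:
        peak = flowering_start + timedelta(
            days=(flowering_end - flowering_start).days // 2
        )
    return PhenoTrace(
        daily=daily,
        sowing_date=sowing_date,
        flowering_start=flowering_start,
        flowering_end=flowering_end,
        peak_flowering=peak,
        podfill_end=podfill_end,
        complete=podfill_end is not None,
    )
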