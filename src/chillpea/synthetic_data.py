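"""Synthetic weather, soil water and yields with a known implanted cold effect.

The generator emulates the statistical structure the downstream analysis
needs rather than any particular station record:

* daily mean temperature = annual sinusoid (phase set by hemisphere)
  + AR(1) day-to-day anomalies (synoptic persistence)
  + an independent year-level anomaly (interannual variability);
  Tmin/Tmax are placed symmetrically around it at a fixed diurnal range;
* rainfall = Bernoulli occurrence x Gamma amounts;
* annual potential yield = g0 + g2 * R - g1 * P(T_C) + Gaussian noise, where
  R is reproductive-period rainfall and P the percentage of reproductive-
  period days with Tmin at or below the implanted threshold.

Every output is a pure function of (spec, seed); random substreams are keyed
by (seed, year, component) so extending the year range never perturbs
already-generated years.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date as Date
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .phenology import SoilProfile

__all__ = [
    "SyntheticSpec",
    "generate_weather",
    "simulate_soil_water",
    "generate_yields",
    "make_season_records",
    "default_soil_profile",
]

# substream component codes
_C_TEMP, _C_YEAR, _C_RAIN, _C_RADN, _C_YIELD = range(5)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic site.

    The default site is a stylised temperate location whose September-
    November daily minima cluster around the implanted 10 degC threshold:
    that is the condition under which a cold-temperature threshold is
    statistically identifiable from 70 seasons.  The default site is
    effectively frost-free; lowering ``temp_mean_annual`` to ~8 degC gives a
    frosty site.
    """

    latitude: float = -35.0
    longitude: float = 147.0
    year_start: int = 1950
    year_end: int = 2019
    temp_mean_annual: float = 15.5
    temp_seasonal_amplitude: float = 2.0
    diurnal_range_mean: float = 11.0
    temp_noise_sd: float = 1.5
    temp_ar1: float = 0.9
    temp_interannual_sd: float = 0.5
    rain_prob_per_day: float = 0.30
    rain_gamma_shape: float = 0.8
    rain_gamma_scale: float = 6.0
    yield_intercept: float = 1500.0
    yield_rain_coef: float = 2.0
    yield_cold_coef: float = 5.0
    implanted_tc: float = 10.0
    yield_noise_sd: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        if self.temp_seasonal_amplitude < 0:
            raise ValueError("temp_seasonal_amplitude must be >= 0")
        if self.temp_noise_sd < 0:
            raise ValueError("temp_noise_sd must be >= 0")
        if not 0.0 <= self.temp_ar1 < 1.0:
            raise ValueError("temp_ar1 must lie in [0, 1)")
        if self.temp_interannual_sd < 0:
            raise ValueError("temp_interannual_sd must be >= 0")
        if self.diurnal_range_mean < 0:
            raise ValueError("diurnal_range_mean must be >= 0")
        if not 0.0 <= self.rain_prob_per_day <= 1.0:
            raise ValueError("rain_prob_per_day must lie in [0, 1]")
        if self.rain_gamma_shape <= 0 or self.rain_gamma_scale <= 0:
            raise ValueError("rain_gamma_shape and rain_gamma_scale must be > 0")
        if self.yield_cold_coef < 0:
            raise ValueError(
                "yield_cold_coef is a loss magnitude and must be >= 0"
            )
        if not 0.0 <= self.implanted_tc <= 19.0:
            raise ValueError("implanted_tc must lie in the scan range [0, 19]")
        if self.yield_noise_sd < 0:
            raise ValueError("yield_noise_sd must be >= 0")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=int(seed))


def _rng(spec: SyntheticSpec, year: int, component: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), int(year), int(component)])


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), n)
    innov[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -rho], innov)


def generate_weather(spec: SyntheticSpec) -> pd.DataFrame:
    """Daily weather table: date, tmin, tmax, rain (mm), radn (MJ/m2).

    Dates are contiguous calendar days covering the spec's year range.  In
    the southern hemisphere (latitude < 0) the temperature sinusoid peaks in
    mid-January so the coldest period falls mid-year.
    """
    peak_doy = 15.0 if spec.latitude < 0 else 197.0
    frames = []
    for year in spec.years:
        days = pd.date_range(Date(year, 1, 1), Date(year, 12, 31), freq="D")
        doy = days.dayofyear.to_numpy(dtype=float)
        clim = spec.temp_mean_annual + spec.temp_seasonal_amplitude * np.cos(
            2.0 * np.pi * (doy - peak_doy) / 365.25
        )
        anom = _ar1(_rng(spec, year, _C_TEMP), len(days), spec.temp_ar1,
                    spec.temp_noise_sd)
        year_eff = (
            _rng(spec, year, _C_YEAR).normal(0.0, spec.temp_interannual_sd)
            if spec.temp_interannual_sd > 0
            else 0.0
        )
        center = clim + anom + year_eff
        half_range = spec.diurnal_range_mean / 2.0
        rng_rain = _rng(spec, year, _C_RAIN)
        wet = rng_rain.random(len(days)) < spec.rain_prob_per_day
        amounts = rng_rain.gamma(
            spec.rain_gamma_shape, spec.rain_gamma_scale, len(days)
        )
        rain = np.where(wet, amounts, 0.0)
        radn_clim = 18.0 + 8.0 * np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)
        radn_noise = (
            _rng(spec, year, _C_RADN).normal(0.0, 1.5, len(days))
            if spec.temp_noise_sd > 0
            else 0.0
        )
        radn = np.clip(radn_clim + radn_noise, 0.5, None)
        frames.append(
            pd.DataFrame(
                {
                    "date": days,
                    "tmin": center - half_range,
                    "tmax": center + half_range,
                    "rain": rain,
                    "radn": radn,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def default_soil_profile() -> SoilProfile:
    """A five-layer loam-like profile (synthetic), PAWC ~195 mm."""
    from .phenology import SoilLayer

    return SoilProfile(
        layers=(
            SoilLayer(thickness=150, ll15=30, dul=55, sat=65),
            SoilLayer(thickness=150, ll15=30, dul=55, sat=65),
            SoilLayer(thickness=300, ll15=60, dul=105, sat=125),
            SoilLayer(thickness=300, ll15=60, dul=100, sat=120),
            SoilLayer(thickness=600, ll15=120, dul=180, sat=220),
        )
    )


def simulate_soil_water(
    weather: pd.DataFrame,
    soil: SoilProfile,
    drainage_frac: float = 0.5,
    et_coef: float = 0.10,
    initial_fasw: float = 0.5,
) -> pd.DataFrame:
    """Bucket-cascade soil water balance; returns start-of-day water per layer.

    Daily update, applied after recording the day's start-of-day state: rain
    enters the top layer; water above saturation overflows downward
    immediately; a fraction ``drainage_frac`` of the water above the drained
    upper limit percolates to the next layer (out of the profile from the
    bottom); evapotranspiration demand ``et_coef * max(0, Tmean)`` (mm/day)
    is extracted top-down, bounded below by LL15.  On every 1 November the
    profile is reset so FASW equals 0.5 in every layer, mimicking a winter
    fallow.
    """
    dates = pd.DatetimeIndex(weather["date"])
    if len(dates) == 0:
        raise ValueError("weather is empty")
    if not (dates[1:] - dates[:-1] == pd.Timedelta(days=1)).all():
        raise ValueError("weather dates must be contiguous")
    nl = len(soil.layers)
    ll15 = np.array([l.ll15 for l in soil.layers])
    dul = np.array([l.dul for l in soil.layers])
    sat = np.array([l.sat for l in soil.layers])
    sw = ll15 + float(initial_fasw) * (dul - ll15)

    tmean = (weather["tmin"].to_numpy() + weather["tmax"].to_numpy()) / 2.0
    rain = weather["rain"].to_numpy(dtype=float)
    out = np.empty((len(dates), nl))
    for i, day in enumerate(dates):
        if day.month == 11 and day.day == 1:
            sw = ll15 + 0.5 * (dul - ll15)
        out[i] = sw
        sw = sw.copy()
        sw[0] += rain[i]
        # saturation overflow cascades immediately
        for j in range(nl):
            excess = sw[j] - sat[j]
            if excess > 0:
                sw[j] = sat[j]
                if j + 1 < nl:
                    sw[j + 1] += excess
        # drainage of water held above DUL
        for j in range(nl):
            above = sw[j] - dul[j]
            if above > 0:
                drain = drainage_frac * above
                sw[j] -= drain
                if j + 1 < nl:
                    sw[j + 1] = min(sw[j + 1] + drain, sat[j + 1])
        # evapotranspiration extraction, top-down
        demand = et_coef * max(0.0, tmean[i])
        for j in range(nl):
            if demand <= 0:
                break
            take = min(demand, sw[j] - ll15[j])
            if take > 0:
                sw[j] -= take
                demand -= take
    df = pd.DataFrame(out, columns=[f"sw{i + 1}" for i in range(nl)])
    df.insert(0, "date", dates)
    return df


def generate_yields(
    per_year: Mapping[int, Mapping[str, float]], spec: SyntheticSpec
) -> dict[int, float]:
    """Potential annual yields (kg/ha) from the linear truth model.

    ``per_year`` maps year -> {"r": reproductive-period rainfall (mm),
    "p": cold-day percentage at the implanted threshold}.  The yield for
    year t is ``g0 + g2 * R_t - g1 * P_t + eps_t`` floored at zero, with
    eps_t ~ Normal(0, yield_noise_sd^2) drawn from the year's substream.
    """
    yields = {}
    for year, vals in per_year.items():
        eps = (
            _rng(spec, year, _C_YIELD).normal(0.0, spec.yield_noise_sd)
            if spec.yield_noise_sd > 0
            else 0.0
        )
        y = (
            spec.yield_intercept
            + spec.yield_rain_coef * float(vals["r"])
            - spec.yield_cold_coef * float(vals["p"])
            + eps
        )
        yields[year] = max(0.0, y)
    return yields


def make_season_records(
    spec: SyntheticSpec,
    rp_start: tuple[int, int] = (9, 1),
    rp_end: tuple[int, int] = (11, 30),
    apply_frost: bool = False,
):
    """Season records for the threshold-recovery study conditions.

    Uses a fixed reproductive window (default 1 September - 30 November, the
    window the default cultivar reaches under the default climate) rather
    than running the phenology engine, so that large replicate studies stay
    cheap.  Returns a list of :class:`chillpea.threshold_detection.SeasonRecord`.
    """
    from .frost_yield import apply_frost_penalty
    from .threshold_detection import SeasonRecord

    weather = generate_weather(spec)
    dates = pd.DatetimeIndex(weather["date"])
    tmin = weather["tmin"].to_numpy()
    rain = weather["rain"].to_numpy()
    per_year: dict[int, dict[str, float]] = {}
    rp_tmin: dict[int, np.ndarray] = {}
    frost_counts: dict[int, int] = {}
    for year in spec.years:
        lo = pd.Timestamp(Date(year, *rp_start))
        hi = pd.Timestamp(Date(year, *rp_end))
        mask = (dates >= lo) & (dates <= hi)
        t = tmin[mask]
        rp_tmin[year] = t
        frost_counts[year] = int(np.sum(t <= 0.0))
        per_year[year] = {
            "r": float(rain[mask].sum()),
            "p": 100.0 * float(np.mean(t <= spec.implanted_tc)),
        }
    yields = generate_yields(per_year, spec)
    records = []
    for year in spec.years:
        yf = yields[year]
        if apply_frost:
            yf = apply_frost_penalty(yf, frost_counts[year])
        records.append(
            SeasonRecord(
                year=year,
                yf=yf,
                r=per_year[year]["r"],
                rp_tmin=rp_tmin[year],
            )
        )
    return records
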