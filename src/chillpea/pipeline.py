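"""End-to-end scenario orchestration.

For every (location, cultivar, sowing window, year): generate weather, run
the bucket water balance (with the 1 November reset), apply the sowing rule
inside the window, run phenology, count reproductive-period frost events,
draw the season's potential yield from the synthetic truth model, apply the
frost penalty, and collect a season record.  Each (location, cultivar,
window) combination then goes through threshold detection, and sites with a
detection feed the spatial T_C-on-geography regression.

Everything is a pure function of the config and master seed; per-location
substreams are keyed by the location name so adding a location never
perturbs another location's rows.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from datetime import date as Date

import numpy as np
import pandas as pd

from .frost_yield import apply_frost_penalty, count_frost_events
from .phenology import (
    CultivarConfig,
    SoilProfile,
    choose_sowing_date,
    run_phenology,
)
from .synthetic_data import (
    SyntheticSpec,
    default_soil_profile,
    generate_weather,
    generate_yields,
    simulate_soil_water,
)
from .threshold_detection import (
    SeasonRecord,
    ThresholdResult,
    detect_threshold,
    spatial_threshold_regression,
)

logger = logging.getLogger(__name__)

__all__ = ["Location", "ScenarioConfig", "ScenarioResults", "run_scenarios"]

DEFAULT_WINDOWS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "early": ((4, 10), (4, 30)),
    "mid": ((5, 1), (5, 21)),
    "late": ((5, 22), (6, 11)),
}


@dataclass(frozen=True)
class Location:
    name: str
    spec: SyntheticSpec
    soil: SoilProfile = field(default_factory=default_soil_profile)

    @property
    def latitude(self) -> float:
        return self.spec.latitude

    @property
    def longitude(self) -> float:
        return self.spec.longitude


@dataclass
class ScenarioConfig:
    locations: list[Location]
    cultivars: list[CultivarConfig] = field(
        default_factory=lambda: [CultivarConfig()]
    )
    sowing_windows: dict[str, tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    penalty_mode: str = "multiplicative"
    grid_lo: float = 0.0
    grid_hi: float = 19.0
    grid_step: float = 0.1
    master_seed: int = 0


@dataclass
class ScenarioResults:
    seasons: pd.DataFrame
    thresholds: pd.DataFrame
    threshold_results: dict[tuple[str, str, str], ThresholdResult]
    spatial: object = None  # GeoRegression when >= 3 sites detected


def _location_seed(master_seed: int, name: str) -> int:
    crc = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return (int(master_seed) * 1_000_003 + crc) % (2**31 - 1)


def run_scenarios(config: ScenarioConfig) -> ScenarioResults:
    """Run the full factorial and the per-combination threshold detection."""
    season_rows = []
    threshold_rows = []
    results: dict[tuple[str, str, str], ThresholdResult] = {}
    site_detections: dict[str, list[float]] = {}

    for loc in config.locations:
        spec = replace(loc.spec, seed=_location_seed(config.master_seed, loc.name))
        weather = generate_weather(spec)
        soilwater = simulate_soil_water(weather, loc.soil)
        dates = pd.DatetimeIndex(weather["date"])
        tmin = pd.Series(weather["tmin"].to_numpy(), index=dates)
        rain = pd.Series(weather["rain"].to_numpy(), index=dates)

        for cv in config.cultivars:
            for window_name, ((m0, d0), (m1, d1)) in config.sowing_windows.items():
                records: list[SeasonRecord] = []
                n_skipped = 0
                for year in spec.years:
                    window = (Date(year, m0, d0), Date(year, m1, d1))
                    sowing = choose_sowing_date(weather, soilwater, loc.soil, window)
                    trace = run_phenology(
                        weather,
                        soilwater,
                        loc.soil,
                        cv,
                        sowing.date,
                        latitude=spec.latitude,
                    )
                    row = {
                        "location": loc.name,
                        "cultivar": cv.name,
                        "window": window_name,
                        "year": year,
                        "sowing_date": sowing.date,
                        "forced_sowing": sowing.forced,
                        "flowering_start": trace.flowering_start,
                        "flowering_end": trace.flowering_end,
                        "peak_flowering": trace.peak_flowering,
                        "podfill_end": trace.podfill_end,
                        "complete": trace.complete,
                    }
                    if not trace.complete:
                        n_skipped += 1
                        season_rows.append(row)
                        continue
                    rp_lo, rp_hi = trace.rp
                    frost = count_frost_events(weather, (rp_lo, rp_hi))
                    mask = (dates >= pd.Timestamp(rp_lo)) & (
                        dates <= pd.Timestamp(rp_hi)
                    )
                    rp_tmin = tmin.to_numpy()[mask]
                    r_mm = float(rain.to_numpy()[mask].sum())
                    p_implanted = 100.0 * float(
                        np.mean(rp_tmin <= spec.implanted_tc)
                    )
                    potential = generate_yields(
                        {year: {"r": r_mm, "p": p_implanted}}, spec
                    )[year]
                    yf = apply_frost_penalty(
                        potential, frost.events, mode=config.penalty_mode
                    )
                    gs = (dates >= pd.Timestamp(sowing.date)) & (
                        dates <= pd.Timestamp(rp_hi)
                    )
                    row.update(
                        rp_days=len(rp_tmin),
                        frost_events=frost.events,
                        rp_rain=r_mm,
                        p_implanted=p_implanted,
                        potential_yield=potential,
                        yf=yf,
                        gs_rain=float(rain.to_numpy()[gs].sum()),
                    )
                    season_rows.append(row)
                    records.append(
                        SeasonRecord(year=year, yf=yf, r=r_mm, rp_tmin=rp_tmin)
                    )
                key = (loc.name, cv.name, window_name)
                if len(records) >= 4:
                    result = detect_threshold(
                        records,
                        grid_lo=config.grid_lo,
                        grid_hi=config.grid_hi,
                        step=config.grid_step,
                    )
                else:
                    result = ThresholdResult(detected=False)
                results[key] = result
                threshold_rows.append(
                    {
                        "location": loc.name,
                        "cultivar": cv.name,
                        "window": window_name,
                        "n_seasons": len(records),
                        "detected": result.detected,
                        "tc": result.tc,
                        "beta1": result.beta1,
                        "p_beta1": result.p_beta1,
                        "q1": result.q1,
                        "q3": result.q3,
                    }
                )
                if result.detected:
                    site_detections.setdefault(loc.name, []).append(result.tc)
                logger.info(
                    "combination %s/%s/%s: seed=%d seasons=%d skipped=%d "
                    "detected=%s tc=%s",
                    loc.name,
                    cv.name,
                    window_name,
                    spec.seed,
                    len(records),
                    n_skipped,
                    result.detected,
                    result.tc,
                )

    spatial = None
    if len(site_detections) >= 3:
        by_name = {loc.name: loc for loc in config.locations}
        triples = [
            (by_name[name].latitude, by_name[name].longitude, float(np.mean(tcs)))
            for name, tcs in site_detections.items()
        ]
        lats = {t[0] for t in triples}
        lons = {t[1] for t in triples}
        if len(lats) > 1 and len(lons) > 1:
            spatial = spatial_threshold_regression(triples)

    return ScenarioResults(
        seasons=pd.DataFrame(season_rows),
        thresholds=pd.DataFrame(threshold_rows),
        threshold_results=results,
        spatial=spatial,
    )
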