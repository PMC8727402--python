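import math
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd
import pytest

from chillpea import (
    CultivarConfig,
    SoilLayer,
    SoilProfile,
    Stage,
    choose_sowing_date,
    compute_fasw,
    daily_thermal_time,
    day_length,
    modify_thermal_time,
    photoperiod_factor,
    run_phenology,
)
from tests.conftest import make_soilwater, make_weather


class TestDailyThermalTime:
    def test_base_temperature_identity(self, cultivar):
        assert daily_thermal_time(cultivar.base_temp, cultivar.base_temp, cultivar) == 0.0

    def test_plateau_identity(self, cultivar):
        tt = daily_thermal_time(cultivar.opt_temp, cultivar.opt_temp, cultivar)
        assert tt == pytest.approx(cultivar.opt_temp - cultivar.base_temp)

    def test_matches_three_hourly_interpolation_oracle(self, cultivar):
        # independent brute-force evaluation of the eight-point scheme
        tmin, tmax = 5.0, 15.0
        total = 0.0
        for k in range(1, 9):
            frac = 0.92105 + 0.1140 * k - 0.0703 * k**2 + 0.0053 * k**3
            t = tmin + frac * (tmax - tmin)
            if t <= 0:
                resp = 0.0
            elif t <= 30:
                resp = t
            elif t < 40:
                resp = 30 * (40 - t) / 10
            else:
                resp = 0.0
            total += resp
        assert daily_thermal_time(tmin, tmax, cultivar) == pytest.approx(total / 8)

    def test_capped_at_opt_minus_base(self, cultivar):
        cap = cultivar.opt_temp - cultivar.base_temp
        assert daily_thermal_time(28, 33, cultivar) <= cap

    def test_rejects_tmin_above_tmax(self, cultivar):
        with pytest.raises(ValueError):
            daily_thermal_time(10, 5, cultivar)


class TestComputeFasw:
    def test_field_capacity_identity(self, default_soil):
        sw = [l.dul for l in default_soil.layers]
        assert compute_fasw(sw, default_soil) == 1.0

    def test_wilting_point_identity(self, default_soil):
        sw = [l.ll15 for l in default_soil.layers]
        assert compute_fasw(sw, default_soil) == 0.0

    def test_two_layer_hand_sum(self):
        soil = SoilProfile(
            layers=(
                SoilLayer(thickness=300, ll15=50, dul=100, sat=120),
                SoilLayer(thickness=300, ll15=50, dul=100, sat=120),
            )
        )
        # (sw - ll15) = 30 and 10 mm; capacities 50 and 50 mm
        assert compute_fasw([80, 60], soil) == pytest.approx(40 / 100)

    def test_straddling_layer_pro_rated(self):
        soil = SoilProfile(
            layers=(
                SoilLayer(thickness=400, ll15=40, dul=80, sat=100),
                SoilLayer(thickness=400, ll15=40, dul=80, sat=100),
            )
        )
        # second layer only half inside the top 600 mm
        got = compute_fasw([80, 40], soil, depth_limit=600)
        assert got == pytest.approx(40 / (40 + 20))

    def test_depth_limit_beyond_profile_uses_whole_profile(self, caplog):
        soil = SoilProfile(layers=(SoilLayer(thickness=300, ll15=30, dul=60, sat=80),))
        got = compute_fasw([45], soil, depth_limit=900)
        assert got == pytest.approx(0.5)


class TestModifyThermalTime:
    def test_inactive_below_threshold(self):
        assert modify_thermal_time(10.0, 0.5, Stage.FLOWERING) == 10.0

    def test_boundary_multiplier_is_exactly_one(self):
        assert modify_thermal_time(10.0, 0.65, Stage.FLOWERING) == 10.0

    def test_field_capacity_value(self):
        assert modify_thermal_time(10.0, 1.0, Stage.FLOWERING) == pytest.approx(6.5)

    def test_pre_emergence_exempt(self):
        assert modify_thermal_time(10.0, 1.0, Stage.GERMINATION) == 10.0

    def test_result_bounded(self):
        for fasw in np.linspace(0, 1, 51):
            ttm = modify_thermal_time(10.0, float(fasw), Stage.FLOWERING)
            assert 6.5 - 1e-12 <= ttm <= 10.0 + 1e-12


class TestPhotoperiod:
    def test_insensitive_cultivar_is_always_one(self):
        cv = CultivarConfig(photoperiod_sensitivity=0.0)
        for dl in (8, 10.5, 12, 14, 16):
            assert photoperiod_factor(dl, cv) == 1.0

    def test_saturating_identity(self):
        cv = CultivarConfig(photoperiod_sensitivity=0.3)
        assert photoperiod_factor(cv.photoperiod_saturating, cv) == 1.0

    def test_linear_interpolation_midpoint(self):
        cv = CultivarConfig(
            photoperiod_critical=10,
            photoperiod_saturating=14,
            photoperiod_sensitivity=0.4,
        )
        assert photoperiod_factor(12.0, cv) == pytest.approx(0.8)


class TestDayLength:
    def test_equator_near_twelve_hours(self):
        for doy in (1, 80, 172, 266, 355):
            assert day_length(0.0, doy) == pytest.approx(12.0, abs=0.2)

    def test_southern_winter_shorter_than_summer(self):
        assert day_length(-35, 172) < day_length(-35, 355)

    def test_equinox_near_twelve_hours(self):
        assert day_length(-35, 80) == pytest.approx(12.0, abs=0.3)

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError):
            day_length(70.0, 100)


class TestSowingRule:
    @staticmethod
    def _setup(rain_per_day, paw_fasw=0.8, n=40):
        soil = SoilProfile(layers=(SoilLayer(thickness=600, ll15=60, dul=200, sat=240),))
        w = make_weather(Date(2000, 4, 20), n, rain=0.0)
        for i, r in enumerate(rain_per_day):
            w.loc[i + 10, "rain"] = r  # window starts at index 10 (30 April)
        sw = make_soilwater(w["date"], soil, paw_fasw)
        window = (Date(2000, 4, 30), Date(2000, 5, 20))
        return w, sw, soil, window

    def test_immediate_trigger(self):
        w, sw, soil, window = self._setup([25.0])
        dec = choose_sowing_date(w, sw, soil, window)
        assert dec.date == Date(2000, 4, 30) and not dec.forced

    def test_no_rain_forces_last_day(self):
        w, sw, soil, window = self._setup([])
        dec = choose_sowing_date(w, sw, soil, window)
        assert dec.date == Date(2000, 5, 20) and dec.forced

    def test_cumulative_rain_triggers_day_seven(self):
        w, sw, soil, window = self._setup([4.0] * 21)
        dec = choose_sowing_date(w, sw, soil, window)
        # trailing 7-day totals reach 28 >= 25 on the seventh window day
        assert dec.date == Date(2000, 5, 6) and not dec.forced

    def test_dry_profile_blocks_sowing(self):
        # PAW = 0.4 * 140 = 56 mm < 80 mm: rain alone is not enough
        w, sw, soil, window = self._setup([30.0] * 21, paw_fasw=0.4)
        dec = choose_sowing_date(w, sw, soil, window)
        assert dec.forced

    def test_window_outside_span_rejected(self):
        w, sw, soil, _ = self._setup([])
        with pytest.raises(ValueError):
            choose_sowing_date(w, sw, soil, (Date(1999, 1, 1), Date(1999, 1, 20)))


def _flat_run(fasw, n_days=400, tt=10.0, cv=None, sow=None):
    """Phenology run under constant weather with FASW pinned."""
    cv = cv or CultivarConfig(
        tt_sowing_to_emergence=100,
        tt_emergence_to_end_juvenile=690,
        tt_end_juvenile_to_flowering=200,
        tt_flowering_to_end_flowering=100,
        tt_flowering_to_end_podfill=300,
    )
    soil = SoilProfile(layers=(SoilLayer(thickness=600, ll15=60, dul=160, sat=200),))
    w = make_weather(Date(2000, 1, 1), n_days, tmin=tt, tmax=tt)
    sw = make_soilwater(w["date"], soil, fasw)
    sow = sow or Date(2000, 1, 5)
    return run_phenology(w, sw, soil, cv, sow, latitude=-35.0), cv


class TestRunPhenology:
    def test_zero_accumulation_never_advances(self):
        cv = CultivarConfig()
        soil = SoilProfile(layers=(SoilLayer(thickness=600, ll15=60, dul=160, sat=200),))
        w = make_weather(Date(2000, 1, 1), 120, tmin=0.0, tmax=0.0)
        sw = make_soilwater(w["date"], soil, 0.5)
        tr = run_phenology(w, sw, soil, cv, Date(2000, 1, 5))
        assert not tr.complete
        assert tr.daily["stage"].max() <= Stage.GERMINATION
        assert tr.flowering_start is None

    def test_hand_schedule_with_water_modifier_active(self):
        # constant 10 degCd/day, FASW = 1.0 (multiplier 0.65 post-emergence)
        tr, cv = _flat_run(fasw=1.0)
        sow = tr.sowing_date
        emergence = tr.daily.loc[
            tr.daily["stage"] >= Stage.EMERGENCE, "date"
        ].iloc[0].date()
        assert emergence == sow + timedelta(days=10)
        expected_flowering = sow + timedelta(
            days=10 + math.ceil(690 / 6.5) + math.ceil(200 / 6.5)
        )
        assert tr.flowering_start == expected_flowering

    def test_modifier_inactive_when_dry(self):
        tr, _ = _flat_run(fasw=0.5)
        daily = tr.daily
        np.testing.assert_array_equal(daily["ttm_day"], daily["tt_day"])

    def test_peak_flowering_is_floored_midpoint(self):
        tr, _ = _flat_run(fasw=0.65)
        days = (tr.flowering_end - tr.flowering_start).days
        assert tr.peak_flowering == tr.flowering_start + timedelta(days=days // 2)
        assert tr.flowering_start <= tr.peak_flowering <= tr.flowering_end

    def test_stage_sequence_non_decreasing(self):
        tr, _ = _flat_run(fasw=0.9)
        stages = tr.daily["stage"].to_numpy()
        assert (np.diff(stages) >= 0).all()

    def test_cumulative_ttm_matches_day_loop_oracle(self):
        # 30-day constant-weather window cross-checked against a hand loop
        tr, cv = _flat_run(fasw=0.8)
        daily = tr.daily
        acc = 0.0
        stage = Stage.SOWING
        for i in range(1, 31):
            if stage == Stage.SOWING:
                stage = Stage.GERMINATION
            tt = 10.0
            ttm = tt * (1.0 - (0.8 - 0.65)) if stage >= Stage.EMERGENCE else tt
            acc += ttm
            if stage == Stage.GERMINATION and acc >= cv.tt_sowing_to_emergence:
                stage, acc = Stage.EMERGENCE, 0.0
            assert daily["cum_ttm"].iloc[i] == pytest.approx(acc, abs=1e-9)

    def test_wetter_never_flowers_earlier_single_day_bump(self):
        base, _ = _flat_run(fasw=0.8)
        # raise FASW on one post-emergence day only
        cvargs = dict(
            tt_sowing_to_emergence=100,
            tt_emergence_to_end_juvenile=690,
            tt_end_juvenile_to_flowering=200,
            tt_flowering_to_end_flowering=100,
            tt_flowering_to_end_podfill=300,
        )
        cv = CultivarConfig(**cvargs)
        soil = SoilProfile(layers=(SoilLayer(thickness=600, ll15=60, dul=160, sat=200),))
        w = make_weather(Date(2000, 1, 1), 400, tmin=10, tmax=10)
        sw = make_soilwater(w["date"], soil, 0.8)
        bump_day = 60
        layer = soil.layers[0]
        sw.loc[bump_day, "sw1"] = layer.ll15 + 0.95 * (layer.dul - layer.ll15)
        tr = run_phenology(w, sw, soil, cv, Date(2000, 1, 5))
        assert tr.flowering_start >= base.flowering_start

    def test_sowing_after_weather_end_rejected(self):
        soil = SoilProfile(layers=(SoilLayer(thickness=600, ll15=60, dul=160, sat=200),))
        w = make_weather(Date(2000, 1, 1), 30)
        sw = make_soilwater(w["date"], soil, 0.5)
        with pytest.raises(ValueError):
            run_phenology(w, sw, soil, CultivarConfig(), Date(2001, 1, 1))
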