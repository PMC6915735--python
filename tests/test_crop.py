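import math

import numpy as np
import pandas as pd
import pytest

from aridwheat.crop import (
    CropParams,
    SoilProfile,
    adjusted_canopy,
    auto_irrigate,
    biomass_step,
    canopy_step,
    evaporation_reduction,
    fco2,
    ks_from_depletion,
    partition_et,
    run_season,
    taw,
    tensift_soil,
    tensift_wheat,
    water_balance_step,
)
from aridwheat.errors import DataError, ParameterError, SimulationError
from aridwheat.phenology import CropCalendar
from aridwheat.synthetic import CO2_REFERENCE_PPM
from aridwheat.weather import DailyWeatherSeries

from conftest import constant_series


def toy_calendar(**kw):
    """Small-threshold calendar: maturity after 30 days at Tmean 20 degC."""
    kw.setdefault("sowing_month", 11)
    kw.setdefault("sowing_day", 1)
    kw.setdefault("gdd_emergence", 40.0)
    kw.setdefault("gdd_max_canopy", 200.0)
    kw.setdefault("gdd_senescence", 400.0)
    kw.setdefault("gdd_maturity", 600.0)
    return CropCalendar(**kw)


def toy_weather(n=40, tmin=13.0, tmax=27.0, precip=0.0):
    dates, a, b, p = constant_series(n, tmin, tmax, precip, start="2000-11-01")
    return DailyWeatherSeries(dates, a, b, p)


class TestTaw:
    def test_regional_soil_one_metre(self, soil):
        assert taw(soil, 1.0) == pytest.approx(150.0)

    def test_linear_in_depth(self, soil):
        assert taw(soil, 0.5) == pytest.approx(75.0)

    def test_degenerate_soil_rejected_but_zero_span_allowed(self):
        with pytest.raises(ParameterError):
            SoilProfile(theta_fc=0.17, theta_wp=0.17)
        with pytest.raises(ParameterError):
            taw(tensift_soil(), 0.0)


class TestStressCoefficient:
    def test_no_stress_at_zero_depletion(self):
        assert ks_from_depletion(0.0, 150.0, 0.5, 3.0) == 1.0

    def test_zero_at_wilting_point(self):
        assert ks_from_depletion(150.0, 150.0, 0.5, 3.0) == pytest.approx(0.0)

    def test_linear_shape_midpoint(self):
        assert ks_from_depletion(112.5, 150.0, 0.5, 0.0) == pytest.approx(0.5)

    def test_convex_shape_delays_stress_onset(self):
        linear = ks_from_depletion(112.5, 150.0, 0.5, 0.0)
        convex = ks_from_depletion(112.5, 150.0, 0.5, 3.0)
        assert convex > linear  # shape > 0 keeps Ks near 1 longer
        assert ks_from_depletion(150.0, 150.0, 0.5, 3.0) == pytest.approx(0.0)

    def test_zero_taw_rejected(self):
        with pytest.raises(ParameterError):
            ks_from_depletion(0.0, 0.0, 0.5, 3.0)

    def test_monotone_non_increasing_in_depletion(self):
        ks = [ks_from_depletion(d, 150.0, 0.3, 2.5) for d in np.linspace(0, 150, 100)]
        assert all(b <= a for a, b in zip(ks, ks[1:]))


class TestAdjustedCanopy:
    @pytest.mark.parametrize(
        "cc,expected",
        [
            (0.0, 0.0),
            (1.0, 1.72 - 1.0 + 0.30),
            (0.5, 1.72 * 0.5 - 0.25 + 0.30 * 0.125),
        ],
    )
    def test_polynomial_values(self, cc, expected):
        assert adjusted_canopy(cc) == pytest.approx(expected)

    def test_exceeds_cc_in_open_interval(self):
        for cc in np.linspace(0.05, 0.95, 19):
            assert adjusted_canopy(cc) > cc


class TestCanopyStep:
    def crop(self):
        return tensift_wheat(toy_calendar())

    def test_zero_before_emergence(self):
        assert canopy_step(0.0, 10.0, 20.0, self.crop(), 1.0) == 0.0

    def test_full_stress_halts_expansion(self):
        crop = self.crop()
        cc = canopy_step(0.0, 50.0, 20.0, crop, 0.0)
        assert cc == crop.cc0  # emergence happens but no growth

    def test_growth_saturates_at_ccx(self):
        crop = self.crop()
        cc = 0.0
        cum = 40.0
        for _ in range(300):
            cc_new = canopy_step(cc, cum, 10.0, crop, 1.0)
            assert cc_new >= cc
            cc = cc_new
            # keep phase fixed inside the growth window
        assert cc <= crop.ccx
        assert cc == pytest.approx(crop.ccx, abs=1e-6)

    def test_senescence_declines_to_zero(self):
        crop = self.crop()
        cc = crop.ccx
        for _ in range(100):
            cc_new = canopy_step(cc, 450.0, 10.0, crop, 1.0)
            assert cc_new <= cc
            cc = cc_new
        assert cc == 0.0


class TestPartition:
    def test_bare_soil_no_transpiration(self):
        tr, _ = partition_et(0.0, 1.0, 1.1, 4.0, 1.0, 1.1)
        assert tr == 0.0

    def test_dry_surface_no_evaporation(self):
        _, e = partition_et(1.0, 1.0, 1.1, 4.0, 0.0, 1.1)
        assert e == 0.0

    def test_direct_transpiration_value(self):
        tr, _ = partition_et(0.5, 1.0, 1.1, 4.0, 1.0, 1.1)
        assert tr == pytest.approx(2.2)

    def test_two_stage_drying_coefficient(self):
        assert evaporation_reduction(5.0, 9.0, 23.5) == 1.0
        assert evaporation_reduction(23.5, 9.0, 23.5) == 0.0
        mid = evaporation_reduction(16.25, 9.0, 23.5)
        assert mid == pytest.approx(0.5)


class TestWaterBalanceStep:
    def test_no_fluxes_no_change(self):
        dr, e, tr, d = water_balance_step(30.0, 0.0, 0.0, 0.0, 0.0, 150.0, 100.0)
        assert (dr, e, tr, d) == (30.0, 0.0, 0.0, 0.0)

    def test_bucket_overflow_drains(self):
        """60 mm of rain into a 10 mm-depleted bucket: refill plus 50 mm of
        deep percolation (ksat 100 >= 50)."""
        dr, e, tr, d = water_balance_step(10.0, 60.0, 0.0, 0.0, 0.0, 150.0, 100.0)
        assert dr == pytest.approx(0.0)
        assert d == pytest.approx(50.0)

    def test_demand_capped_by_available_water(self):
        taw_mm = 150.0
        dr0 = 148.0
        dr, e, tr, d = water_balance_step(dr0, 0.0, 0.0, 5.0, 5.0, taw_mm, 100.0)
        assert e + tr == pytest.approx(taw_mm - dr0)
        assert dr <= taw_mm + 1e-12
        assert e == pytest.approx(tr)  # proportional scaling

    def test_negative_flux_rejected(self):
        with pytest.raises(DataError):
            water_balance_step(10.0, -1.0, 0.0, 0.0, 0.0, 150.0, 100.0)

    def test_exact_closure_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            dr0 = rng.uniform(0, 150)
            p, irr = rng.uniform(0, 40, 2)
            e, tr = rng.uniform(0, 6, 2)
            dr1, ea, tra, d = water_balance_step(dr0, p, irr, e, tr, 150.0, 100.0)
            residual = (dr1 - dr0) - (-(p + irr) + d + ea + tra)
            assert abs(residual) < 1e-9


class TestAutoIrrigation:
    @pytest.mark.parametrize(
        "dr,expected",
        [
            (40.0, 0.0),    # below trigger
            (80.0, 80.0),   # above trigger: refill to zero depletion
            (75.0, 0.0),    # exactly at the threshold: strict inequality
        ],
    )
    def test_trigger_rule(self, dr, expected):
        assert auto_irrigate(dr, 150.0) == expected


class TestFco2:
    def test_reference_identity(self):
        assert fco2(CO2_REFERENCE_PPM) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        want = (550.0 / 369.41) / (1.0 + (550.0 - 369.41) * 0.000138)
        assert fco2(550.0, 369.41) == pytest.approx(want, rel=1e-12)

    def test_doubling_damped_below_two(self):
        v = fco2(2 * 369.41, 369.41)
        assert 1.0 < v < 2.0

    def test_strictly_increasing_over_rcp_range(self):
        cas = np.linspace(369.41, 950.0, 50)
        vals = [fco2(c) for c in cas]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestBiomassStep:
    def test_zero_transpiration_zero_growth(self):
        assert biomass_step(0.0, 4.0, 15.0, 1.0) == 0.0

    def test_unit_ratio(self):
        assert biomass_step(4.0, 4.0, 15.0, 1.0) == pytest.approx(15.0)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(SimulationError):
            biomass_step(1.0, 0.0, 15.0, 1.0)


class TestRunSeason:
    def run(self, co2=CO2_REFERENCE_PPM, irrigate=True, weather=None, **crop_kw):
        weather = weather or toy_weather()
        et0 = np.full(len(weather), 4.0)
        crop = tensift_wheat(toy_calendar(), **crop_kw)
        soil = tensift_soil()
        return run_season(
            weather, et0, crop, soil, co2, irrigate=irrigate, sowing="2000-11-01"
        )

    def test_toy_season_reaches_maturity_in_30_days(self):
        res = self.run()
        assert res.durations.maturity == 30.0
        assert res.durations.emergence == 2.0  # 40 GDD at 20 GDD/day

    def test_water_balance_closes_daily(self):
        res = self.run()
        assert res.max_residual < 1e-6

    def test_et_decomposition_and_wr_identity(self):
        res = self.run()
        assert res.et_mm == pytest.approx(res.e_mm + res.tr_mm)
        assert res.wr_mm == pytest.approx(res.irrigation_mm + res.precip_mm)
        assert res.irrigation_mm == pytest.approx(
            sum(res.irrigation_by_month.values())
        )

    def test_co2_only_scales_yield_by_fco2_exactly(self):
        base = self.run()
        ca = 700.0
        enriched = self.run(co2=ca)
        ratio = enriched.yield_t_ha / base.yield_t_ha
        assert abs(ratio - fco2(ca)) < 1e-10

    def test_rainless_unirrigated_season_conserves_initial_water(self, soil):
        res = self.run(irrigate=False)
        initial_available = (1.0 - soil.initial_depletion_fraction) * taw(
            soil, soil.max_root_depth
        )
        assert res.irrigation_mm == 0.0
        assert res.e_mm + res.tr_mm <= initial_available + 1e-9

    def test_full_canopy_closed_form_transpiration_and_biomass(self):
        """With the canopy pinned at full cover, no stress and constant ET0,
        Tr = n * kc * CC** * et0 and B = WP* * n * kc * CC**."""
        weather = toy_weather(n=40)
        et0 = np.full(len(weather), 4.0)
        cal = toy_calendar()
        crop = tensift_wheat(cal, cc0=0.959999, cgc=1e-9, cdc=1e-9)
        soil = tensift_soil()
        res = run_season(weather, et0, crop, soil, irrigate=True, sowing="2000-11-01")
        cc_star = adjusted_canopy(res.trace["cc"].iloc[5])
        # growth begins after emergence (day 2); the canopy is ~ccx throughout
        grown = res.trace[res.trace["cc"] > 0]
        n = len(grown)
        want_tr = n * crop.kc_tr_x * cc_star * 4.0
        assert grown["tr"].sum() == pytest.approx(want_tr, rel=1e-5)
        assert res.biomass_t_ha * 100 == pytest.approx(
            crop.wp_star * n * crop.kc_tr_x * cc_star, rel=1e-5
        )

    def test_heat_stress_in_pollination_window_reduces_harvest_index(self):
        hot = toy_weather(n=40, tmin=21.0, tmax=35.0)  # Tmax > 30 all season
        cool = toy_weather(n=40, tmin=21.0, tmax=29.9)
        et0 = np.full(40, 5.0)
        soil = tensift_soil()
        kw = dict(heat_slope=0.02)
        res_hot = run_season(
            hot, et0, tensift_wheat(toy_calendar(), **kw), soil, sowing="2000-11-01"
        )
        res_cool = run_season(
            cool, et0, tensift_wheat(toy_calendar(), **kw), soil, sowing="2000-11-01"
        )
        hi_hot = res_hot.trace["hi"].iloc[-1]
        hi_cool = res_cool.trace["hi"].iloc[-1]
        assert hi_hot < hi_cool
        assert hi_cool == pytest.approx(0.48, abs=1e-9)

    def test_maturity_unreachable_raises(self):
        weather = toy_weather(n=10)
        et0 = np.full(10, 4.0)
        with pytest.raises(SimulationError):
            run_season(
                weather, et0, tensift_wheat(toy_calendar()), tensift_soil(),
                sowing="2000-11-01",
            )

    def test_misaligned_et0_rejected(self):
        weather = toy_weather(n=40)
        with pytest.raises(DataError):
            run_season(
                weather, np.ones(5), tensift_wheat(toy_calendar()), tensift_soil()
            )


class TestSeasonalBehaviour:
    """Full-length seasons on the synthetic baseline climatology."""

    def test_auto_irrigation_keeps_stomata_open(
        self, baseline20, et0_20, crops, soil
    ):
        res = run_season(baseline20, et0_20, crops["early"], soil)
        grown = res.trace[res.trace["cc"] > 0]
        assert (grown["ks_stomata"] == 1.0).mean() >= 0.99
        # depletion never exceeds the trigger by more than one day's flux
        flux = (res.trace["e"] + res.trace["tr"]).max()
        assert (res.trace["dr"] <= 0.5 * res.trace["taw"] + flux + 1e-9).all()

    def test_warming_reduces_season_length_and_yield(
        self, baseline20, et0_20, crops, soil, site
    ):
        from aridwheat.atmosphere import seasonal_et0
        from aridwheat.synthetic import apply_scenario_deltas, ClimateScenarioSpec

        spec = ClimateScenarioSpec(
            label="warm", delta_tmin=(3.0,) * 12, delta_tmax=(3.0,) * 12,
            precip_factor=(1.0,) * 12,
        )
        warmed = apply_scenario_deltas(baseline20, spec)
        et0_w = seasonal_et0(warmed, site)
        base = run_season(baseline20, et0_20, crops["early"], soil)
        warm = run_season(warmed, et0_w, crops["early"], soil, sowing=base.sowing)
        assert warm.lcs < base.lcs
        assert warm.tr_mm < base.tr_mm
        assert warm.e_mm < base.e_mm
        assert warm.yield_t_ha < base.yield_t_ha
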