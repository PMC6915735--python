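import numpy as np
import pandas as pd
import pytest

from aridwheat.crop import fco2
from aridwheat.errors import ConfigurationError, DataError
from aridwheat.experiments import (
    KINDS,
    MEMBERS,
    ExperimentSpec,
    GridConfig,
    build_experiment_inputs,
    ensemble_members,
    pseudo_model_specs,
    report,
    run_grid,
)
from aridwheat.synthetic import (
    CO2_REFERENCE_PPM,
    ClimateScenarioSpec,
    scenario_presets,
)


def make_spec(dt=1.0, fac=1.0, co2=500.0, label="s"):
    return ClimateScenarioSpec(
        label=label, delta_tmin=(dt,) * 12, delta_tmax=(dt,) * 12,
        precip_factor=(fac,) * 12, co2_ppm=co2,
    )


@pytest.fixture(scope="module")
def small_grid():
    """A reduced factorial: one scenario, one sowing, mean member, 4 years."""
    cfg = GridConfig(
        n_years=6, seed=3,
        scenarios=("RCP8.5-2090",), sowings=("early",), members=("mean",),
    )
    return cfg, run_grid(cfg)


class TestExperimentSpec:
    def test_validation(self):
        with pytest.raises(ConfigurationError):
            ExperimentSpec(kind="bogus", sowing="early")
        with pytest.raises(ConfigurationError):
            ExperimentSpec(kind="cc_only", sowing="early")  # scenario missing
        spec = ExperimentSpec(kind="historical", sowing="late")
        assert 0 <= spec.run_seed() < 2**31


class TestBuildInputs:
    def scenarios(self):
        return {"s": {m: make_spec(dt=2.0, co2=550.0) for m in MEMBERS}}

    def test_four_kinds_map_to_weather_co2_combinations(self, baseline20):
        scen = self.scenarios()
        w, c = build_experiment_inputs(
            ExperimentSpec(kind="historical", sowing="early"), baseline20, scen
        )
        assert w is baseline20 and c == pytest.approx(CO2_REFERENCE_PPM)
        w, c = build_experiment_inputs(
            ExperimentSpec(kind="co2_only", sowing="early", scenario="s"),
            baseline20, scen,
        )
        assert w is baseline20 and c == 550.0
        w, c = build_experiment_inputs(
            ExperimentSpec(kind="cc_only", sowing="early", scenario="s"),
            baseline20, scen,
        )
        assert c == pytest.approx(CO2_REFERENCE_PPM)
        assert w.tmax.mean() == pytest.approx(baseline20.tmax.mean() + 2.0)
        w, c = build_experiment_inputs(
            ExperimentSpec(kind="cco2", sowing="early", scenario="s"),
            baseline20, scen,
        )
        assert c == 550.0
        assert w.tmax.mean() == pytest.approx(baseline20.tmax.mean() + 2.0)

    def test_unknown_scenario_rejected(self, baseline20):
        with pytest.raises(ConfigurationError):
            build_experiment_inputs(
                ExperimentSpec(kind="cc_only", sowing="early", scenario="nope"),
                baseline20, self.scenarios(),
            )


class TestEnsemble:
    def test_identical_members_have_zero_spread(self):
        members = ensemble_members([make_spec(2.0), make_spec(2.0)])
        for m in MEMBERS:
            assert members[m].delta_tmin == (2.0,) * 12
            assert members[m].precip_factor == (1.0,) * 12

    def test_mean_plus_minus_sd_arithmetic(self):
        members = ensemble_members([make_spec(1.0), make_spec(3.0)])
        assert members["mean"].delta_tmin[0] == pytest.approx(2.0)
        assert members["mean_plus_sd"].delta_tmin[0] == pytest.approx(3.0)
        assert members["mean_minus_sd"].delta_tmin[0] == pytest.approx(1.0)

    def test_negative_precip_factor_floored(self):
        members = ensemble_members([make_spec(fac=0.0), make_spec(fac=0.9)])
        assert min(members["mean_minus_sd"].precip_factor) == 0.0

    def test_single_member_rejected(self):
        with pytest.raises(DataError):
            ensemble_members([make_spec()])

    def test_pseudo_models_deterministic_and_centered(self):
        preset = scenario_presets()["RCP4.5-2050"]
        a = pseudo_model_specs(preset, 5, seed=9)
        b = pseudo_model_specs(preset, 5, seed=9)
        assert [m.delta_tmin for m in a] == [m.delta_tmin for m in b]
        mean_dt = np.mean([m.delta_tmin for m in a])
        assert mean_dt == pytest.approx(np.mean(preset.delta_tmin), rel=0.5)


class TestGrid:
    def test_historical_change_row_is_zero(self, small_grid):
        _, res = small_grid
        hist = res.change_table[res.change_table["kind"] == "historical"]
        pct_cols = [c for c in hist.columns if c.startswith("pct_")]
        assert np.allclose(hist[pct_cols].to_numpy(dtype=float), 0.0)

    def test_co2_only_yield_change_is_fertilization_percentage(self, small_grid):
        cfg, res = small_grid
        co2 = scenario_presets()["RCP8.5-2090"].co2_ppm
        want = 100.0 * (fco2(co2) - 1.0)
        row = res.change_table[
            (res.change_table["kind"] == "co2_only")
        ].iloc[0]
        assert row["pct_yield_t_ha"] == pytest.approx(want, abs=1e-6)
        assert row["pct_lcs"] == 0.0

    def test_cco2_composes_cc_and_fertilization(self, small_grid):
        """Under negligible stress the full-change yield is the warming-only
        yield scaled by fCO2 (compositional sanity within 2%)."""
        cfg, res = small_grid
        ct = res.change_table.set_index("kind")
        co2 = scenario_presets()["RCP8.5-2090"].co2_ppm
        cc = ct.loc["cc_only", "pct_yield_t_ha"]
        cco2 = ct.loc["cco2", "pct_yield_t_ha"]
        composed = ((1 + cc / 100.0) * fco2(co2) - 1.0) * 100.0
        assert cco2 == pytest.approx(composed, abs=2.0)

    def test_row_cardinality(self, small_grid):
        cfg, res = small_grid
        # historical: 1 sowing x 1 member; others: 1 scenario x 1 sowing x 1 member
        assert len(res.change_table) == 4
        assert set(res.change_table["kind"]) == set(KINDS)
        # ir profile: one row per cell per calendar month
        assert len(res.ir_profiles) == 4 * 12

    def test_monthly_profile_sums_to_seasonal_irrigation(self, small_grid):
        cfg, res = small_grid
        for key, agg in res.aggregates.items():
            assert sum(agg.irrigation_by_month.values()) == pytest.approx(
                agg.irrigation_mm, abs=1e-9
            )

    def test_grid_deterministic_under_fixed_seed(self):
        cfg = GridConfig(
            n_years=3, seed=5, scenarios=("RCP4.5-2050",),
            sowings=("late",), members=("mean",), kinds=("historical", "cco2"),
        )
        a = run_grid(cfg).change_table
        b = run_grid(cfg).change_table
        pd.testing.assert_frame_equal(a, b)

    def test_ensemble_ordering_for_monotone_outputs(self):
        """Season length responds monotonically to warming, so the member
        mean lies between mean-SD and mean+SD."""
        cfg = GridConfig(
            n_years=6, seed=2, scenarios=("RCP8.5-2090",),
            sowings=("early",), kinds=("historical", "cc_only"),
        )
        res = run_grid(cfg)
        ct = res.change_table.set_index("member")
        ct = ct[ct["kind"] == "cc_only"]
        lo = ct.loc["mean_plus_sd", "pct_lcs"]     # more warming: larger cut
        mid = ct.loc["mean", "pct_lcs"]
        hi = ct.loc["mean_minus_sd", "pct_lcs"]
        assert lo <= mid <= hi


class TestReport:
    def test_written_tables_round_trip(self, small_grid, tmp_path):
        cfg, res = small_grid
        paths = report(res, tmp_path)
        back = pd.read_csv(paths["changes"])
        pd.testing.assert_frame_equal(back, res.change_table, rtol=1e-5, atol=1e-9)
        ir = pd.read_csv(paths["irrigation"])
        assert len(ir) == len(res.ir_profiles)
        base = pd.read_csv(paths["baseline"])
        assert list(base["sowing"]) == list(cfg.sowings)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg_yaml = tmp_path / "grid.yaml"
        cfg_yaml.write_text(
            """
site:
  latitude: 31.5
climatology:
  temp_noise: 2.0
soil:
  theta_fc: 0.30
crop:
  wp_star: 16.0
management:
  irrigate: true
  trigger_fraction: 0.4
experiments:
  n_years: 4
  seed: 9
  scenarios: [RCP4.5-2050]
  sowings: [early]
  members: [mean]
"""
        )
        cfg = GridConfig.from_yaml(cfg_yaml)
        assert cfg.climatology.temp_noise == 2.0
        assert cfg.soil.theta_fc == 0.30
        assert cfg.crop_overrides == {"wp_star": 16.0}
        assert cfg.trigger_fraction == 0.4
        assert cfg.n_years == 4 and cfg.seed == 9
        assert cfg.scenarios == ("RCP4.5-2050",)

    def test_unknown_scenario_label_rejected(self):
        with pytest.raises(ConfigurationError):
            GridConfig(scenarios=("madeup",)).scenario_specs()
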