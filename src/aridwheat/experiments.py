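"""Factorial climate-impact experiments and reporting.

The study design crosses four experiment kinds with climate scenarios,
sowing dates and ensemble members:

* ``historical`` -- baseline weather, reference CO2 (the yardstick);
* ``co2_only``  -- baseline weather, scenario CO2 (fertilization alone);
* ``cc_only``   -- scenario weather, reference CO2 (warming/drying alone);
* ``cco2``      -- scenario weather and scenario CO2 (the full change).

Ensemble spread is emulated the way multi-model studies propagate it: a
small set of pseudo-model scenario specs is synthesised around each preset
by seeded jitter, and the crop model is run under the member Mean and
Mean +/- SD of their monthly deltas.

Every cell reports season-mean yield, stage durations, evaporation,
transpiration, water requirement, irrigation (total and by calendar month)
and water productivity, plus their relative change against the historical
baseline of the same sowing date.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atmosphere import SiteGeometry, seasonal_et0
from .crop import (
    CropParams,
    SimulationResult,
    SoilProfile,
    run_seasons,
    tensift_soil,
    tensift_wheat,
)
from .errors import ConfigurationError, DataError
from .phenology import (
    SOWING_DATES,
    STAGE_DURATION_TARGETS,
    StageDurations,
    calibrate_gdd_thresholds,
)
from .synthetic import (
    CO2_REFERENCE_PPM,
    BaselineClimatology,
    ClimateScenarioSpec,
    apply_scenario_deltas,
    co2_concentration,
    generate_baseline_weather,
    marrakech_climatology,
    scenario_presets,
)
from .weather import DailyWeatherSeries

__all__ = [
    "KINDS",
    "MEMBERS",
    "ExperimentSpec",
    "GridConfig",
    "GridResult",
    "SeasonAggregate",
    "pseudo_model_specs",
    "ensemble_members",
    "build_experiment_inputs",
    "aggregate_seasons",
    "run_grid",
    "report",
]

log = logging.getLogger(__name__)

KINDS: tuple[str, ...] = ("historical", "co2_only", "cc_only", "cco2")
MEMBERS: tuple[str, ...] = ("mean", "mean_plus_sd", "mean_minus_sd")

#: metrics carried into the relative-change table
CHANGE_METRICS: tuple[str, ...] = (
    "yield_t_ha", "lcs", "emergence", "max_canopy", "senescence_start",
    "e_mm", "tr_mm", "et_mm", "wr_mm", "irrigation_mm", "wp",
)


@dataclass(frozen=True)
class ExperimentSpec:
    """One cell of the factorial design."""

    kind: str
    sowing: str
    scenario: str | None = None
    member: str = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown experiment kind {self.kind!r}")
        if self.sowing not in SOWING_DATES:
            raise ConfigurationError(f"unknown sowing {self.sowing!r}")
        if self.member not in MEMBERS:
            raise ConfigurationError(f"unknown ensemble member {self.member!r}")
        if self.kind != "historical" and self.scenario is None:
            raise ConfigurationError(f"{self.kind} experiment needs a scenario")

    def run_seed(self) -> int:
        """Deterministic per-run seed derived from the spec's fields."""
        tag = f"{self.kind}|{self.scenario}|{self.sowing}|{self.member}|{self.seed}"
        return zlib.crc32(tag.encode()) % (2**31 - 1)


def pseudo_model_specs(
    preset: ClimateScenarioSpec, k: int, seed: int
) -> list[ClimateScenarioSpec]:
    """Synthesise ``k`` pseudo-model scenario specs around a preset.

    Monthly temperature deltas get multiplicative jitter (sd 20% of the
    delta) and precipitation factors additive jitter (sd 0.05, floored at
    0): a stand-in for the inter-model spread of a downscaled ensemble.
    """
    if k < 1:
        raise ConfigurationError("need at least one pseudo model")
    rng = np.random.default_rng(seed)
    out = []
    for j in range(k):
        tj = 1.0 + 0.2 * rng.standard_normal(12)
        tj2 = 1.0 + 0.2 * rng.standard_normal(12)
        fj = 0.05 * rng.standard_normal(12)
        out.append(
            ClimateScenarioSpec(
                label=f"{preset.label}#m{j}",
                delta_tmin=tuple(np.asarray(preset.delta_tmin) * tj),
                delta_tmax=tuple(np.asarray(preset.delta_tmax) * tj2),
                precip_factor=tuple(
                    np.maximum(np.asarray(preset.precip_factor) + fj, 0.0)
                ),
                co2_ppm=preset.co2_ppm,
            )
        )
    return out


def ensemble_members(
    models: list[ClimateScenarioSpec],
) -> dict[str, ClimateScenarioSpec]:
    """Mean and Mean +/- SD scenario specs across pseudo-model deltas.

    Mean - SD precipitation factors are floored at 0 (with a warning).
    """
    if len(models) < 2:
        raise DataError("ensemble statistics need at least two models")
    dtmin = np.array([m.delta_tmin for m in models])
    dtmax = np.array([m.delta_tmax for m in models])
    fac = np.array([m.precip_factor for m in models])
    co2 = models[0].co2_ppm
    base = models[0].label.split("#")[0]
    mu_tmin, sd_tmin = dtmin.mean(axis=0), dtmin.std(axis=0)
    mu_tmax, sd_tmax = dtmax.mean(axis=0), dtmax.std(axis=0)
    mu_fac, sd_fac = fac.mean(axis=0), fac.std(axis=0)
    lo_fac = mu_fac - sd_fac
    if np.any(lo_fac < 0):
        log.warning(
            "mean-SD precipitation factor negative in %d months; floored at 0",
            int((lo_fac < 0).sum()),
        )
        lo_fac = np.maximum(lo_fac, 0.0)
    members = {
        "mean": (mu_tmin, mu_tmax, mu_fac),
        "mean_plus_sd": (mu_tmin + sd_tmin, mu_tmax + sd_tmax, mu_fac + sd_fac),
        "mean_minus_sd": (mu_tmin - sd_tmin, mu_tmax - sd_tmax, lo_fac),
    }
    return {
        name: ClimateScenarioSpec(
            label=f"{base}[{name}]",
            delta_tmin=tuple(t1),
            delta_tmax=tuple(t2),
            precip_factor=tuple(f),
            co2_ppm=co2,
        )
        for name, (t1, t2, f) in members.items()
    }


def build_experiment_inputs(
    spec: ExperimentSpec,
    baseline: DailyWeatherSeries,
    scenarios: dict[str, dict[str, ClimateScenarioSpec]],
) -> tuple[DailyWeatherSeries, float]:
    """Map an experiment spec to its (weather series, CO2 ppm) pair.

    ``scenarios`` maps scenario label -> member name -> member spec.
    """
    if spec.kind == "historical":
        return baseline, CO2_REFERENCE_PPM
    if spec.scenario not in scenarios:
        raise ConfigurationError(f"unknown scenario {spec.scenario!r}")
    member_spec = scenarios[spec.scenario][spec.member]
    if spec.kind == "co2_only":
        return baseline, co2_concentration(member_spec)
    weather = apply_scenario_deltas(baseline, member_spec)
    if spec.kind == "cc_only":
        return weather, CO2_REFERENCE_PPM
    return weather, co2_concentration(member_spec)  # cco2


# -- aggregation -------------------------------------------------------------

@dataclass(frozen=True)
class SeasonAggregate:
    """Climatological means of the seasonal outputs over all simulated years."""

    yield_t_ha: float
    biomass_t_ha: float
    emergence: float
    max_canopy: float
    senescence_start: float
    lcs: float
    e_mm: float
    tr_mm: float
    et_mm: float
    precip_mm: float
    irrigation_mm: float
    wr_mm: float
    wp: float
    irrigation_by_month: dict[int, float]
    n_seasons: int


def aggregate_seasons(results: list[SimulationResult]) -> SeasonAggregate:
    if not results:
        raise DataError("no seasons to aggregate")
    mean = lambda xs: float(np.mean(xs))
    months: dict[int, float] = {}
    for r in results:
        for m, v in r.irrigation_by_month.items():
            months[m] = months.get(m, 0.0) + v / len(results)
    return SeasonAggregate(
        yield_t_ha=mean([r.yield_t_ha for r in results]),
        biomass_t_ha=mean([r.biomass_t_ha for r in results]),
        emergence=mean([r.durations.emergence for r in results]),
        max_canopy=mean([r.durations.max_canopy for r in results]),
        senescence_start=mean([r.durations.senescence_start for r in results]),
        lcs=mean([r.lcs for r in results]),
        e_mm=mean([r.e_mm for r in results]),
        tr_mm=mean([r.tr_mm for r in results]),
        et_mm=mean([r.et_mm for r in results]),
        precip_mm=mean([r.precip_mm for r in results]),
        irrigation_mm=mean([r.irrigation_mm for r in results]),
        wr_mm=mean([r.wr_mm for r in results]),
        wp=mean([r.wp for r in results]),
        irrigation_by_month=months,
        n_seasons=len(results),
    )


# -- grid configuration and driver -------------------------------------------

@dataclass(frozen=True)
class GridConfig:
    """Everything needed to reproduce the full factorial run."""

    climatology: BaselineClimatology = field(default_factory=marrakech_climatology)
    n_years: int = 20
    start_year: int = 1991
    scenarios: tuple[str, ...] = (
        "RCP4.5-2050", "RCP8.5-2050", "RCP4.5-2090", "RCP8.5-2090",
    )
    sowings: tuple[str, ...] = ("early", "intermediate", "late")
    members: tuple[str, ...] = MEMBERS
    kinds: tuple[str, ...] = KINDS
    n_pseudo_models: int = 5
    seed: int = 0
    soil: SoilProfile = field(default_factory=tensift_soil)
    crop_overrides: dict = field(default_factory=dict)
    irrigate: bool = True
    trigger_fraction: float = 0.5
    extra_scenarios: dict = field(default_factory=dict)  # label -> ClimateScenarioSpec

    def scenario_specs(self) -> dict[str, ClimateScenarioSpec]:
        presets = scenario_presets()
        presets.update(self.extra_scenarios)
        missing = [s for s in self.scenarios if s not in presets]
        if missing:
            raise ConfigurationError(f"unknown scenarios: {missing}")
        return {s: presets[s] for s in self.scenarios}

    @classmethod
    def from_dict(cls, d: dict) -> "GridConfig":
        kw: dict = {}
        clim_kw = dict(d.get("climatology", {}))
        site = d.get("site", {})
        if "latitude" in site:
            clim_kw["latitude"] = site["latitude"]
        if clim_kw:
            kw["climatology"] = BaselineClimatology(**clim_kw)
        if "soil" in d:
            kw["soil"] = SoilProfile(**d["soil"])
        if "crop" in d:
            kw["crop_overrides"] = dict(d["crop"])
        man = d.get("management", {})
        if "irrigate" in man:
            kw["irrigate"] = bool(man["irrigate"])
        if "trigger_fraction" in man:
            kw["trigger_fraction"] = float(man["trigger_fraction"])
        exp = d.get("experiments", {})
        for key in ("n_years", "start_year", "seed", "n_pseudo_models"):
            if key in exp:
                kw[key] = int(exp[key])
        for key in ("scenarios", "sowings", "members", "kinds"):
            if key in exp:
                kw[key] = tuple(exp[key])
        extra = {}
        for sdict in d.get("scenario_specs", []):
            spec = ClimateScenarioSpec.from_dict(sdict)
            extra[spec.label] = spec
        if extra:
            kw["extra_scenarios"] = extra
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "GridConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class GridResult:
    """Outputs of the full factorial run."""

    baseline: dict[str, SeasonAggregate]       # sowing -> historical aggregate
    aggregates: dict[tuple, SeasonAggregate]   # (kind, scenario, sowing, member)
    change_table: pd.DataFrame
    ir_profiles: pd.DataFrame
    calendars: dict


def _pct(new: float, base: float) -> float:
    return 100.0 * (new - base) / base if base != 0 else float("nan")


def run_grid(config: GridConfig) -> GridResult:
    """Run the full factorial design and assemble the change table.

    Deterministic given the config seed.  Historical cells are run once per
    sowing; scenario cells cover kinds x scenarios x sowings x members
    (duplicate weather/CO2 combinations are computed once and reused).
    """
    clim = config.climatology
    site = SiteGeometry(clim.latitude)
    baseline = generate_baseline_weather(
        clim, config.n_years, seed=config.seed, start_year=config.start_year
    )
    presets = config.scenario_specs()
    scenarios: dict[str, dict[str, ClimateScenarioSpec]] = {}
    for label, preset in presets.items():
        member_seed = zlib.crc32(f"{label}|{config.seed}".encode()) % (2**31 - 1)
        models = pseudo_model_specs(preset, config.n_pseudo_models, member_seed)
        scenarios[label] = ensemble_members(models)

    calendars = {}
    crops = {}
    for sowing in config.sowings:
        month, day = SOWING_DATES[sowing]
        cal = calibrate_gdd_thresholds(
            baseline, month, day, StageDurations(*STAGE_DURATION_TARGETS[sowing])
        )
        calendars[sowing] = cal
        crops[sowing] = tensift_wheat(cal, **config.crop_overrides)

    et0_cache: dict[int, np.ndarray] = {}

    def run_cell(weather: DailyWeatherSeries, co2: float, sowing: str) -> SeasonAggregate:
        key = id(weather)
        if key not in et0_cache:
            et0_cache[key] = seasonal_et0(weather, site)
        results = run_seasons(
            weather, et0_cache[key], crops[sowing], config.soil, co2,
            irrigate=config.irrigate, trigger_fraction=config.trigger_fraction,
        )
        return aggregate_seasons(results)

    # historical baseline per sowing
    base_aggs = {
        sowing: run_cell(baseline, CO2_REFERENCE_PPM, sowing)
        for sowing in config.sowings
    }

    weather_cache: dict[tuple, DailyWeatherSeries] = {}
    cell_cache: dict[tuple, SeasonAggregate] = {}
    aggregates: dict[tuple, SeasonAggregate] = {}
    rows = []
    ir_rows = []

    for kind in config.kinds:
        scenario_list: list[str | None] = (
            [None] if kind == "historical" else list(config.scenarios)
        )
        for scen in scenario_list:
            for sowing in config.sowings:
                for member in config.members:
                    spec = ExperimentSpec(
                        kind=kind, sowing=sowing, scenario=scen,
                        member=member, seed=config.seed,
                    )
                    if kind == "historical":
                        agg = base_aggs[sowing]
                    else:
                        member_spec = scenarios[scen][member]
                        if kind == "co2_only":
                            wkey: tuple = ("baseline",)
                            co2 = co2_concentration(member_spec)
                        else:
                            wkey = (scen, member)
                            co2 = (
                                CO2_REFERENCE_PPM
                                if kind == "cc_only"
                                else co2_concentration(member_spec)
                            )
                        if wkey not in weather_cache:
                            weather_cache[wkey] = (
                                baseline
                                if wkey == ("baseline",)
                                else apply_scenario_deltas(baseline, member_spec)
                            )
                        ckey = (wkey, co2, sowing)
                        if ckey not in cell_cache:
                            cell_cache[ckey] = run_cell(
                                weather_cache[wkey], co2, sowing
                            )
                        agg = cell_cache[ckey]
                    akey = (kind, scen or "-", sowing, member)
                    aggregates[akey] = agg
                    log.info("ran %s", spec)
                    base = base_aggs[sowing]
                    row = {
                        "kind": kind,
                        "scenario": scen or "-",
                        "sowing": sowing,
                        "member": member,
                    }
                    for metric in CHANGE_METRICS:
                        row[f"pct_{metric}"] = _pct(
                            getattr(agg, metric), getattr(base, metric)
                        )
                    rows.append(row)
                    for m in range(1, 13):
                        v = agg.irrigation_by_month.get(m, 0.0)
                        ir_rows.append(
                            {
                                "kind": kind, "scenario": scen or "-",
                                "sowing": sowing, "member": member,
                                "month": m, "irrigation_mm": v,
                            }
                        )

    change_table = pd.DataFrame(rows)
    ir_profiles = pd.DataFrame(ir_rows)
    return GridResult(
        baseline=base_aggs,
        aggregates=aggregates,
        change_table=change_table,
        ir_profiles=ir_profiles,
        calendars=calendars,
    )


def report(result: GridResult, outdir) -> dict[str, Path]:
    """Write the grid outputs as CSV tables; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    base_rows = []
    for sowing, agg in result.baseline.items():
        row = {"sowing": sowing}
        row.update(
            {
                k: getattr(agg, k)
                for k in (
                    "yield_t_ha", "biomass_t_ha", "emergence", "max_canopy",
                    "senescence_start", "lcs", "e_mm", "tr_mm", "et_mm",
                    "precip_mm", "irrigation_mm", "wr_mm", "wp", "n_seasons",
                )
            }
        )
        base_rows.append(row)
    paths["baseline"] = outdir / "baseline_summary.csv"
    pd.DataFrame(base_rows).to_csv(paths["baseline"], index=False, float_format="%.6g")

    paths["changes"] = outdir / "change_table.csv"
    result.change_table.to_csv(paths["changes"], index=False, float_format="%.6g")

    paths["irrigation"] = outdir / "irrigation_profiles.csv"
    result.ir_profiles.to_csv(paths["irrigation"], index=False, float_format="%.6g")
    return paths
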