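"""Synthetic semi-arid Mediterranean climate for end-to-end pipeline testing.

The study region (Haouz plain, central Morocco, ~31.5 degN) has a dry
semi-arid climate: 190-250 mm of rain per year, almost all of it between
November and April, against an evaporative demand of roughly 1600 mm/yr of
reference evapotranspiration.  This module emulates three kinds of daily
series so that the whole pipeline runs without any external download:

* a *baseline* station-like record (stochastic weather generator);
* a *pseudo-RCM* record: the baseline distorted by prescribed seasonal
  biases, standing in for raw regional-climate-model output that the
  quantile mapping must correct;
* *scenario* records: the baseline shifted by monthly temperature deltas
  and scaled by monthly precipitation factors, the standard delta-change
  emulation of downscaled projections.

Weather model: precipitation occurrence follows a first-order two-state
(wet/dry) Markov chain with monthly stationary wet-day probability and a
persistence parameter; wet-day depths are gamma distributed with monthly
means.  Temperature is a smooth seasonal cycle (two-harmonic fit to monthly
normals) plus an AR(1) daily anomaly shared by Tmin and Tmax, plus
independent noise on the diurnal range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .qmap import MONTH_TO_SEASON, SEASONS
from .weather import DailyWeatherSeries

__all__ = [
    "BaselineClimatology",
    "ClimateScenarioSpec",
    "BiasSpec",
    "marrakech_climatology",
    "generate_baseline_weather",
    "generate_pseudo_rcm",
    "apply_scenario_deltas",
    "co2_concentration",
    "scenario_presets",
    "CO2_REFERENCE_PPM",
]

log = logging.getLogger(__name__)

#: atmospheric CO2 of the reference year 2000 (ppm)
CO2_REFERENCE_PPM = 369.41

_DAYS_IN_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass(frozen=True)
class BaselineClimatology:
    """Monthly climate normals parameterizing the weather generator.

    Defaults describe a Marrakech-like semi-arid site: ~230 mm/yr of rain,
    74% of it November-April, and temperatures yielding ~1600 mm/yr of
    Hargreaves-Samani ET0 at latitude 31.5 degN.
    """

    #: per-month mean of daily Tmin (degC), January first
    mean_tmin: tuple[float, ...] = (
        5.9, 7.6, 9.4, 11.0, 14.2, 17.5, 20.2, 20.2, 18.0, 14.5, 10.2, 6.8,
    )
    #: per-month mean of daily Tmax (degC)
    mean_tmax: tuple[float, ...] = (
        18.4, 20.0, 22.7, 24.9, 28.5, 32.9, 37.2, 37.0, 32.4, 27.9, 22.7, 18.9,
    )
    #: per-month unconditional wet-day probability
    wet_prob: tuple[float, ...] = (
        0.17, 0.17, 0.18, 0.17, 0.07, 0.04, 0.02, 0.02, 0.05, 0.13, 0.18, 0.14,
    )
    #: per-month mean precipitation depth on wet days (mm)
    wet_depth: tuple[float, ...] = (
        5.0, 5.8, 5.9, 6.1, 4.8, 4.2, 3.2, 4.8, 5.6, 6.0, 6.1, 5.3,
    )
    #: lag-1 autocorrelation of the wet/dry occurrence chain
    wet_persistence: float = 0.4
    #: gamma shape of wet-day depths (semi-arid rain is strongly skewed)
    depth_shape: float = 0.7
    #: AR(1) coefficient of the daily temperature anomaly
    temp_ar1: float = 0.7
    #: marginal standard deviation of the daily temperature anomaly (degC)
    temp_noise: float = 2.2
    #: standard deviation of independent diurnal-range noise on Tmax (degC)
    range_noise: float = 1.0
    #: site latitude (decimal degrees, positive north)
    latitude: float = 31.5

    def __post_init__(self) -> None:
        for name in ("mean_tmin", "mean_tmax", "wet_prob", "wet_depth"):
            vals = getattr(self, name)
            if len(vals) != 12:
                raise ParameterError(f"{name} needs 12 monthly values")
            object.__setattr__(self, name, tuple(float(v) for v in vals))
        if any(p < 0 or p > 1 for p in self.wet_prob):
            raise ParameterError("wet-day probabilities must lie in [0, 1]")
        if any(d <= 0 for d in self.wet_depth):
            raise ParameterError("wet-day depths must be positive")
        if any(a > b for a, b in zip(self.mean_tmin, self.mean_tmax)):
            raise ParameterError("monthly mean tmin must not exceed mean tmax")
        if not (0 <= self.wet_persistence < 1):
            raise ParameterError("wet_persistence must lie in [0, 1)")
        if self.depth_shape <= 0:
            raise ParameterError("depth_shape must be positive")
        if not (0 <= self.temp_ar1 < 1):
            raise ParameterError("temp_ar1 must lie in [0, 1)")
        if self.temp_noise < 0 or self.range_noise < 0:
            raise ParameterError("noise scales must be non-negative")
        if not (-66 <= self.latitude <= 66):
            raise ParameterError("latitude must lie in [-66, 66]")

    @property
    def diurnal_range(self) -> tuple[float, ...]:
        """Per-month mean diurnal temperature range (degC)."""
        return tuple(b - a for a, b in zip(self.mean_tmin, self.mean_tmax))

    @property
    def expected_monthly_precip(self) -> np.ndarray:
        """Expected precipitation total per month (mm): prob x depth x days."""
        return (
            np.asarray(self.wet_prob)
            * np.asarray(self.wet_depth)
            * _DAYS_IN_MONTH
        )

    @property
    def expected_annual_precip(self) -> float:
        return float(self.expected_monthly_precip.sum())


def marrakech_climatology() -> BaselineClimatology:
    """Default semi-arid baseline (all defaults)."""
    return BaselineClimatology()


@dataclass(frozen=True)
class ClimateScenarioSpec:
    """Delta-change description of one climate scenario at one horizon.

    ``delta_tmin``/``delta_tmax`` are additive monthly offsets (degC),
    ``precip_factor`` multiplicative monthly factors, January first.
    ``co2_ppm`` is the scenario's atmospheric CO2 concentration; ``None``
    marks a spec with no CO2 information (asking for it is an error).
    """

    label: str
    delta_tmin: tuple[float, ...]
    delta_tmax: tuple[float, ...]
    precip_factor: tuple[float, ...]
    co2_ppm: float | None = None

    def __post_init__(self) -> None:
        for name in ("delta_tmin", "delta_tmax", "precip_factor"):
            vals = getattr(self, name)
            if len(vals) != 12:
                raise ParameterError(f"{name} needs 12 monthly values")
            object.__setattr__(self, name, tuple(float(v) for v in vals))
        if any(f < 0 for f in self.precip_factor):
            raise ParameterError("precip_factor must be non-negative")

    @property
    def mean_warming(self) -> float:
        """Annual-mean warming of the daily mean temperature (degC)."""
        return float(
            (np.asarray(self.delta_tmin) + np.asarray(self.delta_tmax)).mean() / 2
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "delta_tmin": list(self.delta_tmin),
            "delta_tmax": list(self.delta_tmax),
            "precip_factor": list(self.precip_factor),
            "co2_ppm": self.co2_ppm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClimateScenarioSpec":
        return cls(
            label=d["label"],
            delta_tmin=tuple(d["delta_tmin"]),
            delta_tmax=tuple(d["delta_tmax"]),
            precip_factor=tuple(d["precip_factor"]),
            co2_ppm=d.get("co2_ppm"),
        )


def historical_spec() -> ClimateScenarioSpec:
    """Identity scenario at the reference CO2 concentration."""
    return ClimateScenarioSpec(
        label="historical",
        delta_tmin=(0.0,) * 12,
        delta_tmax=(0.0,) * 12,
        precip_factor=(1.0,) * 12,
        co2_ppm=CO2_REFERENCE_PPM,
    )


@dataclass(frozen=True)
class BiasSpec:
    """Prescribed systematic error of a pseudo regional climate model.

    Additive temperature bias and multiplicative precipitation bias per
    Q-Q season (JFM, AMJ, JAS, OND), plus an optional variance inflation of
    the temperature anomaly around the seasonal mean.
    """

    temp_bias: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in SEASONS}
    )
    precip_factor: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in SEASONS}
    )
    variance_inflation: float = 1.0
    #: std-dev of extra white noise added to both temperatures (degC)
    temp_noise: float = 0.0

    def __post_init__(self) -> None:
        for s in SEASONS:
            if s not in self.temp_bias or s not in self.precip_factor:
                raise ParameterError(f"bias spec missing season {s}")
        if any(v < 0 for v in self.precip_factor.values()):
            raise ParameterError("precipitation bias factors must be >= 0")
        if self.variance_inflation <= 0:
            raise ParameterError("variance inflation must be positive")

    @classmethod
    def uniform(
        cls,
        temp_bias: float = 0.0,
        precip_factor: float = 1.0,
        variance_inflation: float = 1.0,
        temp_noise: float = 0.0,
    ) -> "BiasSpec":
        return cls(
            temp_bias={s: temp_bias for s in SEASONS},
            precip_factor={s: precip_factor for s in SEASONS},
            variance_inflation=variance_inflation,
            temp_noise=temp_noise,
        )


# -- generation --------------------------------------------------------------

def _harmonic_daily(monthly: np.ndarray, doy_frac: np.ndarray) -> np.ndarray:
    """Smooth daily curve through 12 monthly values via two Fourier harmonics.

    ``doy_frac`` is the fractional position of each day in its year, in
    [0, 1).  The fit is least squares on the month midpoints.
    """
    mid = (np.arange(12) + 0.5) / 12.0
    X = np.column_stack(
        [
            np.ones(12),
            np.cos(2 * np.pi * mid), np.sin(2 * np.pi * mid),
            np.cos(4 * np.pi * mid), np.sin(4 * np.pi * mid),
        ]
    )
    coef, *_ = np.linalg.lstsq(X, monthly, rcond=None)
    Xd = np.column_stack(
        [
            np.ones_like(doy_frac),
            np.cos(2 * np.pi * doy_frac), np.sin(2 * np.pi * doy_frac),
            np.cos(4 * np.pi * doy_frac), np.sin(4 * np.pi * doy_frac),
        ]
    )
    return Xd @ coef


def generate_baseline_weather(
    clim: BaselineClimatology,
    n_years: int,
    seed: int,
    start_year: int = 1991,
) -> DailyWeatherSeries:
    """Generate ``n_years`` of daily weather on a true calendar (leap days).

    Deterministic given (clim, n_years, seed, start_year).
    """
    if n_years < 1:
        raise ParameterError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D"
    )
    n = len(dates)
    month_idx = dates.month.to_numpy() - 1
    # fractional position of each day within its own year
    year_len = np.where(dates.is_leap_year, 366.0, 365.0)
    doy_frac = (dates.dayofyear.to_numpy() - 0.5) / year_len

    clim_tmin = _harmonic_daily(np.asarray(clim.mean_tmin), doy_frac)
    clim_tmax = _harmonic_daily(np.asarray(clim.mean_tmax), doy_frac)

    # AR(1) anomaly with marginal sd temp_noise, shared by tmin and tmax
    phi = clim.temp_ar1
    innov_sd = clim.temp_noise * math.sqrt(1.0 - phi * phi)
    z = rng.standard_normal(n)
    anom = np.empty(n)
    prev = clim.temp_noise * z[0]
    anom[0] = prev
    for i in range(1, n):
        prev = phi * prev + innov_sd * z[i]
        anom[i] = prev
    range_eps = clim.range_noise * rng.standard_normal(n)

    tmin = clim_tmin + anom
    tmax = clim_tmax + anom + range_eps
    bad = tmax < tmin
    if bad.any():
        log.debug("clamped tmax up to tmin on %d generated days", int(bad.sum()))
        tmax = np.where(bad, tmin, tmax)

    # two-state occurrence chain: stationary prob pi, persistence r
    pi = np.asarray(clim.wet_prob)[month_idx]
    r = clim.wet_persistence
    u = rng.random(n)
    wet = np.empty(n, dtype=bool)
    wet[0] = u[0] < pi[0]
    for i in range(1, n):
        p = (1.0 - r) * pi[i] + (r if wet[i - 1] else 0.0)
        wet[i] = u[i] < p
    depth_mean = np.asarray(clim.wet_depth)[month_idx]
    k = clim.depth_shape
    depths = rng.gamma(shape=k, scale=depth_mean / k, size=n)
    precip = np.where(wet, depths, 0.0)

    return DailyWeatherSeries(dates=dates, tmin=tmin, tmax=tmax, precip=precip)


def generate_pseudo_rcm(
    base: DailyWeatherSeries,
    bias: BiasSpec,
    seed: int,
) -> DailyWeatherSeries:
    """Distort a series with seasonal biases, emulating raw RCM output.

    Temperatures get the seasonal additive bias (and optional variance
    inflation of the anomaly about the seasonal mean, plus white noise);
    precipitation is scaled by the seasonal factor.  ``tmin <= tmax`` is
    re-enforced by raising ``tmax`` where the noise breaks it.
    """
    rng = np.random.default_rng(seed)
    season = np.array([MONTH_TO_SEASON[m] for m in base.months])
    tbias = np.array([bias.temp_bias[s] for s in season])
    pfac = np.array([bias.precip_factor[s] for s in season])

    tmin = base.tmin.copy()
    tmax = base.tmax.copy()
    if bias.variance_inflation != 1.0:
        for s in SEASONS:
            mask = season == s
            if not mask.any():
                continue
            for arr in (tmin, tmax):
                mu = arr[mask].mean()
                arr[mask] = mu + bias.variance_inflation * (arr[mask] - mu)
    tmin = tmin + tbias
    tmax = tmax + tbias
    if bias.temp_noise > 0:
        tmin = tmin + bias.temp_noise * rng.standard_normal(len(base))
        tmax = tmax + bias.temp_noise * rng.standard_normal(len(base))
    bad = tmax < tmin
    if bad.any():
        log.debug("pseudo-RCM clamped tmax on %d days", int(bad.sum()))
        tmax = np.where(bad, tmin, tmax)
    return DailyWeatherSeries(
        dates=base.dates, tmin=tmin, tmax=tmax, precip=base.precip * pfac
    )


def apply_scenario_deltas(
    base: DailyWeatherSeries, spec: ClimateScenarioSpec
) -> DailyWeatherSeries:
    """Monthly delta-change perturbation of a baseline series."""
    m = base.months - 1
    dtmin = np.asarray(spec.delta_tmin)[m]
    dtmax = np.asarray(spec.delta_tmax)[m]
    fac = np.asarray(spec.precip_factor)[m]
    tmin = base.tmin + dtmin
    tmax = base.tmax + dtmax
    bad = tmax < tmin
    if bad.any():
        log.debug("scenario deltas clamped tmax on %d days", int(bad.sum()))
        tmax = np.where(bad, tmin, tmax)
    return DailyWeatherSeries(
        dates=base.dates, tmin=tmin, tmax=tmax, precip=base.precip * fac
    )


def co2_concentration(spec: ClimateScenarioSpec) -> float:
    """The scenario's atmospheric CO2 (ppm); errors if the spec has none."""
    if spec.co2_ppm is None:
        raise ConfigurationError(f"scenario {spec.label!r} has no co2_ppm")
    return float(spec.co2_ppm)


# -- shipped scenario presets ------------------------------------------------

def _monthly_warming(annual: float, winter_amp: float) -> tuple[float, ...]:
    """Monthly warming pattern: annual mean + cosine winter amplification.

    Peaks in mid-January; the monthly mean equals ``annual`` exactly.
    """
    mid = (np.arange(12) + 0.5) / 12.0
    return tuple(annual + winter_amp * np.cos(2 * np.pi * (mid - 0.5 / 12.0)))


def _monthly_factors(spring: float, autumn: float, other: float = 0.95) -> tuple[float, ...]:
    """Monthly precipitation factors: reductions focused on spring (Mar-Apr)
    and autumn/early winter (Oct-Dec); summer left at 1 (negligible rain)."""
    fac = [other] * 12
    fac[2] = spring   # March
    fac[3] = spring   # April
    fac[9] = autumn   # October
    fac[10] = autumn  # November
    fac[11] = autumn  # December
    fac[5] = fac[6] = fac[7] = 1.0  # Jun-Aug
    return tuple(fac)


def scenario_presets() -> dict[str, ClimateScenarioSpec]:
    """Four delta-change presets emulating two emission pathways at two
    horizons (mid and end of century).

    Magnitudes follow the projected ranges for the region: annual warming
    from ~1.2 degC (moderate pathway, 2050) to ~5.5 degC (high pathway,
    2090), amplified in winter; spring and autumn precipitation reduced by
    12-45%.  CO2 concentrations are 20-year means from the published RCP
    concentration tables (Meinshausen et al. 2011).  These are emulations of
    downscaled ensembles, not reproductions of any specific model run.
    """
    presets = {}
    for label, annual, amp, spring, autumn, co2 in [
        ("RCP4.5-2050", 1.2, 0.6, 0.88, 0.88, 487.0),
        ("RCP8.5-2050", 2.0, 0.8, 0.62, 0.75, 541.0),
        ("RCP4.5-2090", 2.3, 0.9, 0.80, 0.82, 532.0),
        ("RCP8.5-2090", 5.5, 1.2, 0.55, 0.65, 845.0),
    ]:
        warm = _monthly_warming(annual, amp)
        presets[label] = ClimateScenarioSpec(
            label=label,
            delta_tmin=warm,
            delta_tmax=warm,
            precip_factor=_monthly_factors(spring, autumn),
            co2_ppm=co2,
        )
    return presets
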