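"""Water-driven wheat simulation in the AquaCrop style.

The model advances one day at a time through a crop season:

1.  thermal time: daily growing degree days accumulate and set the
    phenological phase (emergence, canopy growth, senescence, maturity);
2.  canopy cover ``CC`` grows exponentially toward its maximum on a GDD
    clock (scaled by a water-stress coefficient on expansion) and declines
    after senescence onset;
3.  reference evapotranspiration is partitioned into crop transpiration
    ``Tr = Ks_sto * KcTr_x * CC** * ET0`` (``CC**`` the micro-advection
    adjusted cover) and soil evaporation ``E = Kr * Ke_max * (1 - CC**) *
    ET0`` with a two-stage drying surface layer;
4.  a single root-zone bucket tracks depletion ``Dr`` below field capacity:
    rain and irrigation reduce it, evaporation and transpiration increase
    it, surplus beyond field capacity drains at up to ``Ksat``;
5.  automatic irrigation refills the bucket to zero depletion whenever
    depletion exceeds half of the total available water (Dr > 0.5 TAW), the
    scheduling rule used for optimally irrigated wheat in the study region;
6.  biomass grows by the normalized water productivity ``dB = WP* * fCO2 *
    Tr/ET0`` and yield is biomass times a harvest index that builds
    linearly in thermal time from flowering to maturity.

Rising atmospheric CO2 acts through the multiplier ``fCO2`` on WP*; heat
above 30 degC during the pollination window can optionally reduce the
attainable harvest index (off by default).

The per-day update order in :func:`run_season` is normative and documented
in the methods note; a deliberately naive reference implementation of the
same order must reproduce the daily trace exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, SimulationError
from .phenology import CropCalendar, StageDurations, daily_gdd, season_starts
from .synthetic import CO2_REFERENCE_PPM
from .weather import DailyWeatherSeries

__all__ = [
    "SoilProfile",
    "CropParams",
    "SimulationResult",
    "tensift_soil",
    "tensift_wheat",
    "taw",
    "ks_from_depletion",
    "adjusted_canopy",
    "canopy_step",
    "evaporation_reduction",
    "partition_et",
    "water_balance_step",
    "auto_irrigate",
    "fco2",
    "biomass_step",
    "run_season",
    "run_seasons",
]


@dataclass(frozen=True)
class SoilProfile:
    """Homogeneous soil water-holding characteristics.

    Defaults describe the clay-loam of the study region.
    """

    theta_fc: float = 0.32      # field capacity, m3/m3
    theta_wp: float = 0.17      # permanent wilting point, m3/m3
    theta_sat: float = 0.45     # saturation, m3/m3
    ksat: float = 100.0         # saturated hydraulic conductivity, mm/day
    initial_depletion_fraction: float = 0.5   # Dr(0) as a fraction of TAW
    min_root_depth: float = 0.3  # m, effective zone at sowing
    max_root_depth: float = 1.0  # m
    rew: float = 9.0            # readily evaporable water, mm
    evap_layer_depth: float = 0.1  # m, surface layer governing stage-II drying

    def __post_init__(self) -> None:
        if not (self.theta_wp < self.theta_fc < self.theta_sat):
            raise ParameterError("need theta_wp < theta_fc < theta_sat")
        if self.ksat <= 0:
            raise ParameterError("ksat must be positive")
        if not (0.0 <= self.initial_depletion_fraction <= 1.0):
            raise ParameterError("initial depletion fraction must lie in [0, 1]")
        if not (0 < self.min_root_depth <= self.max_root_depth):
            raise ParameterError("need 0 < min_root_depth <= max_root_depth")
        if self.rew <= 0 or self.evap_layer_depth <= 0:
            raise ParameterError("rew and evap_layer_depth must be positive")

    @property
    def tew(self) -> float:
        """Total evaporable water of the surface layer (mm)."""
        return 1000.0 * (self.theta_fc - 0.5 * self.theta_wp) * self.evap_layer_depth


def tensift_soil() -> SoilProfile:
    return SoilProfile()


@dataclass(frozen=True)
class CropParams:
    """Wheat parameters: canopy, transpiration, productivity, stress response.

    The phenological clock lives in ``calendar`` (GDD thresholds).
    """

    calendar: CropCalendar
    cc0: float = 0.03           # initial canopy fraction at emergence
    ccx: float = 0.96           # maximum canopy fraction
    cgc: float = 0.008          # canopy growth coefficient, per GDD
    cdc: float = 0.002          # canopy decline coefficient, per GDD
    kc_tr_x: float = 1.1        # maximum crop transpiration coefficient
    ke_max: float = 1.1         # maximum soil evaporation coefficient
    wp_star: float = 15.0       # normalized water productivity, g/m2
    hi0: float = 0.48           # reference harvest index
    p_expansion_upper: float = 0.2   # depletion fraction halting leaf expansion
    p_stomata: float = 0.65          # depletion fraction closing stomata
    p_senescence: float = 0.70       # depletion fraction triggering early senescence
    stress_shape: float = 3.0        # curvature of the stress response (0 = linear)
    co2_ref: float = CO2_REFERENCE_PPM
    gdd_flowering: float | None = None   # default: midway max-canopy..senescence
    heat_threshold: float = 30.0     # degC on Tmax, pollination sensitivity
    heat_slope: float = 0.0          # attainable-HI loss per degC-day above threshold
    pollination_window_days: int = 5  # half-width around flowering
    sowing_density: float = 150.0    # kg/ha, informational

    def __post_init__(self) -> None:
        if not (0 < self.cc0 < self.ccx <= 1):
            raise ParameterError("need 0 < cc0 < ccx <= 1")
        if not (0 < self.hi0 < 1):
            raise ParameterError("hi0 must lie in (0, 1)")
        for name in ("p_expansion_upper", "p_stomata", "p_senescence"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.p_stomata < self.p_expansion_upper:
            raise ParameterError("p_stomata must be >= p_expansion_upper")
        if min(self.cgc, self.cdc, self.kc_tr_x, self.ke_max, self.wp_star) <= 0:
            raise ParameterError("cgc, cdc, kc_tr_x, ke_max, wp_star must be positive")

    @property
    def flowering_gdd(self) -> float:
        if self.gdd_flowering is not None:
            return self.gdd_flowering
        cal = self.calendar
        return 0.5 * (cal.gdd_max_canopy + cal.gdd_senescence)


def tensift_wheat(calendar: CropCalendar, **overrides) -> CropParams:
    """Durum-wheat profile for the study region (published wheat defaults for
    the non-conservative parameters; all overridable)."""
    return CropParams(calendar=calendar, **overrides)


# -- elementary operations ---------------------------------------------------

def taw(soil: SoilProfile, root_depth: float) -> float:
    """Total available water of the root zone (mm)."""
    if root_depth <= 0:
        raise ParameterError("root depth must be positive")
    return 1000.0 * (soil.theta_fc - soil.theta_wp) * root_depth


def ks_from_depletion(dr: float, taw_mm: float, p_upper: float, shape: float) -> float:
    """Water-stress coefficient in [0, 1] from root-zone depletion.

    Ks = 1 while depletion is below ``p_upper * TAW``, 0 at full depletion,
    and a convex curve in between (``shape = 0`` gives the linear response;
    larger shapes delay the stress onset).
    """
    if taw_mm <= 0:
        raise ParameterError("TAW must be positive")
    if dr < 0 or dr > taw_mm:
        dr = min(max(dr, 0.0), taw_mm)
    thresh = p_upper * taw_mm
    if dr <= thresh:
        return 1.0
    if taw_mm == thresh:
        return 0.0
    s = (dr - thresh) / (taw_mm - thresh)
    if shape == 0.0:
        return 1.0 - s
    return 1.0 - math.expm1(s * shape) / math.expm1(shape)


def adjusted_canopy(cc: float) -> float:
    """Micro-advection adjusted canopy cover CC** = 1.72 CC - CC^2 + 0.30 CC^3."""
    return 1.72 * cc - cc * cc + 0.30 * cc * cc * cc


def canopy_step(
    cc: float,
    cum_gdd: float,
    gdd_today: float,
    crop: CropParams,
    ks_expansion: float,
) -> float:
    """One-day canopy update on the GDD clock.

    Before emergence the cover is zero; at emergence it starts at ``cc0``.
    During growth the cover rises exponentially while below half of ``ccx``
    and then decays exponentially toward ``ccx`` (growth scaled by the
    expansion stress coefficient); after senescence onset it declines at
    ``cdc`` per GDD until zero.
    """
    cal = crop.calendar
    if cum_gdd < cal.gdd_emergence:
        return 0.0
    if cum_gdd < cal.gdd_senescence:
        if cc <= 0.0:
            cc = crop.cc0
        growth = crop.cgc * ks_expansion * gdd_today
        if cc <= crop.ccx / 2.0:
            cc = cc * math.exp(growth)
        else:
            cc = crop.ccx - (crop.ccx - cc) * math.exp(-growth)
        return min(cc, crop.ccx)
    return max(0.0, cc - crop.cdc * gdd_today)


def evaporation_reduction(de: float, rew: float, tew: float) -> float:
    """Two-stage soil-drying coefficient Kr.

    Stage I (surface depletion below REW): evaporation at the full rate.
    Stage II: linear reduction to zero as depletion approaches TEW.
    """
    if de <= rew:
        return 1.0
    if de >= tew:
        return 0.0
    return (tew - de) / (tew - rew)


def partition_et(
    cc_star: float,
    ks_stomata: float,
    kc_tr_x: float,
    et0: float,
    kr: float,
    ke_max: float,
) -> tuple[float, float]:
    """Potential (transpiration, evaporation) for one day (mm)."""
    tr = ks_stomata * kc_tr_x * cc_star * et0
    e = kr * ke_max * (1.0 - min(cc_star, 1.0)) * et0
    return tr, e


def water_balance_step(
    dr: float,
    precip: float,
    irrigation: float,
    e: float,
    tr: float,
    taw_mm: float,
    ksat: float,
) -> tuple[float, float, float, float]:
    """One-day root-zone bucket update.

    Inflows reduce depletion; surplus beyond field capacity (negative
    depletion) drains at up to ``ksat`` per day.  Evaporation plus
    transpiration are capped by the water still available above wilting
    point (proportional scaling).  Returns ``(dr', e_actual, tr_actual,
    drainage)``; closure ``P + I = E + Tr + D + (dr' - dr... )`` holds
    exactly in the sense ``dr' = dr - P - I + D + E + Tr``.
    """
    if min(precip, irrigation, e, tr) < 0:
        raise DataError("water fluxes must be non-negative")
    dr1 = dr - precip - irrigation
    drainage = 0.0
    if dr1 < 0.0:
        excess = -dr1
        drainage = excess if excess <= ksat else ksat
        dr1 = -(excess - drainage)
    available = taw_mm - dr1
    demand = e + tr
    if demand > available:
        f = available / demand if demand > 0.0 else 0.0
        f = max(f, 0.0)
        e = e * f
        tr = tr * f
    dr2 = dr1 + e + tr
    return dr2, e, tr, drainage


def auto_irrigate(dr: float, taw_mm: float, trigger_fraction: float = 0.5) -> float:
    """Refill-to-zero-depletion irrigation when Dr strictly exceeds the
    trigger fraction of TAW (0.5 TAW by default); otherwise no water."""
    if dr > trigger_fraction * taw_mm:
        return dr
    return 0.0


def fco2(ca: float, ca_ref: float = CO2_REFERENCE_PPM) -> float:
    """CO2 fertilization multiplier on normalized water productivity.

    ``fCO2 = (Ca/Ca_ref) / (1 + (Ca - Ca_ref) * 0.000138)``: a damped
    proportional response, equal to 1 at the reference concentration.
    """
    if ca <= 0:
        raise ParameterError("CO2 concentration must be positive")
    return (ca / ca_ref) / (1.0 + (ca - ca_ref) * 0.000138)


def biomass_step(tr: float, et0: float, wp_star: float, f_co2: float) -> float:
    """Daily biomass increment dB = WP* * fCO2 * (Tr / ET0) in g/m2."""
    if tr == 0.0:
        return 0.0
    if et0 <= 0.0:
        raise SimulationError("positive transpiration with zero ET0")
    return wp_star * f_co2 * (tr / et0)


# -- season driver -----------------------------------------------------------

@dataclass(frozen=True)
class SimulationResult:
    """Season outputs: yield, phenology, water fluxes and derived indicators."""

    yield_t_ha: float
    biomass_t_ha: float
    durations: StageDurations
    e_mm: float
    tr_mm: float
    precip_mm: float
    irrigation_mm: float
    drainage_mm: float
    irrigation_by_month: dict[int, float]
    max_residual: float
    sowing: pd.Timestamp
    trace: pd.DataFrame = field(repr=False, compare=False)

    @property
    def lcs(self) -> float:
        return self.durations.maturity

    @property
    def et_mm(self) -> float:
        return self.e_mm + self.tr_mm

    @property
    def wr_mm(self) -> float:
        """Seasonal water requirement: irrigation + precipitation received."""
        return self.irrigation_mm + self.precip_mm

    @property
    def effective_precip_mm(self) -> float:
        """Precipitation minus deep drainage over the season."""
        return self.precip_mm - self.drainage_mm

    @property
    def wp(self) -> float:
        """Water productivity: grain yield per unit of evapotranspired water
        (kg of grain per m3 of ET)."""
        # 1 t/ha over 1 mm on 1 m2: t/ha = 100 g/m2; mm = litre/m2
        return (self.yield_t_ha * 100.0) / self.et_mm if self.et_mm > 0 else 0.0

    @property
    def wp_biomass_tr(self) -> float:
        """Above-ground dry matter per unit of transpired water (kg/m3)."""
        return (self.biomass_t_ha * 100.0) / self.tr_mm if self.tr_mm > 0 else 0.0


def run_season(
    weather: DailyWeatherSeries,
    et0: np.ndarray,
    crop: CropParams,
    soil: SoilProfile,
    co2_ppm: float = CO2_REFERENCE_PPM,
    irrigate: bool = True,
    sowing: pd.Timestamp | None = None,
    trigger_fraction: float = 0.5,
    max_days: int = 330,
) -> SimulationResult:
    """Simulate one crop season from sowing to thermal maturity.

    ``et0`` must be aligned with ``weather``.  With ``sowing`` omitted the
    first complete season in the series is used.  Raises
    :class:`SimulationError` if maturity is not reached within ``max_days``
    or the series end.
    """
    if len(et0) != len(weather):
        raise DataError("et0 series must align with the weather series")
    cal = crop.calendar
    if sowing is None:
        sowing = season_starts(weather, cal.sowing_month, cal.sowing_day)[0]
    sowing = pd.Timestamp(sowing)
    i0 = int(np.searchsorted(weather.dates, sowing))
    if i0 >= len(weather) or weather.dates[i0] != sowing:
        raise DataError(f"sowing date {sowing.date()} not in the weather series")

    f_co2 = fco2(co2_ppm, crop.co2_ref)
    tew = soil.tew
    dr = soil.initial_depletion_fraction * taw(soil, soil.min_root_depth)
    de = min(dr, tew)
    cc = 0.0
    cum_gdd = 0.0
    biomass = 0.0
    hi = 0.0
    penalty = 0.0
    flowering_day: int | None = None
    stage_days = [None, None, None, None]  # emergence, max canopy, senescence, maturity
    root_span = soil.max_root_depth - soil.min_root_depth
    gdd_span = cal.gdd_max_canopy - cal.gdd_emergence
    gf = crop.flowering_gdd
    hi_span = cal.gdd_maturity - gf
    win = crop.pollination_window_days

    rows = []
    tmax_hist: list[float] = []
    n_avail = len(weather) - i0
    n_days = min(max_days, n_avail)
    max_residual = 0.0
    cum_e = cum_tr = cum_irr = cum_p = cum_drain = 0.0

    day = 0
    matured = False
    while day < n_days:
        i = i0 + day
        day += 1  # 1-based day-after-sowing index
        tmin_d = float(weather.tmin[i])
        tmax_d = float(weather.tmax[i])
        p_d = float(weather.precip[i])
        et0_d = float(et0[i])
        tmax_hist.append(tmax_d)

        # 1. thermal time
        gdd_today = float(daily_gdd(tmin_d, tmax_d, cal.tbase, cal.tupper))
        cum_gdd += gdd_today
        if stage_days[0] is None and cum_gdd >= cal.gdd_emergence:
            stage_days[0] = day
        if stage_days[1] is None and cum_gdd >= cal.gdd_max_canopy:
            stage_days[1] = day
        if stage_days[2] is None and cum_gdd >= cal.gdd_senescence:
            stage_days[2] = day

        # 2. root zone
        if gdd_span > 0.0:
            frac = (cum_gdd - cal.gdd_emergence) / gdd_span
        else:
            frac = 1.0
        frac = min(max(frac, 0.0), 1.0)
        z = soil.min_root_depth + root_span * frac
        taw_mm = taw(soil, z)
        if dr > taw_mm:
            dr = taw_mm  # cannot be more depleted than the (grown) zone allows

        # 3. irrigation decision (before any extraction)
        irr = auto_irrigate(dr, taw_mm, trigger_fraction) if irrigate else 0.0

        # 4. infiltration, drainage and surface wetting
        dr_start = dr
        de = max(0.0, de - p_d - irr)

        # 5. canopy development
        ks_exp = ks_from_depletion(
            max(dr - p_d - irr, 0.0), taw_mm, crop.p_expansion_upper, crop.stress_shape
        )
        cc = canopy_step(cc, cum_gdd, gdd_today, crop, ks_exp)

        # 6.-7. evapotranspiration partition
        cc_star = adjusted_canopy(cc)
        ks_sto = ks_from_depletion(
            max(dr - p_d - irr, 0.0), taw_mm, crop.p_stomata, crop.stress_shape
        )
        kr = evaporation_reduction(de, soil.rew, tew)
        tr_pot, e_pot = partition_et(
            cc_star, ks_sto, crop.kc_tr_x, et0_d, kr, crop.ke_max
        )

        # 8. bucket update with supply cap
        dr, e_act, tr_act, drain = water_balance_step(
            dr, p_d, irr, e_pot, tr_pot, taw_mm, soil.ksat
        )
        de = min(tew, de + e_act)

        # closure: dr' - dr_start = -(P + I) + D + E + Tr
        residual = abs((dr - dr_start) - (-(p_d + irr) + drain + e_act + tr_act))
        if residual > max_residual:
            max_residual = residual

        # 9. biomass and harvest index
        biomass += biomass_step(tr_act, et0_d, crop.wp_star, f_co2) if et0_d > 0 else 0.0
        if flowering_day is None and cum_gdd >= gf:
            flowering_day = day
            if crop.heat_slope > 0.0:
                for past in tmax_hist[max(0, day - 1 - win): day - 1]:
                    if past > crop.heat_threshold:
                        penalty += crop.heat_slope * (past - crop.heat_threshold)
        if (
            flowering_day is not None
            and crop.heat_slope > 0.0
            and flowering_day <= day <= flowering_day + win
            and tmax_d > crop.heat_threshold
        ):
            penalty += crop.heat_slope * (tmax_d - crop.heat_threshold)
        if flowering_day is not None:
            attainable = crop.hi0 * max(0.0, 1.0 - penalty)
            hi = attainable * min(1.0, (cum_gdd - gf) / hi_span)

        cum_e += e_act
        cum_tr += tr_act
        cum_irr += irr
        cum_p += p_d
        cum_drain += drain
        rows.append(
            (
                weather.dates[i], gdd_today, cum_gdd, cc, z, taw_mm, dr, de,
                e_act, tr_act, irr, p_d, drain, biomass, hi, residual,
                ks_exp, ks_sto,
            )
        )

        if cum_gdd >= cal.gdd_maturity:
            stage_days[3] = day
            matured = True
            break

    if not matured:
        raise SimulationError(
            f"maturity not reached within {n_days} days from {sowing.date()} "
            f"(accumulated {cum_gdd:.0f}/{cal.gdd_maturity:.0f} GDD)"
        )

    trace = pd.DataFrame(
        rows,
        columns=[
            "date", "gdd", "cum_gdd", "cc", "root_depth", "taw", "dr", "de",
            "e", "tr", "irrigation", "precip", "drainage", "biomass", "hi",
            "residual", "ks_expansion", "ks_stomata",
        ],
    )
    irr_by_month: dict[int, float] = {}
    if cum_irr > 0:
        g = trace.groupby(trace["date"].dt.month)["irrigation"].sum()
        irr_by_month = {int(m): float(v) for m, v in g.items() if v > 0}

    durations = StageDurations(
        emergence=float(stage_days[0]),
        max_canopy=float(stage_days[1]),
        senescence_start=float(stage_days[2]),
        maturity=float(stage_days[3]),
    )
    return SimulationResult(
        yield_t_ha=biomass * hi / 100.0,
        biomass_t_ha=biomass / 100.0,
        durations=durations,
        e_mm=cum_e,
        tr_mm=cum_tr,
        precip_mm=cum_p,
        irrigation_mm=cum_irr,
        drainage_mm=cum_drain,
        irrigation_by_month=irr_by_month,
        max_residual=max_residual,
        sowing=sowing,
        trace=trace,
    )


def run_seasons(
    weather: DailyWeatherSeries,
    et0: np.ndarray,
    crop: CropParams,
    soil: SoilProfile,
    co2_ppm: float = CO2_REFERENCE_PPM,
    irrigate: bool = True,
    trigger_fraction: float = 0.5,
) -> list[SimulationResult]:
    """Simulate every complete season in a multi-year series."""
    cal = crop.calendar
    starts = season_starts(weather, cal.sowing_month, cal.sowing_day)
    return [
        run_season(
            weather, et0, crop, soil, co2_ppm,
            irrigate=irrigate, sowing=s, trigger_fraction=trigger_fraction,
        )
        for s in starts
    ]
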