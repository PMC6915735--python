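# Methods

`aridwheat` chains five stages: a stochastic weather generator for a
semi-arid Mediterranean site, seasonal empirical quantile mapping,
temperature-only reference evapotranspiration, degree-day wheat phenology,
and a daily water-driven crop simulation wired into factorial
CO2 x climate experiments. This note records the models, the parameter
choices and the numerical conventions, and what the synthetic setting can
and cannot show.

## Synthetic climate

The generator emulates a Marrakech-like station record (Haouz plain,
~31.5 degN): annual rainfall in the 190-250 mm band concentrated from
November to April, and an evaporative demand near 1600 mm/yr.

**Precipitation.** Daily occurrence follows a first-order two-state
(wet/dry) Markov chain. Each month m has an unconditional wet-day
probability pi_m (default 0.02-0.18 across the year); persistence r (lag-1
occurrence autocorrelation, default 0.4) sets the transition probabilities
`p(wet|dry) = (1-r) pi` and `p(wet|wet) = (1-r) pi + r`, which leave pi
stationary. Wet-day depths are gamma with monthly mean (3.2-6.1 mm) and
shape 0.7 — semi-arid daily rain is strongly right-skewed. Expected monthly
totals are therefore `pi_m x depth_m x days_m`, summing to ~227 mm/yr with
~76% in November-April.

**Temperature.** Monthly normal Tmin/Tmax (December ~6.8/18.9, July
~20.2/37.2 degC) are smoothed into a daily seasonal cycle by a two-harmonic
Fourier fit through the month midpoints. A single AR(1) anomaly (phi = 0.7,
marginal sd 2.2 degC) is added to both temperatures — synoptic variability
moves Tmin and Tmax together — plus independent N(0, 1 degC) noise on Tmax
for diurnal-range variability. Violations of Tmin <= Tmax (vanishingly rare
given the ~12-17 degC mean range) are repaired by raising Tmax, which
preserves means better than swapping.

**Pseudo-RCM and scenarios.** Raw regional-model output is emulated by
distorting the baseline with per-season additive temperature biases,
multiplicative precipitation biases, optional variance inflation and white
noise. Scenario series use the delta-change method: monthly additive
Tmin/Tmax offsets and multiplicative precipitation factors. Four shipped
presets emulate two emission pathways at mid- and end-century: annual
warming 1.2 / 2.0 / 2.3 / 5.5 degC with a cosine winter amplification
(+0.6 to +1.2 degC at the mid-January peak, matching the stronger projected
winter warming), spring (Mar-Apr) precipitation factors down to 0.55 and
autumn/early-winter (Oct-Dec) factors down to 0.65. Preset CO2
concentrations are 20-year means from the published RCP concentration
tables (Meinshausen et al. 2011): 487 / 541 / 532 / 845 ppm. The presets
are emulations of a downscaled ensemble's magnitudes, not reproductions of
any model run.

What the generator does *not* emulate: multi-day storm totals beyond
chain persistence, spatial fields, humidity/wind/radiation (not needed by
the ET0 method), observed interannual drought cycles, and trends within the
baseline window. Tests passing on this synthetic baseline demonstrate the
pipeline's internal contracts (closure, monotonicity, round trips,
directions of change), not predictive skill on the real station record.

## Quantile-quantile bias correction

For each variable (Tmin, Tmax, precipitation) and each three-month season
(JFM, AMJ, JAS, OND — the partition keeps the rainy and dry seasons apart),
the correction matches 101 nodes: the minimum, percentiles 1-99, and the
maximum of the daily series. Model values between nodes are corrected by
linear interpolation of (model node -> observed node).

Numerical conventions, chosen where the procedure itself is silent:

* **Percentile estimator**: linear interpolation between order statistics
  ("type 7"), applied identically to both series, so fitting a series
  against itself yields the exact identity map.
* **Tails**: values beyond the min/max nodes get the constant additive
  offset of the nearest endpoint (`obs_end + (x - model_end)`). This is
  monotone and bounded; empirical quantile maps are known to corrupt
  extremes, and a constant extension is the least-surprise choice.
  The additive tail is used for precipitation too (flagged for sensitivity
  testing); corrected precipitation is clamped at zero.
* **Dry days**: precipitation is fitted on all days, dry days included; an
  all-dry season yields a flat (all-zero) map that leaves zeros unchanged.
* **Temperatures** are corrected independently; Tmin <= Tmax is re-enforced
  afterwards by raising Tmax (count logged).

Because both sides use one percentile definition, correcting the
calibration series reproduces observed seasonal percentiles to floating
precision, and an additive bias leaves scenario-minus-historical seasonal
mean changes intact to well under 10% (both are tested).

## Reference evapotranspiration

Only air temperature is available, so ET0 uses Hargreaves-Samani:

    ET0 = 0.0023 (Tmean + 17.8) sqrt(Tmax - Tmin) (0.408 Ra)   [mm/day]

with Ra the extraterrestrial radiation from standard FAO-56 astronomy
(inverse relative distance, solar declination, sunset hour angle; solar
constant 0.0820 MJ m-2 min-1). The 0.0023 coefficient is kept at its
published value — the formula has been validated in the study region
without local recalibration. Ra is tabulated once per latitude for
day-of-year 1-366 and cached; latitude is restricted to [-66, 66] where the
sunset-angle formula is valid. Negative (Tmean + 17.8) clamps ET0 to zero,
a physically forced choice that never triggers in this climate.

## Degree-day phenology

Daily growing degree days use the mean method: `GDD = clip((Tmin+Tmax)/2,
Tbase, Tupper) - Tbase`, with wheat defaults Tbase = 0 degC and
Tupper = 26 degC. The locally calibrated cardinal temperatures for the
study cultivar are not published in accessible form, so the defaults are
exposed in the calendar and overridable.

Stage thresholds are calibrated by inversion: the observed year-2000 stage
boundaries (days after sowing) per sowing date —

| sowing       | date   | emergence | max canopy | senescence | maturity |
|--------------|--------|-----------|------------|------------|----------|
| early        | Nov 15 | 7         | 83         | 112        | 152      |
| intermediate | Dec 15 | 9         | 83         | 106        | 141      |
| late         | Jan 15 | 11        | 72         | 93         | 125      |

— are converted to GDD sums from sowing, averaged over all complete
baseline seasons (treating the published durations as climatological
means). Projection finds, per season, the first day whose running GDD sum
reaches each threshold (day 1 = sowing day); whole-day discretization makes
the calibrate-project round trip exact to within one day, with a ~+0.5 day
ceiling bias. Ties between adjacent boundaries are broken by pushing the
later stage one day forward. Multi-year projections average the per-season
durations. No photoperiod or vernalization response is modelled.

## Crop simulation

A single-bucket, water-driven canopy model. The per-day update order is
normative (the test suite holds a naive transcription to bit-identical
agreement):

1. **Thermal time**: accumulate GDD; stage boundaries from the calendar.
2. **Root zone**: depth grows linearly in GDD from 0.3 m to 1.0 m between
   emergence and maximum canopy; `TAW = 1000 (theta_fc - theta_wp) z`.
   Newly tapped soil enters at field capacity, i.e. depletion Dr (mm) is
   carried unchanged, and storage is accounted as depletion so root growth
   does not break closure.
3. **Irrigation decision** (before any extraction): if `Dr > 0.5 TAW`
   (strict inequality), apply `Dr` mm — refill to zero depletion. This is
   the automatic scheduling rule for optimally irrigated wheat in the
   region; the trigger fraction is configurable.
4. **Infiltration**: rain + irrigation reduce Dr; surplus below zero
   depletion (above field capacity) drains at up to Ksat/day, any remainder
   is carried as negative depletion. The surface evaporation layer is
   wetted first (`de -= P + I`, floored at 0).
5. **Canopy**: `CC` starts at cc0 = 0.03 at emergence, grows exponentially
   at `cgc x Ks_exp` per GDD while below CCx/2, then approaches
   CCx = 0.96 by exponential decay of the gap; after senescence onset it
   declines at cdc per GDD to zero. cgc = 0.008/GDD and cdc = 0.002/GDD
   were set so the canopy closes by the observed maximum-canopy stage and
   dies back over the senescence window under the baseline thermal regime.
6. **Transpiration**: `Tr = Ks_sto Kc_Tr,x CC** ET0` with Kc_Tr,x = 1.1 and
   the micro-advection adjustment `CC** = 1.72 CC - CC^2 + 0.30 CC^3`.
7. **Evaporation**: `E = Kr Ke_max (1 - min(CC**,1)) ET0`, Ke_max = 1.1,
   with two-stage drying of a 0.1 m surface layer: full rate while its
   depletion is below REW = 9 mm, then linear reduction to zero at
   TEW = 1000 (theta_fc - 0.5 theta_wp) x 0.1 = 23.5 mm.
8. **Supply cap**: E + Tr jointly limited to the water above wilting point
   (proportional scaling), then `Dr += E + Tr`. Closure
   `P + I = E + Tr + drainage + dStorage` holds identically; the engine
   records the per-day residual (~1e-14 mm in practice, asserted < 1e-6).
9. **Stress**: `Ks = 1` below the depletion threshold `p x TAW`, 0 at full
   depletion, with a convex exponential curve (shape 3) between; shape 0
   recovers the linear response. Thresholds p_expansion = 0.2,
   p_stomata = 0.65 (published wheat defaults). With auto-irrigation at
   0.5 TAW the stomatal coefficient stays at 1 — the "optimal irrigation"
   premise — which the suite asserts on >= 99% of growth days.
10. **Biomass**: `dB = WP* fCO2 (Tr/ET0)` with WP* = 15 g/m2 (C3 cereal).
    `fCO2 = (Ca/Ca_ref)/(1 + (Ca - Ca_ref) 0.000138)`, Ca_ref = 369.41 ppm
    (year 2000). Under ample irrigation yield therefore scales exactly by
    fCO2 — the analytic content of the CO2-only experiment.
11. **Harvest index**: zero before flowering (default flowering GDD midway
    between maximum canopy and senescence onset), linear in GDD to
    HI0 = 0.48 at maturity. Days with Tmax > 30 degC inside a +/-5-day
    pollination window can reduce the attainable HI linearly
    (`heat_slope` per degC-day); the slope defaults to 0 because the
    threshold is essentially never reached in these runs, and the mechanism
    is exercised in tests with a nonzero slope.

Yield (t/ha) = biomass (g/m2) x HI / 100. Soil defaults are the regional
clay loam: theta_fc/theta_wp/theta_sat = 0.32/0.17/0.45 m3/m3,
Ksat = 100 mm/day; initial depletion is half of the initial-root-zone TAW.
Runoff, capillary rise, salinity, fertility and multi-layer soil are out of
scope (flat irrigated fields, ~230 mm rain, homogeneous profile).

**Reported water indicators.** `WR` (water requirement) is seasonal
irrigation + precipitation received between sowing and maturity; effective
precipitation (precipitation minus drainage) is available separately.
`WP` is grain yield per cubic metre of seasonal evapotranspiration
(kg/m3), the definition that matches the regional reference values
(~2.1/1.6/1.3 kg/m3 for early/intermediate/late sowing); the alternative
above-ground-biomass-per-transpiration ratio is exposed as
`wp_biomass_tr`. Monthly irrigation profiles attribute each event to its
calendar month (event-date convention).

## Experiments

Four kinds — historical (baseline weather, 369.41 ppm), co2_only (baseline
weather, scenario CO2), cc_only (scenario weather, 369.41 ppm), cco2
(both) — crossed with the scenario presets, the three sowing dates and
three ensemble members. Ensemble spread is emulated by synthesising five
pseudo-model specs per preset (seeded multiplicative jitter, sd 20%, on
monthly warming; additive jitter, sd 0.05, on precipitation factors) and
running the member Mean and Mean +/- SD of their monthly deltas
(mean-minus-SD precipitation factors floored at zero). Relative changes are
`100 (x - x_hist)/x_hist` against the historical cell of the same sowing.
One master seed drives everything; per-run seeds derive deterministically
(CRC32 of the spec fields), so grid outputs are bit-reproducible.

**Problem sizes.** The default window is 20 years (the length of the
historical study period), giving 19-20 seasons per cell; the full grid
(4 kinds x 4 scenarios x 3 sowings x 3 members, deduplicated) runs in a few
seconds, and analysis drivers and the acceptance script use these same
sizes.

## Known limitations

* The fCO2 response is the first-order normalized ratio; later crop-model
  variants damp it further with a sink-strength weighting, so the CO2-only
  gains here sit above the published impact-study range at high
  concentrations.
* The canopy, productivity and harvest-index parameters are published wheat
  defaults, not the locally calibrated (supplementary-only) values;
  absolute yields land in the regionally reported range but are not a
  calibration.
* Stage-II soil evaporation uses a single surface layer without
  re-wetting-fraction bookkeeping; under frequent small storms E is
  slightly optimistic.
* The weather generator's variance structure (single AR(1), monthly
  stationary chain) understates low-frequency drought persistence, so
  ensemble spreads here reflect parameter jitter, not climate-model
  disagreement.
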