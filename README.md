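# aridwheat

Climate-change impact analysis for irrigated wheat in a semi-arid
Mediterranean environment (a Marrakech-like site, ~31.5 degN, 190-250 mm
of rain against ~1600 mm of evaporative demand per year). The package is
aimed at agronomists and hydrologists who want a transparent, fully
testable version of the standard impact chain:

1. **synthetic climate** (`aridwheat.synthetic`) — a stochastic weather
   generator (monthly Markov-chain occurrence + gamma depths; harmonic
   seasonal temperature cycle + AR(1) anomaly) for the baseline, biased
   "pseudo-RCM" series, and monthly delta-change scenario series with
   winter-amplified warming of 1.2-5.5 degC and spring/autumn drying;
2. **bias correction** (`aridwheat.qmap`) — seasonal empirical
   quantile-quantile mapping: per variable and per season (JFM/AMJ/JAS/OND)
   the 99 percentiles plus min/max of the model series are matched onto the
   observed ones, with linear interpolation between nodes;
3. **reference evapotranspiration** (`aridwheat.atmosphere`) —
   Hargreaves-Samani, `ET0 = 0.0023 (Tmean+17.8) sqrt(Tmax-Tmin) (0.408 Ra)`,
   with FAO-56 extraterrestrial radiation Ra(latitude, day of year);
4. **phenology** (`aridwheat.phenology`) — growing-degree-day thermal time
   (mean method, Tbase 0 / Tupper 26 degC); stage thresholds calibrated by
   inversion from the observed stage durations per sowing date and
   projected onto warmed series;
5. **crop simulation** (`aridwheat.crop`) — a daily water-driven canopy
   model: canopy cover on a GDD clock, `Tr = Ks Kc_Tr,x CC** ET0`,
   two-stage soil evaporation, a single root-zone bucket with automatic
   irrigation (refill when depletion Dr > 0.5 TAW), normalized water
   productivity biomass `dB = WP* fCO2 Tr/ET0` with CO2 fertilization, and
   harvest-index yield formation;
6. **experiments** (`aridwheat.experiments`) — the factorial design:
   historical / CO2-only / climate-only / combined, crossed with scenario
   presets, three sowing dates (Nov 15, Dec 15, Jan 15) and ensemble
   members (Mean, Mean +/- SD of five pseudo-models), reported as relative
   changes in yield, season length, E, Tr, water requirement, irrigation
   (total and by month) and water productivity.

See `docs/methods.md` for the models, parameter defaults and numerical
conventions.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
baseline and write tables under `results/` (bulky daily series go to
`scratch/`):

```sh
python analysis/01_generate_climate.py   # baseline + pseudo-RCM weather
python analysis/02_bias_correction.py    # Q-Q fit, apply, verification
python analysis/03_phenology.py          # stage-duration projections
python analysis/04_baseline_crop.py      # historical crop simulation
python analysis/05_experiments.py        # full factorial grid
```

`01` prints the climate the rest builds on:

```
baseline: 20 years, 7305 days
  annual precipitation :  236.3 mm (target band 190-250)
  Nov-Apr share        :   74.1 % (>= 70 expected)
  annual ET0           : 1575.1 mm (~1600 regional)
```

`02` shows the quantile mapping removing a prescribed +1.5-2.5 degC /
x1.2-1.5 seasonal bias (seasonal means after correction agree to a few
thousandths), `04` prints the historical baseline that anchors every
relative change:

```
       early: yield  7.9 t/ha | LCS 152.6 d | E  90.1 + Tr 276.7 = ET 366.8 mm | WR 372.3 mm (IR 224.9) | WP 2.17 kg/m3
intermediate: yield  7.0 t/ha | LCS 141.5 d | E  91.0 + Tr 303.7 = ET 394.7 mm | WR 387.7 mm (IR 261.9) | WP 1.77 kg/m3
        late: yield  5.8 t/ha | LCS 125.5 d | E  95.3 + Tr 307.2 = ET 402.5 mm | WR 397.5 mm (IR 288.4) | WP 1.43 kg/m3
```

— early sowing yields most but also demands the longest season, and water
productivity falls from 2.2 to 1.4 kg of grain per m3 of evapotranspired
water as sowing is delayed. `05` then reports the factorial changes, e.g.
for early sowing (ensemble-mean member):

```
 co2_only  RCP4.5-2050: +29.7 %   (fertilization alone raises yield)
  cc_only  RCP8.5-2090: -30.6 %   (warming alone: shorter cycle, less biomass)
     cco2  RCP8.5-2090: +49.0 %   (CO2 offsets the climate penalty)
irrigation peak month, early sowing: historical 3 -> RCP8.5-2090 2
```

Season length shrinks monotonically with warming (-9% to -29% across the
presets), water requirements fall by 11-30%, and the irrigation peak
advances from March to February under the strongest scenario.

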