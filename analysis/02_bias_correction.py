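#!/usr/bin/env python
"""Fit the seasonal quantile-quantile correction of the pseudo-RCM series
against the synthetic observations and verify that it removes the bias.

Reads the CSVs written by 01_generate_climate.py, writes the fitted
correction nodes and the corrected series, and prints before/after
seasonal-mean biases.
"""

import argparse
from pathlib import Path

import numpy as np

from aridwheat.qmap import SEASONS, apply_qq, fit_qq, maps_to_frame, seasonal_partition
from aridwheat.weather import DailyWeatherSeries

ap = argparse.ArgumentParser()
ap.add_argument("--climate-dir", type=Path, default=Path("scratch/climate"))
ap.add_argument("--out", type=Path, default=Path("results/bias_correction"))
ap.add_argument("--scratch", type=Path, default=Path("scratch/bias_correction"),
                help="directory for the bulky corrected daily series")
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)
args.scratch.mkdir(parents=True, exist_ok=True)

obs = DailyWeatherSeries.read_csv(args.climate_dir / "baseline_weather.csv")
model = DailyWeatherSeries.read_csv(args.climate_dir / "pseudo_rcm_weather.csv")

maps = fit_qq(obs, model)
corrected = apply_qq(maps, model)
maps_to_frame(maps).to_csv(
    args.out / "quantile_maps.csv", index=False, float_format="%.6g"
)
corrected.to_csv(args.scratch / "corrected_weather.csv")

masks = seasonal_partition(obs)
print("seasonal Tmax bias (model - obs) before -> after correction:")
for season in SEASONS:
    m = masks[season]
    raw = model.tmax[m].mean() - obs.tmax[m].mean()
    cor = corrected.tmax[m].mean() - obs.tmax[m].mean()
    print(f"  {season}: {raw:+6.2f} -> {cor:+8.4f} degC")
print("seasonal precipitation ratio (model/obs) before -> after:")
for season in SEASONS:
    m = masks[season]
    denom = obs.precip[m].sum()
    if denom == 0:
        continue
    raw = model.precip[m].sum() / denom
    cor = corrected.precip[m].sum() / denom
    print(f"  {season}: {raw:6.2f} -> {cor:6.3f}")
err = max(
    np.abs(
        np.percentile(corrected.tmax[masks[s]], np.arange(1, 100))
        - np.percentile(obs.tmax[masks[s]], np.arange(1, 100))
    ).max()
    for s in SEASONS
)
print(f"max seasonal percentile error after correction: {err:.2e} degC")
print(f"wrote {args.out}/quantile_maps.csv and {args.scratch}/corrected_weather.csv")
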