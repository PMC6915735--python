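"""Seasonal empirical quantile-quantile bias correction.

Regional climate model output carries systematic biases relative to station
observations.  The correction used here is the classic empirical quantile
mapping: for each weather variable and each three-month season
(JFM, AMJ, JAS, OND), the 99 percentiles of the daily model series plus the
minimum and maximum (101 nodes in total) are matched to the corresponding
nodes of the observed series.  A model value falling between two nodes is
corrected by linear interpolation; values beyond the min/max nodes are
shifted by the constant offset at the nearest endpoint, which keeps the
mapping monotone and bounded in the tails.

Percentiles are estimated by linear interpolation between order statistics
(the common "type 7" definition), identically for both sides, so that
fitting a series against itself yields the identity map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .weather import DailyWeatherSeries

__all__ = [
    "SEASONS",
    "MONTH_TO_SEASON",
    "QuantileMap",
    "season_of_months",
    "seasonal_partition",
    "fit_qq",
    "apply_qq",
    "correct_series",
    "maps_to_frame",
    "maps_from_frame",
]

#: season labels in calendar order; each season is a block of three months
SEASONS: tuple[str, ...] = ("JFM", "AMJ", "JAS", "OND")

#: month number (1..12) -> season label
MONTH_TO_SEASON: dict[int, str] = {
    1: "JFM", 2: "JFM", 3: "JFM",
    4: "AMJ", 5: "AMJ", 6: "AMJ",
    7: "JAS", 8: "JAS", 9: "JAS",
    10: "OND", 11: "OND", 12: "OND",
}

_SEASON_MONTHS: dict[str, tuple[int, int, int]] = {
    "JFM": (1, 2, 3),
    "AMJ": (4, 5, 6),
    "JAS": (7, 8, 9),
    "OND": (10, 11, 12),
}

VARIABLES: tuple[str, ...] = ("tmin", "tmax", "precip")

#: percentile levels of the 101 correction nodes: min, 1..99, max
NODE_PERCENTILES: np.ndarray = np.concatenate(
    ([0.0], np.arange(1.0, 100.0), [100.0])
)


@dataclass(frozen=True)
class QuantileMap:
    """Empirical correction function for one (variable, season) pair.

    ``model_nodes`` and ``obs_nodes`` each hold 101 values: the minimum,
    percentiles 1-99 and the maximum of the daily series in that season.
    """

    variable: str
    season: str
    model_nodes: np.ndarray
    obs_nodes: np.ndarray

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ConfigurationError(f"unknown variable {self.variable!r}")
        if self.season not in SEASONS:
            raise ConfigurationError(f"unknown season {self.season!r}")
        m = np.asarray(self.model_nodes, dtype=float)
        o = np.asarray(self.obs_nodes, dtype=float)
        if m.shape != (101,) or o.shape != (101,):
            raise DataError("quantile maps need exactly 101 nodes per side")
        if np.any(np.diff(m) < 0) or np.any(np.diff(o) < 0):
            raise DataError("quantile-map nodes must be non-decreasing")
        object.__setattr__(self, "model_nodes", m)
        object.__setattr__(self, "obs_nodes", o)

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Correct values by node interpolation with constant-offset tails."""
        x = np.asarray(values, dtype=float)
        m, o = self.model_nodes, self.obs_nodes
        out = np.interp(x, m, o)
        # np.interp is flat beyond the endpoints; replace with offset extension
        low = x < m[0]
        high = x > m[-1]
        if np.any(low):
            out[low] = o[0] + (x[low] - m[0])
        if np.any(high):
            out[high] = o[-1] + (x[high] - m[-1])
        if self.variable == "precip":
            out = np.maximum(out, 0.0)
        return out


def season_of_months(months: np.ndarray) -> np.ndarray:
    """Vector of season labels for a vector of month numbers."""
    lut = np.empty(13, dtype="<U3")
    for m, s in MONTH_TO_SEASON.items():
        lut[m] = s
    return lut[np.asarray(months, dtype=int)]


def seasonal_partition(
    series: DailyWeatherSeries,
) -> dict[str, np.ndarray]:
    """Boolean day masks assigning every day to exactly one season.

    The masks are disjoint and their union covers the whole series, so the
    four sub-series reconstruct the input exactly.
    """
    months = series.months
    return {
        s: np.isin(months, _SEASON_MONTHS[s]) for s in SEASONS
    }


def _nodes(values: np.ndarray) -> np.ndarray:
    return np.percentile(values, NODE_PERCENTILES)


def fit_qq(
    obs: DailyWeatherSeries,
    model_hist: DailyWeatherSeries,
    variables: Iterable[str] = VARIABLES,
    seasons: Iterable[str] = SEASONS,
) -> dict[tuple[str, str], QuantileMap]:
    """Fit one :class:`QuantileMap` per (variable, season).

    Both series should cover the same historical window; each requested
    season must be non-empty in both.  Precipitation is fitted on all days,
    dry days included.
    """
    obs_masks = seasonal_partition(obs)
    mod_masks = seasonal_partition(model_hist)
    maps: dict[tuple[str, str], QuantileMap] = {}
    for var in variables:
        if var not in VARIABLES:
            raise ConfigurationError(f"unknown variable {var!r}")
        obs_vals = getattr(obs, var)
        mod_vals = getattr(model_hist, var)
        for season in seasons:
            om = obs_masks[season]
            mm = mod_masks[season]
            if not om.any() or not mm.any():
                raise DataError(f"season {season} empty in obs or model series")
            maps[(var, season)] = QuantileMap(
                variable=var,
                season=season,
                model_nodes=_nodes(mod_vals[mm]),
                obs_nodes=_nodes(obs_vals[om]),
            )
    return maps


def apply_qq(
    maps: Mapping[tuple[str, str], QuantileMap],
    series: DailyWeatherSeries,
    variables: Iterable[str] = VARIABLES,
) -> DailyWeatherSeries:
    """Correct a series with previously fitted maps, season by season.

    Raises :class:`ConfigurationError` if a needed (variable, season) map is
    missing.  The two temperatures are corrected independently, then
    ``tmin <= tmax`` is re-enforced by raising ``tmax`` to ``tmin`` where
    violated; this is rare because both maps are monotone.
    """
    corrected, _ = _apply_qq_counted(maps, series, variables)
    return corrected


def _apply_qq_counted(
    maps: Mapping[tuple[str, str], QuantileMap],
    series: DailyWeatherSeries,
    variables: Iterable[str] = VARIABLES,
) -> tuple[DailyWeatherSeries, int]:
    masks = seasonal_partition(series)
    new: dict[str, np.ndarray] = {}
    for var in variables:
        vals = getattr(series, var).copy()
        for season in SEASONS:
            mask = masks[season]
            if not mask.any():
                continue
            key = (var, season)
            if key not in maps:
                raise ConfigurationError(f"no quantile map for {key}")
            vals[mask] = maps[key].apply(vals[mask])
        new[var] = vals
    tmin = new.get("tmin", series.tmin)
    tmax = new.get("tmax", series.tmax)
    bad = tmin > tmax
    n_clamped = int(bad.sum())
    if n_clamped:
        tmax = np.where(bad, tmin, tmax)
    out = DailyWeatherSeries(
        dates=series.dates,
        tmin=tmin,
        tmax=tmax,
        precip=new.get("precip", series.precip),
    )
    return out, n_clamped


def correct_series(
    obs: DailyWeatherSeries,
    model_hist: DailyWeatherSeries,
    model_target: DailyWeatherSeries,
) -> DailyWeatherSeries:
    """Fit on the historical pair, apply to a (possibly future) model series."""
    return apply_qq(fit_qq(obs, model_hist), model_target)


# -- serialization -----------------------------------------------------------

def maps_to_frame(maps: Mapping[tuple[str, str], QuantileMap]) -> pd.DataFrame:
    """Flatten maps to a table: variable, season, node_index, model/obs value."""
    rows = []
    for (var, season), qm in sorted(maps.items()):
        for i in range(101):
            rows.append((var, season, i, qm.model_nodes[i], qm.obs_nodes[i]))
    return pd.DataFrame(
        rows, columns=["variable", "season", "node_index", "model_value", "obs_value"]
    )


def maps_from_frame(df: pd.DataFrame) -> dict[tuple[str, str], QuantileMap]:
    maps: dict[tuple[str, str], QuantileMap] = {}
    for (var, season), grp in df.groupby(["variable", "season"], sort=False):
        grp = grp.sort_values("node_index")
        maps[(var, season)] = QuantileMap(
            variable=var,
            season=season,
            model_nodes=grp["model_value"].to_numpy(),
            obs_nodes=grp["obs_value"].to_numpy(),
        )
    return maps
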