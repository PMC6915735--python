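"""Degree-day wheat phenology: thermal-time accumulation, calibration of
stage thresholds from observed calendar durations, and projection of stage
durations under altered climates.

Crop development is driven by cumulative growing degree days (GDD) above a
base temperature, computed with the mean-temperature method: the daily mean
(Tmin+Tmax)/2 is clipped to [tbase, tupper] and tbase subtracted.  The four
stage boundaries tracked are emergence, maximum canopy cover, onset of
senescence and maturity; sowing-to-maturity is the length of the crop
season (LCS).

Because thermal thresholds for a local cultivar are usually unknown while
its calendar-day stage durations are, :func:`calibrate_gdd_thresholds`
inverts the relationship on a baseline climatology: the GDD accumulated
from sowing to each observed stage boundary, averaged over the baseline
years, becomes the threshold.  Re-projecting on the same climatology
returns the observed durations (to within a day of discretization), and
projecting on a warmed series quantifies the shortening of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, SimulationError
from .weather import DailyWeatherSeries

__all__ = [
    "CropCalendar",
    "StageDurations",
    "SOWING_DATES",
    "STAGE_DURATION_TARGETS",
    "daily_gdd",
    "cumulative_degree_days",
    "calibrate_gdd_thresholds",
    "project_stage_durations",
    "season_starts",
]

#: conventional sowing dates in the study region (month, day)
SOWING_DATES: dict[str, tuple[int, int]] = {
    "early": (11, 15),
    "intermediate": (12, 15),
    "late": (1, 15),
}

#: observed year-2000 stage durations (days after sowing) per sowing date:
#: emergence, maximum canopy cover, start of senescence, maturity (= LCS)
STAGE_DURATION_TARGETS: dict[str, tuple[int, int, int, int]] = {
    "early": (7, 83, 112, 152),
    "intermediate": (9, 83, 106, 141),
    "late": (11, 72, 93, 125),
}

#: default cardinal temperatures for wheat (degC)
TBASE_DEFAULT = 0.0
TUPPER_DEFAULT = 26.0


@dataclass(frozen=True)
class StageDurations:
    """Stage boundaries in days after sowing; ``maturity`` is the LCS."""

    emergence: float
    max_canopy: float
    senescence_start: float
    maturity: float

    def __post_init__(self) -> None:
        seq = (self.emergence, self.max_canopy, self.senescence_start, self.maturity)
        if not all(b > a for a, b in zip(seq, seq[1:])):
            raise DataError(f"stage durations must be strictly increasing: {seq}")

    @property
    def lcs(self) -> float:
        return self.maturity

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.emergence, self.max_canopy, self.senescence_start, self.maturity)


@dataclass(frozen=True)
class CropCalendar:
    """Sowing date plus GDD thresholds of the four stage boundaries."""

    sowing_month: int
    sowing_day: int
    gdd_emergence: float
    gdd_max_canopy: float
    gdd_senescence: float
    gdd_maturity: float
    tbase: float = TBASE_DEFAULT
    tupper: float = TUPPER_DEFAULT

    def __post_init__(self) -> None:
        thresholds = (
            self.gdd_emergence,
            self.gdd_max_canopy,
            self.gdd_senescence,
            self.gdd_maturity,
        )
        if not (0 < thresholds[0] < thresholds[1] < thresholds[2] < thresholds[3]):
            raise DataError(
                f"GDD thresholds must be positive and strictly increasing: {thresholds}"
            )
        if self.tbase >= self.tupper:
            raise ParameterError("tbase must be below tupper")

    def thresholds(self) -> tuple[float, float, float, float]:
        return (
            self.gdd_emergence,
            self.gdd_max_canopy,
            self.gdd_senescence,
            self.gdd_maturity,
        )


def daily_gdd(tmin, tmax, tbase: float = TBASE_DEFAULT, tupper: float = TUPPER_DEFAULT):
    """Growing degree days of one day (mean method, both cutoffs).

    Vectorized over ``tmin``/``tmax``; returns values in [0, tupper - tbase].
    """
    if tbase >= tupper:
        raise ParameterError("tbase must be below tupper")
    tavg = (np.asarray(tmin, dtype=float) + np.asarray(tmax, dtype=float)) / 2.0
    return np.clip(tavg, tbase, tupper) - tbase


def cumulative_degree_days(
    series: DailyWeatherSeries,
    start,
    end,
    tbase: float = TBASE_DEFAULT,
    tupper: float = TUPPER_DEFAULT,
) -> float:
    """GDD accumulated over the half-open date window [start, end).

    Additive over adjacent windows by construction.
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if end < start:
        raise DataError("window end precedes start")
    if start == end:
        return 0.0
    if start < series.dates[0] or end > series.dates[-1] + pd.Timedelta(days=1):
        raise DataError("degree-day window extends outside the series")
    mask = (series.dates >= start) & (series.dates < end)
    return float(daily_gdd(series.tmin[mask], series.tmax[mask], tbase, tupper).sum())


def season_starts(
    series: DailyWeatherSeries,
    sowing_month: int,
    sowing_day: int,
    min_tail_days: int = 260,
) -> list[pd.Timestamp]:
    """All sowing dates inside the series followed by at least
    ``min_tail_days`` of data (so a full season can be evaluated)."""
    last = series.dates[-1]
    starts = []
    for year in np.unique(series.years):
        try:
            d = pd.Timestamp(year=int(year), month=sowing_month, day=sowing_day)
        except ValueError:  # pragma: no cover - (11,31)-style configs
            raise ParameterError(
                f"invalid sowing date {sowing_month:02d}-{sowing_day:02d}"
            )
        if d >= series.dates[0] and d + pd.Timedelta(days=min_tail_days) <= last:
            starts.append(d)
    if not starts:
        raise DataError("series too short for a single crop season")
    return starts


def calibrate_gdd_thresholds(
    baseline: DailyWeatherSeries,
    sowing_month: int,
    sowing_day: int,
    target: StageDurations,
    tbase: float = TBASE_DEFAULT,
    tupper: float = TUPPER_DEFAULT,
) -> CropCalendar:
    """Thresholds = GDD from sowing to each target boundary, averaged over
    all complete baseline seasons."""
    tgt = target.as_tuple()
    if any(d != int(d) or d < 1 for d in tgt):
        raise DataError("target stage durations must be positive whole days")
    starts = season_starts(
        baseline, sowing_month, sowing_day, min_tail_days=int(tgt[-1]) + 5
    )
    sums = np.zeros(4)
    for s in starts:
        for i, d in enumerate(tgt):
            sums[i] += cumulative_degree_days(
                baseline, s, s + pd.Timedelta(days=int(d)), tbase, tupper
            )
    means = sums / len(starts)
    return CropCalendar(
        sowing_month=sowing_month,
        sowing_day=sowing_day,
        gdd_emergence=means[0],
        gdd_max_canopy=means[1],
        gdd_senescence=means[2],
        gdd_maturity=means[3],
        tbase=tbase,
        tupper=tupper,
    )


def _project_one_season(
    series: DailyWeatherSeries, calendar: CropCalendar, sowing: pd.Timestamp
) -> StageDurations:
    i0 = int(np.searchsorted(series.dates, sowing))
    if i0 >= len(series) or series.dates[i0] != sowing:
        raise DataError(f"sowing date {sowing.date()} not in series")
    gdd = daily_gdd(series.tmin[i0:], series.tmax[i0:], calendar.tbase, calendar.tupper)
    cum = np.cumsum(gdd)
    days = []
    for thr in calendar.thresholds():
        idx = int(np.searchsorted(cum, thr))
        if idx >= len(cum):
            raise SimulationError(
                f"maturity threshold {thr:.0f} GDD not reached within the series "
                f"(accumulated {cum[-1]:.0f} GDD after {len(cum)} days "
                f"from {sowing.date()})"
            )
        days.append(idx + 1)  # duration in days after sowing (day 1 = sowing day)
    # discretization can tie adjacent boundaries; nudge to keep them increasing
    for i in range(1, 4):
        if days[i] <= days[i - 1]:
            days[i] = days[i - 1] + 1
    return StageDurations(*[float(d) for d in days])


def project_stage_durations(
    series: DailyWeatherSeries,
    calendar: CropCalendar,
    sowing: pd.Timestamp | None = None,
) -> StageDurations:
    """Stage durations implied by a calendar on a weather series.

    With ``sowing`` given, one season is projected.  Otherwise every
    complete season in the series is projected and the durations averaged
    (climatological-mean durations).
    """
    if sowing is not None:
        return _project_one_season(series, calendar, pd.Timestamp(sowing))
    starts = season_starts(series, calendar.sowing_month, calendar.sowing_day)
    per = np.array(
        [_project_one_season(series, calendar, s).as_tuple() for s in starts]
    )
    return StageDurations(*per.mean(axis=0))
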