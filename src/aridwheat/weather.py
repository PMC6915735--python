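"""Daily weather series: the currency passed between every pipeline stage.

A :class:`DailyWeatherSeries` is a thin, validated wrapper around four aligned
arrays (calendar dates, minimum and maximum air temperature in degC,
precipitation in mm/day).  All downstream stages -- bias correction,
reference evapotranspiration, phenology and the crop simulation -- consume
and produce this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["DailyWeatherSeries"]


@dataclass(frozen=True)
class DailyWeatherSeries:
    """Contiguous daily record of Tmin, Tmax (degC) and precipitation (mm/day).

    Invariants (checked on construction):

    * dates strictly increasing, no calendar gaps;
    * ``tmin <= tmax`` on every day;
    * ``precip >= 0`` on every day.
    """

    dates: pd.DatetimeIndex
    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray
    #: months as 1..12, cached for seasonal grouping
    months: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        tmin = np.asarray(self.tmin, dtype=float)
        tmax = np.asarray(self.tmax, dtype=float)
        precip = np.asarray(self.precip, dtype=float)
        n = len(dates)
        if not (len(tmin) == len(tmax) == len(precip) == n):
            raise DataError("dates, tmin, tmax and precip must have equal length")
        if n > 1:
            step = np.diff(dates.values.astype("datetime64[D]").astype(int))
            if not np.all(step == 1):
                raise DataError("dates must be contiguous calendar days")
        if np.any(tmin > tmax):
            k = int(np.argmax(tmin > tmax))
            raise DataError(
                f"tmin > tmax on {dates[k].date()} ({tmin[k]:.2f} > {tmax[k]:.2f})"
            )
        if np.any(precip < 0):
            raise DataError("precipitation must be non-negative")
        if np.any(~np.isfinite(tmin)) or np.any(~np.isfinite(tmax)) or np.any(
            ~np.isfinite(precip)
        ):
            raise DataError("weather values must be finite")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "tmin", tmin)
        object.__setattr__(self, "tmax", tmax)
        object.__setattr__(self, "precip", precip)
        object.__setattr__(self, "months", dates.month.to_numpy())

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def years(self) -> np.ndarray:
        return self.dates.year.to_numpy()

    @property
    def day_of_year(self) -> np.ndarray:
        return self.dates.dayofyear.to_numpy()

    def replace(
        self,
        tmin: np.ndarray | None = None,
        tmax: np.ndarray | None = None,
        precip: np.ndarray | None = None,
    ) -> "DailyWeatherSeries":
        """Return a copy with one or more variables substituted (revalidated)."""
        return DailyWeatherSeries(
            dates=self.dates,
            tmin=self.tmin if tmin is None else tmin,
            tmax=self.tmax if tmax is None else tmax,
            precip=self.precip if precip is None else precip,
        )

    def window(self, start, end) -> "DailyWeatherSeries":
        """Sub-series on the half-open date window [start, end)."""
        start = pd.Timestamp(start)
        end = pd.Timestamp(end)
        mask = (self.dates >= start) & (self.dates < end)
        if end > self.dates[-1] + pd.Timedelta(days=1) or start < self.dates[0]:
            raise DataError(
                f"window [{start.date()}, {end.date()}) outside series "
                f"[{self.dates[0].date()}, {self.dates[-1].date()}]"
            )
        return DailyWeatherSeries(
            dates=self.dates[mask],
            tmin=self.tmin[mask],
            tmax=self.tmax[mask],
            precip=self.precip[mask],
        )

    # -- tabular interchange -------------------------------------------------

    def to_frame(self, et0: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "date": self.dates,
                "tmin": self.tmin,
                "tmax": self.tmax,
                "precip": self.precip,
            }
        )
        if et0 is not None:
            df["et0"] = np.asarray(et0, dtype=float)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DailyWeatherSeries":
        return cls(
            dates=pd.DatetimeIndex(pd.to_datetime(df["date"])),
            tmin=df["tmin"].to_numpy(dtype=float),
            tmax=df["tmax"].to_numpy(dtype=float),
            precip=df["precip"].to_numpy(dtype=float),
        )

    def to_csv(self, path, et0: np.ndarray | None = None) -> None:
        """Write ``date,tmin,tmax,precip[,et0]`` with ISO-8601 dates."""
        df = self.to_frame(et0=et0)
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "DailyWeatherSeries":
        return cls.from_frame(pd.read_csv(path))
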