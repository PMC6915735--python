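"""Temperature-only reference evapotranspiration (Hargreaves-Samani).

The pipeline needs daily ET0 but the only available weather variables are
Tmin, Tmax and precipitation, so ET0 is estimated with the
Hargreaves-Samani formula

    ET0 = 0.0023 * (Tmean + 17.8) * sqrt(Tmax - Tmin) * (0.408 * Ra)

where Ra is extraterrestrial radiation (MJ m-2 day-1) from the standard
FAO-56 astronomy: a deterministic function of latitude and day of year.
The 0.408 factor converts Ra to equivalent evaporation (mm/day).  Negative
(Tmean + 17.8) is clamped to zero ET0 -- physically forced and irrelevant
for warm climates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .weather import DailyWeatherSeries

__all__ = [
    "SiteGeometry",
    "extraterrestrial_radiation",
    "sunset_hour_angle",
    "hargreaves_et0",
    "seasonal_et0",
]

#: solar constant, MJ m-2 min-1 (FAO-56)
SOLAR_CONSTANT = 0.0820


@dataclass(frozen=True)
class SiteGeometry:
    """Site location; latitude in decimal degrees, positive north.

    Restricted to [-66, 66] where the sunset-hour-angle formula is valid
    (no polar day/night).
    """

    latitude: float = 31.5

    def __post_init__(self) -> None:
        if not (-66.0 <= self.latitude <= 66.0):
            raise ParameterError("latitude must lie in [-66, 66] degrees")


def _solar_declination(day_of_year: int) -> float:
    return 0.409 * math.sin(2.0 * math.pi * day_of_year / 365.0 - 1.39)


def sunset_hour_angle(latitude_deg: float, day_of_year: int) -> float:
    """Sunset hour angle (radians) for a latitude and day of year."""
    phi = math.radians(latitude_deg)
    delta = _solar_declination(day_of_year)
    return math.acos(-math.tan(phi) * math.tan(delta))


def extraterrestrial_radiation(site: SiteGeometry, day_of_year: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ m-2 day-1), FAO-56.

    Uses the inverse relative Earth-Sun distance and solar declination
    approximations; smooth and strictly positive away from polar latitudes.
    """
    if not (1 <= day_of_year <= 366):
        raise ParameterError("day_of_year must lie in [1, 366]")
    j = int(day_of_year)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * j / 365.0)
    delta = _solar_declination(j)
    phi = math.radians(site.latitude)
    ws = math.acos(-math.tan(phi) * math.tan(delta))
    ra = (
        24.0 * 60.0 / math.pi
        * SOLAR_CONSTANT
        * dr
        * (
            ws * math.sin(phi) * math.sin(delta)
            + math.cos(phi) * math.cos(delta) * math.sin(ws)
        )
    )
    return ra


_RA_CACHE: dict[float, np.ndarray] = {}


def _ra_table(latitude: float) -> np.ndarray:
    """Ra for day-of-year 1..366 at one latitude, computed once and cached."""
    tab = _RA_CACHE.get(latitude)
    if tab is None:
        site = SiteGeometry(latitude)
        tab = np.array(
            [extraterrestrial_radiation(site, j) for j in range(1, 367)]
        )
        _RA_CACHE[latitude] = tab
    return tab


def hargreaves_et0(tmin: float, tmax: float, ra: float) -> float:
    """Daily reference evapotranspiration (mm/day) from temperatures and Ra."""
    if tmin > tmax:
        raise DataError(f"tmin ({tmin}) exceeds tmax ({tmax})")
    tmean = (tmin + tmax) / 2.0
    base = 0.0023 * (tmean + 17.8) * math.sqrt(tmax - tmin) * (0.408 * ra)
    return max(base, 0.0)


def seasonal_et0(series: DailyWeatherSeries, site: SiteGeometry) -> np.ndarray:
    """Daily ET0 series (mm/day) aligned with the weather series."""
    ra = _ra_table(site.latitude)[series.day_of_year - 1]
    tmean = (series.tmin + series.tmax) / 2.0
    rng = np.sqrt(series.tmax - series.tmin)
    et0 = 0.0023 * (tmean + 17.8) * rng * (0.408 * ra)
    return np.maximum(et0, 0.0)
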