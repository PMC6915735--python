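import numpy as np
import pandas as pd
import pytest

from aridwheat.atmosphere import SiteGeometry, seasonal_et0
from aridwheat.crop import tensift_soil, tensift_wheat
from aridwheat.phenology import (
    SOWING_DATES,
    STAGE_DURATION_TARGETS,
    StageDurations,
    calibrate_gdd_thresholds,
)
from aridwheat.synthetic import generate_baseline_weather, marrakech_climatology


@pytest.fixture(scope="session")
def clim():
    return marrakech_climatology()


@pytest.fixture(scope="session")
def baseline20(clim):
    """20 years of default synthetic station weather (the study window)."""
    return generate_baseline_weather(clim, n_years=20, seed=1, start_year=1991)


@pytest.fixture(scope="session")
def site(clim):
    return SiteGeometry(clim.latitude)


@pytest.fixture(scope="session")
def et0_20(baseline20, site):
    return seasonal_et0(baseline20, site)


@pytest.fixture(scope="session")
def soil():
    return tensift_soil()


@pytest.fixture(scope="session")
def calendars(baseline20):
    """GDD calendars calibrated to the observed stage durations per sowing."""
    out = {}
    for sowing, (m, d) in SOWING_DATES.items():
        out[sowing] = calibrate_gdd_thresholds(
            baseline20, m, d, StageDurations(*STAGE_DURATION_TARGETS[sowing])
        )
    return out


@pytest.fixture(scope="session")
def crops(calendars):
    return {s: tensift_wheat(cal) for s, cal in calendars.items()}


def constant_series(n_days, tmin, tmax, precip=0.0, start="2000-11-01"):
    dates = pd.date_range(start, periods=n_days, freq="D")
    return dates, np.full(n_days, float(tmin)), np.full(n_days, float(tmax)), np.full(
        n_days, float(precip)
    )
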