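import numpy as np
import pandas as pd
import pytest

from batdyn.synthetic import ScenarioConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """Full 42-year synthetic study under the default scenario truth."""
    return generate_study(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def small_study():
    """Shorter 30-year study used by IO/CLI tests to keep them quick."""
    return generate_study(ScenarioConfig(seed=5, year_end=2006))


def _mild_year(first_year: int = 2000, tmax: float = 10.0) -> pd.DataFrame:
    """A 1 Jul - 30 Jun frame of uniformly mild, snow-free days."""
    dates = pd.date_range(f"{first_year}-07-01", f"{first_year + 1}-06-30", freq="D")
    return pd.DataFrame(
        {
            "date": dates,
            "tmax": tmax,
            "tmin": tmax - 8.0,
            "tavg": tmax - 4.0,
            "prcp": 0.0,
            "snwd": 0.0,
        }
    )


@pytest.fixture
def mild_year():
    return _mild_year()


@pytest.fixture
def hand_scored_week():
    """Seven winter days scored by hand against the default point tables.

    Per-day points (temperature + snow), worked from the banded tables:
      day1 (1,-2, snow 0, depth 0):   0+1         = 1
      day2 (-1,-5, fall 2, depth 2):  1+2+1+0     = 4
      day3 (-7,-13, fall 0, depth 3): 3+5+0+1     = 9
      day4 (-10,-16, fall 5.2, d 8):  4+6+3+2     = 15
      day5 (0,-1, fall 0, depth 8):   1+1+0+2     = 4
      day6 (3,-1, fall 0, depth 5):   0+1+0+1     = 2
      day7 (5,1, fall 0, depth 0):    0           = 0
    """
    dates = pd.date_range("2001-01-01", periods=7, freq="D")
    tmax = [1.0, -1.0, -7.0, -10.0, 0.0, 3.0, 5.0]
    tmin = [-2.0, -5.0, -13.0, -16.0, -1.0, -1.0, 1.0]
    frame = pd.DataFrame(
        {
            "date": dates,
            "tmax": tmax,
            "tmin": tmin,
            "tavg": [(a + b) / 2 for a, b in zip(tmax, tmin)],
            "prcp": 0.0,
            "snowfall": [0.0, 2.0, 0.0, 5.2, 0.0, 0.0, 0.0],
            "snwd": [0.0, 2.0, 3.0, 8.0, 8.0, 5.0, 0.0],
        }
    )
    daily_points = np.array([1, 4, 9, 15, 4, 2, 0], dtype=float)
    return frame, daily_points
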