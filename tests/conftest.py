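import numpy as np
import pandas as pd
import pytest

from ricetrend.simulate import WeatherScenario, synth_weather
from ricetrend.weather import aggregate_seasons, impute


@pytest.fixture(scope="session")
def short_seasonal_climate():
    """Seasonal climate from a missing-free 12-year synthetic record."""
    wx = synth_weather(WeatherScenario(start_year=2001, end_year=2012,
                                       missing_rate=0.0, seed=42))
    clean, report = impute(wx)
    return aggregate_seasons(clean, report=report)


@pytest.fixture(scope="session")
def long_seasonal_climate():
    """Seasonal climate over a 91-year missing-free synthetic record
    (used by the parameter-recovery simulations)."""
    wx = synth_weather(WeatherScenario(start_year=1929, end_year=2019,
                                       missing_rate=0.0, seed=7))
    clean, report = impute(wx)
    return aggregate_seasons(clean, report=report)


def toy_daily_frame(years, base=20.0, year_offsets=None):
    """Deterministic daily weather: smooth annual cycle plus a small
    per-year offset, so day-of-year climatologies have tiny but nonzero
    spread and hand-computed neighbor means are exact."""
    frames = []
    for i, y in enumerate(years):
        dates = pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D")
        doy = dates.dayofyear.to_numpy(float)
        off = (year_offsets[i] if year_offsets is not None else 0.1 * i)
        tavg = base + 3.0 * np.sin(2 * np.pi * doy / 365.25) + off
        frames.append(pd.DataFrame({
            "date": dates,
            "tavg": tavg,
            "tmin": tavg - 4.0,
            "tmax": tavg + 4.0,
            "rain": 1.0 + 0.01 * (doy % 7),
            "sunshine": 6.0 + 0.02 * (doy % 5),
        }))
    return pd.concat(frames, ignore_index=True)
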