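"""Synthetic daily weather and cultivar yield generators.

The generators produce data with *known* ground truth so that every
downstream stage — quality control, seasonal aggregation, trend fitting,
first-difference regression, grouping and projection — can be verified
without any external download.

The weather generator emulates a subtropical lowland station record of
the kind kept at long-running agronomic research farms: a ~95-year daily
series with the warming trend concentrated in the minimum temperature
(hence a shrinking diurnal temperature range), slowly declining rainfall
and sunshine totals, day-to-day AR(1) temperature anomalies, a
Bernoulli–Gamma rainfall mixture, and a small fraction of wholly missing
days.  The yield generator is the exact inverse of the first-difference
regression model: yearly yield is linear in the seasonal climate
variables plus an additive technology trend and Gaussian noise, with
gap years absent (never zero).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError, CoverageError

__all__ = [
    "WeatherScenario",
    "CultivarSpec",
    "YieldScenario",
    "synth_weather",
    "synth_yields",
    "make_fixture",
    "Fixture",
    "FIXTURE_NAMES",
    "WEATHER_COLUMNS",
    "YIELD_COLUMNS",
]

WEATHER_COLUMNS = ["date", "tavg", "tmin", "tmax", "rain", "sunshine"]
YIELD_COLUMNS = ["cultivar", "season", "year", "yield"]

#: Days per year used when converting annual-total trends to daily terms.
_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class WeatherScenario:
    """Parameters of the stochastic daily weather generator.

    Defaults describe the study conditions the package targets: a
    95-year (1925–2019) subtropical station series whose minimum
    temperature warms much faster than its maximum (total warming of
    order 1 °C), with declining rainfall and sunshine and 2.65 % of
    days missing.

    Parameters
    ----------
    start_year, end_year : int
        Inclusive calendar span of the series.
    baseline_tavg : float
        Annual-mean daily average temperature at ``start_year`` (°C).
    seasonal_amplitude : float
        Half-range of the annual temperature cycle (°C).
    baseline_dtr : float
        Mean diurnal temperature range at ``start_year`` (°C).
    trend_tmin, trend_tmax : float
        Linear trends of minimum/maximum temperature (°C per year);
        their mean drives the average-temperature trend and their
        difference drives the DTR trend.
    ar1_coeff : float
        Day-to-day AR(1) coefficient of the temperature anomaly,
        in [0, 1).
    anomaly_sd : float
        Stationary standard deviation of the temperature anomaly (°C).
    dtr_anomaly_sd : float
        Daily noise SD of the diurnal range (°C).
    tavg_year_sd : float
        SD of a year-level temperature anomaly (°C): daily noise alone
        averages out over a season, so interannual spread needs a
        year-scale term.
    dtr_year_sd : float
        SD of the year-level diurnal-range anomaly (°C).
    rain_year_sd : float
        Lognormal sigma of a year-level wetness factor multiplying the
        Gamma scale (mean-one, so trends are preserved).
    sunshine_year_sd : float
        Year-level sunshine anomaly per daily hour (h); driven by the
        *same* wetness draw with opposite sign, so wet years are dull
        years — the rain–sunshine anticorrelation seen in station data.
    rain_prob : float
        Probability that a day is wet.
    rain_gamma_shape, rain_gamma_scale : float
        Gamma parameters of wet-day rainfall (mm).
    rain_trend : float
        Trend of the *annual total* rainfall (mm per year), applied
        through a drifting Gamma scale.
    sunshine_max : float
        Dry-day sunshine duration at the daylight peak (h), net of the
        partial cloudiness a binary wet/dry process cannot express.
    sunshine_rain_penalty : float
        Sunshine hours lost on a wet day (h).
    sunshine_trend : float
        Trend of the annual total sunshine duration (h per year).
    sunshine_noise_sd : float
        Daily sunshine noise SD (h).
    missing_rate : float
        Fraction of days whose record is wholly absent, in [0, 1).
    seed : int
        Seed of the generator's private RNG.
    """

    start_year: int = 1925
    end_year: int = 2019
    baseline_tavg: float = 22.4
    seasonal_amplitude: float = 8.0
    baseline_dtr: float = 9.2
    trend_tmin: float = 0.016
    trend_tmax: float = 0.003
    ar1_coeff: float = 0.65
    anomaly_sd: float = 1.2
    dtr_anomaly_sd: float = 0.9
    tavg_year_sd: float = 0.5
    dtr_year_sd: float = 0.6
    rain_year_sd: float = 0.3
    sunshine_year_sd: float = 0.5
    rain_prob: float = 0.35
    rain_gamma_shape: float = 0.9
    rain_gamma_scale: float = 20.0
    rain_trend: float = -6.3
    sunshine_max: float = 7.2
    sunshine_rain_penalty: float = 3.0
    sunshine_trend: float = -3.5
    sunshine_noise_sd: float = 1.5
    missing_rate: float = 0.0265
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ConfigurationError(
                f"end_year {self.end_year} precedes start_year {self.start_year}"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError(f"missing_rate {self.missing_rate} not in [0, 1)")
        if not 0.0 <= self.rain_prob <= 1.0:
            raise ConfigurationError(f"rain_prob {self.rain_prob} not in [0, 1]")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ConfigurationError(f"ar1_coeff {self.ar1_coeff} not in [0, 1)")
        for name in ("anomaly_sd", "dtr_anomaly_sd", "sunshine_noise_sd",
                     "tavg_year_sd", "dtr_year_sd", "rain_year_sd",
                     "sunshine_year_sd", "rain_gamma_shape", "rain_gamma_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


def synth_weather(scenario: WeatherScenario) -> pd.DataFrame:
    """Generate one daily weather record per calendar day of the scenario.

    Returns a frame with columns ``date, tavg, tmin, tmax, rain,
    sunshine``; on missing days every value column is NaN (the day is
    flagged absent, never zeroed).  Identical scenarios produce
    identical output.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    dates = pd.date_range(
        f"{s.start_year}-01-01", f"{s.end_year}-12-31", freq="D"
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    years = (dates.year - s.start_year).to_numpy(dtype=float)
    yidx = years.astype(int)
    n_years = s.end_year - s.start_year + 1

    # Year-level anomalies (drawn first so the RNG stream is stable).
    z_t = rng.standard_normal(n_years)
    z_d = rng.standard_normal(n_years)
    z_wet = rng.standard_normal(n_years)
    year_t = (s.tavg_year_sd * z_t)[yidx]
    year_dtr = (s.dtr_year_sd * z_d)[yidx]
    wet_factor = np.exp(s.rain_year_sd * z_wet - 0.5 * s.rain_year_sd**2)[yidx]
    year_sun = (-s.sunshine_year_sd * z_wet)[yidx]

    # Annual cycle: coldest in mid-January for a northern subtropical site.
    cycle = -np.cos(2.0 * np.pi * (doy - 15.0) / _DAYS_PER_YEAR)
    trend_avg = 0.5 * (s.trend_tmin + s.trend_tmax) * years

    # AR(1) anomaly with stationary SD anomaly_sd; innovations are drawn
    # even when anomaly_sd == 0 so the RNG stream is stable across the
    # noise-free limit.
    innov = rng.standard_normal(n) * s.anomaly_sd * np.sqrt(1.0 - s.ar1_coeff**2)
    anomaly = lfilter([1.0], [1.0, -s.ar1_coeff], innov)

    tavg = (s.baseline_tavg + s.seasonal_amplitude * cycle + trend_avg
            + anomaly + year_t)

    dtr_noise = rng.standard_normal(n) * s.dtr_anomaly_sd
    dtr = (s.baseline_dtr + (s.trend_tmax - s.trend_tmin) * years
           + dtr_noise + year_dtr)
    dtr = np.clip(dtr, 0.2, None)
    tmin = tavg - dtr / 2.0
    tmax = tavg + dtr / 2.0

    wet = rng.random(n) < s.rain_prob
    # Drift the Gamma scale so the annual total trends by rain_trend mm/yr.
    if s.rain_prob > 0 and s.rain_gamma_shape > 0:
        per_day = s.rain_trend / (_DAYS_PER_YEAR * s.rain_prob * s.rain_gamma_shape)
    else:
        per_day = 0.0
    scale = np.clip(s.rain_gamma_scale + per_day * years, 0.0, None) * wet_factor
    rain = np.where(wet, rng.gamma(s.rain_gamma_shape, 1.0, size=n) * scale, 0.0)

    # Day length ~10.5–13.5 h at subtropical latitude; sunshine scales with
    # it, loses hours on wet days, and drifts by the prescribed trend.
    daylight = 12.0 + 1.5 * np.sin(2.0 * np.pi * (doy - 81.0) / _DAYS_PER_YEAR)
    sunshine = (
        s.sunshine_max * daylight / 13.5
        - s.sunshine_rain_penalty * wet
        + year_sun
        + s.sunshine_trend * years / _DAYS_PER_YEAR
        + rng.standard_normal(n) * s.sunshine_noise_sd
    )
    sunshine = np.clip(sunshine, 0.0, 24.0)

    df = pd.DataFrame(
        {
            "date": dates,
            "tavg": tavg,
            "tmin": tmin,
            "tmax": tmax,
            "rain": rain,
            "sunshine": sunshine,
        }
    )
    if s.missing_rate > 0:
        missing = rng.random(n) < s.missing_rate
        df.loc[missing, ["tavg", "tmin", "tmax", "rain", "sunshine"]] = np.nan
    return df


@dataclass(frozen=True)
class CultivarSpec:
    """Ground-truth yield model of one cultivar–season series.

    Yearly yield (kg/ha) is ``intercept + tech_trend*(year-first_year)
    + beta_T*T + beta_DTR*DTR + beta_R*R + beta_S*S + eps`` with
    ``eps ~ N(0, noise_sd)``.
    """

    id: str
    season: str
    first_year: int
    last_year: int
    intercept: float = 5000.0
    tech_trend: float = 0.0
    beta_T: float = 0.0
    beta_DTR: float = 0.0
    beta_R: float = 0.0
    beta_S: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.last_year < self.first_year:
            raise ConfigurationError(
                f"cultivar {self.id}: last_year precedes first_year"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"cultivar {self.id}: noise_sd < 0")


@dataclass(frozen=True)
class YieldScenario:
    """A set of cultivar ground truths plus experiment gap years."""

    cultivars: tuple[CultivarSpec, ...]
    gap_years: frozenset[int] = frozenset()
    seed: int = 0

    def __init__(
        self,
        cultivars: Iterable[CultivarSpec],
        gap_years: Iterable[int] = (),
        seed: int = 0,
    ) -> None:
        object.__setattr__(self, "cultivars", tuple(cultivars))
        object.__setattr__(self, "gap_years", frozenset(gap_years))
        object.__setattr__(self, "seed", seed)


def synth_yields(scenario: YieldScenario, climate: pd.DataFrame) -> pd.DataFrame:
    """Generate the cultivar yield table from seasonal climate records.

    Parameters
    ----------
    scenario : YieldScenario
    climate : DataFrame
        Seasonal climate with columns ``season, year, T, DTR, R, S``
        covering every cultivar's cultivation span (gap years excepted).

    Returns
    -------
    DataFrame with columns ``cultivar, season, year, yield``; gap years
    produce absent rows, not zeros.
    """
    rng = np.random.default_rng(scenario.seed)
    idx = climate.set_index(["season", "year"])
    rows: list[tuple[str, str, int, float]] = []
    for cv in scenario.cultivars:
        years = [
            y
            for y in range(cv.first_year, cv.last_year + 1)
            if y not in scenario.gap_years
        ]
        missing = [y for y in years if (cv.season, y) not in idx.index]
        if missing:
            raise CoverageError(
                f"climate series does not cover cultivar {cv.id} "
                f"({cv.season}) in years {missing[:5]}"
            )
        noise = rng.normal(0.0, cv.noise_sd, size=len(years)) if cv.noise_sd > 0 \
            else np.zeros(len(years))
        for y, eps in zip(years, noise):
            rec = idx.loc[(cv.season, y)]
            yld = (
                cv.intercept
                + cv.tech_trend * (y - cv.first_year)
                + cv.beta_T * rec["T"]
                + cv.beta_DTR * rec["DTR"]
                + cv.beta_R * rec["R"]
                + cv.beta_S * rec["S"]
                + eps
            )
            rows.append((cv.id, cv.season, y, float(yld)))
    return pd.DataFrame(rows, columns=YIELD_COLUMNS)


# ---------------------------------------------------------------------------
# Fixture registry: tiny deterministic datasets with hand-checkable truths.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fixture:
    """A small deterministic dataset plus its ground truth."""

    name: str
    weather: pd.DataFrame
    yields: pd.DataFrame
    config: dict
    truth: dict


def _toy_weather(start: int, end: int, seed: int, missing_dates: Sequence[str] = ()) -> pd.DataFrame:
    scn = WeatherScenario(
        start_year=start,
        end_year=end,
        missing_rate=0.0,
        seed=seed,
    )
    df = synth_weather(scn)
    if missing_dates:
        mask = df["date"].isin(pd.to_datetime(list(missing_dates)))
        df.loc[mask, ["tavg", "tmin", "tmax", "rain", "sunshine"]] = np.nan
    return df


def _toy_linear(gap_years: Iterable[int] = ()) -> Fixture:
    # 8 years -> 7 first-difference pairs, enough for the 5-parameter fit.
    from . import weather as weather_qc  # local import to avoid a cycle

    start, end = 2001, 2008
    wx = _toy_weather(start, end, seed=7)
    clean, report = weather_qc.impute(wx)
    seasonal = weather_qc.aggregate_seasons(clean, report=report)
    truth_betas = {
        "beta0": 0.0,
        "beta_T": 50.0,
        "beta_DTR": -30.0,
        "beta_R": 0.5,
        "beta_S": 1.2,
    }
    cv = CultivarSpec(
        id="TOY1",
        season="cool",
        first_year=start,
        last_year=end,
        intercept=4000.0,
        tech_trend=25.0,
        beta_T=truth_betas["beta_T"],
        beta_DTR=truth_betas["beta_DTR"],
        beta_R=truth_betas["beta_R"],
        beta_S=truth_betas["beta_S"],
        noise_sd=0.0,
    )
    scn = YieldScenario([cv], gap_years=gap_years, seed=11)
    yields = synth_yields(scn, seasonal)
    config = {
        "seasons": "default",
        "periods": [[start, end]],
        "groups": [
            {
                "id": f"{start}-{end}",
                "season": "cool",
                "members": ["TOY1"],
                "period": [start, end],
                "excluded": False,
            }
        ],
        "min_pairs": 6,
    }
    return Fixture(
        name="toy-linear",
        weather=wx,
        yields=yields,
        config=config,
        truth=dict(truth_betas, tech_trend=25.0, cultivar="TOY1"),
    )


def _toy_gap() -> Fixture:
    fx = _toy_linear(gap_years=[2004])
    config = dict(fx.config, min_pairs=4)
    # 7 present years, one interior gap -> 5 consecutive pairs.
    truth = dict(fx.truth, n_present_years=7, n_pairs=5)
    return Fixture("toy-gap", fx.weather, fx.yields, config, truth)


def _toy_missingdays() -> Fixture:
    missing = ["2002-03-05", "2002-08-10", "2003-02-01"]
    wx = _toy_weather(2001, 2004, seed=3, missing_dates=missing)
    return Fixture(
        name="toy-missingdays",
        weather=wx,
        yields=pd.DataFrame(columns=YIELD_COLUMNS),
        config={"seasons": "default"},
        truth={"n_missing_days": 3, "missing_dates": missing},
    )


_REGISTRY = {
    "toy-linear": _toy_linear,
    "toy-gap": _toy_gap,
    "toy-missingdays": _toy_missingdays,
}

FIXTURE_NAMES = tuple(sorted(_REGISTRY))


def make_fixture(name: str) -> Fixture:
    """Build a registered toy fixture by name.

    Raises
    ------
    KeyError
        If ``name`` is not registered (see :data:`FIXTURE_NAMES`).
    """
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()


def scenario_from_mapping(data: Mapping) -> WeatherScenario:
    """Build a :class:`WeatherScenario` from a plain key–value mapping."""
    fields = {f.name for f in dataclasses.fields(WeatherScenario)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(f"unknown weather scenario keys: {sorted(unknown)}")
    return WeatherScenario(**data)


def yield_scenario_from_mapping(data: Mapping) -> YieldScenario:
    """Build a :class:`YieldScenario` from a plain mapping."""
    try:
        cultivars = [CultivarSpec(**cv) for cv in data["cultivars"]]
    except TypeError as exc:
        raise ConfigurationError(f"bad cultivar entry: {exc}") from exc
    except KeyError:
        raise ConfigurationError("yield scenario needs a 'cultivars' list") from None
    return YieldScenario(
        cultivars,
        gap_years=data.get("gap_years", ()),
        seed=int(data.get("seed", 0)),
    )
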