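"""Linear time trends of seasonal climate variables.

Each seasonal climate series x(t) is modelled as a simple linear trend
``x = beta0 + beta1 * t + eps`` fitted by ordinary least squares on
calendar years as-is.  The trend-implied total change over a period
[start, end] is ``beta1 * (end - start)``: the rise of the regression
line between its endpoint years, which is the convention long-term
station analyses quote (e.g. a 0.01 deg C/yr slope over 1925-2019 is
reported as a 0.94 deg C total change).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, RankError

__all__ = [
    "TrendFit",
    "ClimateChangeSummary",
    "SeasonalTrendModel",
    "fit_linear_trend",
    "trend_total_change",
    "significance_marker",
]


def significance_marker(p: float) -> str:
    """Two-star significance marker: ``**`` for p<0.01, ``*`` for
    0.01<=p<0.05, ``'`` for 0.05<=p<0.1, empty otherwise.

    Boundary p-values fall into the weaker class (p=0.05 -> ``'``).
    """
    if not 0.0 <= p <= 1.0 or np.isnan(p):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "’"
    return ""


@dataclass(frozen=True)
class ClimateChangeSummary:
    """Trend-implied total change of one variable over a period."""

    variable: str
    season: str
    period: tuple[int, int]
    delta_total: float

    @property
    def n_years(self) -> int:
        """Calendar years inside the period, endpoints inclusive."""
        return self.period[1] - self.period[0] + 1


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of a seasonal climate variable on calendar year."""

    variable: str
    season: str
    beta0: float
    beta1: float
    p_slope: float
    r2: float
    n: int
    residual_sd: float

    @property
    def marker(self) -> str:
        return significance_marker(self.p_slope)

    def total_change(self, start_year: int, end_year: int) -> ClimateChangeSummary:
        return trend_total_change(self, start_year, end_year)

    def summary(self) -> str:
        return (
            f"{self.variable} ({self.season}): slope {self.beta1:+.4g}/yr"
            f"{self.marker}  intercept {self.beta0:.4g}  r2={self.r2:.3f}"
            f"  n={self.n}  p={self.p_slope:.3g}"
        )


class SeasonalTrendModel:
    """OLS model of one climate variable against calendar year.

    Parameters
    ----------
    years, values : sequence of float
        The (t, x) points; at least 3 points with >=2 distinct years.
    variable, season : str
        Labels carried through to the results.
    """

    def __init__(
        self,
        years: Sequence[float],
        values: Sequence[float],
        variable: str = "",
        season: str = "",
    ) -> None:
        self.years = np.asarray(years, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.variable = variable
        self.season = season
        if self.years.shape != self.values.shape or self.years.ndim != 1:
            raise ValueError("years and values must be equal-length 1-d sequences")
        if len(self.years) < 3:
            raise InsufficientDataError(
                f"trend fit needs >=3 points, got {len(self.years)}"
            )
        if np.ptp(self.years) == 0:
            raise RankError("all years identical: slope is unidentifiable")

    def fit(self) -> TrendFit:
        t, x = self.years, self.values
        res = stats.linregress(t, x)
        n = len(t)
        resid = x - (res.intercept + res.slope * t)
        ssr = float(resid @ resid)
        residual_sd = float(np.sqrt(ssr / (n - 2))) if n > 2 else 0.0
        tss = float(((x - x.mean()) ** 2).sum())
        if tss <= 1e-300:
            r2 = 1.0 if ssr <= 1e-300 else 0.0
            p = 1.0
        else:
            r2 = float(np.clip(res.rvalue**2, 0.0, 1.0))
            p = float(res.pvalue)
        return TrendFit(
            variable=self.variable,
            season=self.season,
            beta0=float(res.intercept),
            beta1=float(res.slope),
            p_slope=p,
            r2=r2,
            n=n,
            residual_sd=residual_sd,
        )


def fit_linear_trend(
    points: Iterable[tuple[float, float]],
    variable: str = "",
    season: str = "",
) -> TrendFit:
    """Fit ``x = beta0 + beta1*t + eps`` to (year, value) points by OLS."""
    pts = list(points)
    years = [p[0] for p in pts]
    values = [p[1] for p in pts]
    return SeasonalTrendModel(years, values, variable=variable, season=season).fit()


def trend_total_change(
    fit: TrendFit, start_year: int, end_year: int
) -> ClimateChangeSummary:
    """Total change implied by the trend line over [start_year, end_year].

    ``delta_total = beta1 * (end_year - start_year)`` — the span between
    the endpoint years, not the count of years.
    """
    if end_year <= start_year:
        raise ValueError(f"end_year {end_year} must exceed start_year {start_year}")
    return ClimateChangeSummary(
        variable=fit.variable,
        season=fit.season,
        period=(start_year, end_year),
        delta_total=fit.beta1 * (end_year - start_year),
    )
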