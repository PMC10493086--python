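"""Daily weather quality control and seasonal aggregation.

Cleaning follows the station-record convention of replacing a missing or
outlying value on calendar day (m, d) of year y by the mean of the
values on the same calendar day of years y-1 and y+1 (a single neighbor
is used at the ends of the record).  Outliers are screened against a
+/-7-day day-of-year climatology.  Cleaned days are then aggregated into
per-season, per-year climate records: mean daily average temperature T,
mean diurnal temperature range DTR, total rainfall R and total sunshine
duration S over a fixed calendar window — by default Jan 20–Jun 23 for
the cool cropping season and Jul 4–Nov 22 for the warm cropping season.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AggregationError, ConfigurationError

__all__ = [
    "VARIABLES",
    "SeasonDefinition",
    "DEFAULT_SEASONS",
    "SeasonalClimateRecord",
    "QCReplacement",
    "QCReport",
    "impute",
    "aggregate_season",
    "aggregate_seasons",
]

VARIABLES = ("tavg", "tmin", "tmax", "rain", "sunshine")

# Cumulative month lengths of a leap year, to index every possible
# (month, day) into 0..365.
_LEAP_CUM = np.concatenate(([0], np.cumsum([31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])))


@dataclass(frozen=True)
class SeasonDefinition:
    """A date-anchored cropping-season window, endpoints inclusive."""

    name: str
    start: tuple[int, int]  # (month, day)
    end: tuple[int, int]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ConfigurationError(
                f"season {self.name}: start {self.start} must precede end {self.end}"
            )

    def window(self, year: int) -> tuple[dt.date, dt.date]:
        return (dt.date(year, *self.start), dt.date(year, *self.end))

    def n_days(self, year: int) -> int:
        a, b = self.window(year)
        return (b - a).days + 1


DEFAULT_SEASONS = (
    SeasonDefinition("cool", (1, 20), (6, 23)),
    SeasonDefinition("warm", (7, 4), (11, 22)),
)


@dataclass(frozen=True)
class SeasonalClimateRecord:
    """Per (season, year) climate summary: the level series behind the
    first-difference anomalies."""

    season: str
    year: int
    T: float        # mean daily average temperature, deg C
    DTR: float      # mean (tmax - tmin), deg C
    R: float        # total rainfall, mm
    S: float        # total sunshine, h
    n_days: int
    n_imputed: int


@dataclass(frozen=True)
class QCReplacement:
    date: pd.Timestamp
    variable: str
    old: float          # NaN when the cell was missing
    new: float
    rule: str


@dataclass
class QCReport:
    """Audit trail of every imputation performed on a daily series."""

    n_missing_replaced: int = 0
    n_outliers_replaced: int = 0
    n_unresolved: int = 0
    total_cells: int = 0
    total_days: int = 0
    n_missing_days: int = 0
    replacements: list[QCReplacement] = field(default_factory=list)
    unresolved: list[tuple[pd.Timestamp, str]] = field(default_factory=list)

    @property
    def fraction_missing(self) -> float:
        """Replaced-missing cells over all day-variable cells."""
        return self.n_missing_replaced / self.total_cells if self.total_cells else 0.0

    @property
    def fraction_missing_days(self) -> float:
        """Wholly missing days over all days (the convention long-term
        station reports usually quote)."""
        return self.n_missing_days / self.total_days if self.total_days else 0.0

    def imputed_dates(self) -> set[pd.Timestamp]:
        return {r.date for r in self.replacements}

    def to_log(self) -> str:
        lines = [
            f"# weather QC report",
            f"missing_replaced\t{self.n_missing_replaced}",
            f"outliers_replaced\t{self.n_outliers_replaced}",
            f"unresolved\t{self.n_unresolved}",
            f"fraction_missing_cells\t{self.fraction_missing:.6f}",
            f"fraction_missing_days\t{self.fraction_missing_days:.6f}",
        ]
        for r in self.replacements:
            lines.append(
                f"{r.date.date()}\t{r.variable}\t{r.old!r}\t{r.new!r}\t{r.rule}"
            )
        for d, v in self.unresolved:
            lines.append(f"{d.date()}\t{v}\tunresolved")
        return "\n".join(lines) + "\n"


def _md_index(dates: pd.DatetimeIndex) -> np.ndarray:
    """Map each date's (month, day) to a stable 0..365 index."""
    return _LEAP_CUM[dates.month.to_numpy() - 1] + dates.day.to_numpy() - 1


def _neighbor_date(year: int, month: int, day: int) -> dt.date | None:
    """Same calendar day in another year; Feb 29 falls back to Feb 28."""
    if month == 2 and day == 29 and not calendar.isleap(year):
        return dt.date(year, 2, 28)
    try:
        return dt.date(year, month, day)
    except ValueError:  # pragma: no cover - only Feb 29 is irregular
        return None


def _normalise(series: pd.DataFrame) -> pd.DataFrame:
    df = series.copy()
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
        df = df.set_index("date")
    df.index = pd.DatetimeIndex(df.index)
    df = df.sort_index()
    # A day absent from the table entirely is a missing day.
    full = pd.date_range(df.index.min(), df.index.max(), freq="D")
    df = df.reindex(full)
    df.index.name = "date"
    return df[list(VARIABLES)].astype(float)


def _climatology(df: pd.DataFrame, halfwidth: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variable day-of-year mean/SD over a +/-halfwidth circular window."""
    md = _md_index(df.index)
    means = {}
    sds = {}
    for var in VARIABLES:
        vals = df[var].to_numpy()
        sums = np.zeros(366)
        sqs = np.zeros(366)
        cnt = np.zeros(366)
        ok = ~np.isnan(vals)
        np.add.at(sums, md[ok], vals[ok])
        np.add.at(sqs, md[ok], vals[ok] ** 2)
        np.add.at(cnt, md[ok], 1.0)
        w = 2 * halfwidth + 1
        pad = lambda a: np.concatenate([a[-halfwidth:], a, a[:halfwidth]])
        ker = np.ones(w)
        tot = np.convolve(pad(sums), ker, mode="valid")
        tot2 = np.convolve(pad(sqs), ker, mode="valid")
        n = np.convolve(pad(cnt), ker, mode="valid")
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = tot / n
            var_ = np.maximum(tot2 / n - mu**2, 0.0)
            sd = np.sqrt(var_)
        means[var] = mu
        sds[var] = sd
    return pd.DataFrame(means), pd.DataFrame(sds)


def impute(
    series: pd.DataFrame,
    outlier_z: float = 4.0,
    climatology_halfwidth: int = 7,
) -> tuple[pd.DataFrame, QCReport]:
    """Replace missing values and outliers by adjacent-year neighbor means.

    A cell (calendar day m-d of year y, variable v) is *flagged* when it
    is absent or when ``|value - clim_mean| > outlier_z * clim_sd``
    against the +/-``climatology_halfwidth``-day day-of-year climatology
    computed across all years.  A flagged cell is replaced by the mean
    of the same-calendar-day values of years y-1 and y+1; if only one
    neighbor exists (record ends) that value is used alone.  Cells whose
    neighbors are themselves flagged are retried in later passes using
    already-imputed values; cells that never resolve are left absent and
    listed in the report.

    Returns the cleaned series (full daily index, ``date`` index) and a
    :class:`QCReport` enumerating every replacement.
    """
    if outlier_z <= 0:
        raise ConfigurationError("outlier_z must be positive")
    df = _normalise(series)
    report = QCReport(
        total_cells=df.shape[0] * len(VARIABLES),
        total_days=df.shape[0],
        n_missing_days=int(df.isna().all(axis=1).sum()),
    )
    clim_mu, clim_sd = _climatology(df, climatology_halfwidth)
    md = _md_index(df.index)
    y0, y1 = df.index[0].year, df.index[-1].year

    flagged: dict[str, set[pd.Timestamp]] = {}
    reasons: dict[tuple[pd.Timestamp, str], str] = {}
    for var in VARIABLES:
        vals = df[var].to_numpy()
        mu = clim_mu[var].to_numpy()[md]
        sd = clim_sd[var].to_numpy()[md]
        missing = np.isnan(vals)
        with np.errstate(invalid="ignore"):
            outlier = (~missing) & (sd > 1e-12) & (np.abs(vals - mu) > outlier_z * sd)
        idx = df.index
        flagged[var] = set(idx[missing | outlier])
        for ts in idx[missing]:
            reasons[(ts, var)] = "missing"
        for ts in idx[outlier]:
            reasons[(ts, var)] = "outlier"

    clean = df.copy()
    pending = {(ts, var) for var, tss in flagged.items() for ts in tss}
    still_flagged = dict(flagged)  # cells not yet trusted as neighbors
    pass_no = 0
    while pending:
        pass_no += 1
        resolved_now: list[tuple[pd.Timestamp, str, float]] = []
        for ts, var in sorted(pending):
            vals = []
            for ny in (ts.year - 1, ts.year + 1):
                if ny < y0 or ny > y1:
                    continue
                nd = _neighbor_date(ny, ts.month, ts.day)
                if nd is None:
                    continue
                nts = pd.Timestamp(nd)
                if nts in still_flagged[var]:
                    continue
                v = clean.at[nts, var]
                if not np.isnan(v):
                    vals.append(float(v))
            if vals:
                resolved_now.append((ts, var, float(np.mean(vals))))
        if not resolved_now:
            break
        for ts, var, new in resolved_now:
            old = df.at[ts, var]
            reason = reasons[(ts, var)]
            rule = f"{reason}-neighbor-mean" + (f"-pass{pass_no}" if pass_no > 1 else "")
            clean.at[ts, var] = new
            report.replacements.append(
                QCReplacement(ts, var, float(old) if not np.isnan(old) else float("nan"), new, rule)
            )
            if reason == "missing":
                report.n_missing_replaced += 1
            else:
                report.n_outliers_replaced += 1
            pending.discard((ts, var))
            still_flagged[var].discard(ts)

    for ts, var in sorted(pending):
        report.unresolved.append((ts, var))
    report.n_unresolved = len(pending)
    return clean, report


def aggregate_season(
    series: pd.DataFrame,
    season: SeasonDefinition,
    year: int,
    report: QCReport | None = None,
) -> SeasonalClimateRecord:
    """Aggregate cleaned daily records over one season window.

    T is the mean of daily average temperature, DTR the mean of daily
    (tmax - tmin), R and S the sums of daily rainfall and sunshine, all
    over the window inclusive of its endpoints (Feb 29 included in leap
    years, so ``n_days`` varies by one).

    Raises
    ------
    AggregationError
        If any day of the window is absent or still has a missing value,
        naming the offending day.
    """
    df = series
    if "date" in df.columns:
        df = df.set_index(pd.to_datetime(df["date"]))
    a, b = season.window(year)
    win = df.loc[pd.Timestamp(a): pd.Timestamp(b), list(VARIABLES)]
    expected = season.n_days(year)
    if len(win) != expected:
        raise AggregationError(
            f"{season.name} {year}: window has {len(win)} of {expected} days"
        )
    bad = win.isna()
    if bad.to_numpy().any():
        day = win.index[bad.any(axis=1)][0]
        var = bad.columns[bad.loc[day]][0]
        raise AggregationError(
            f"{season.name} {year}: unresolved missing {var} on {day.date()}"
        )
    n_imputed = 0
    if report is not None:
        lo, hi = pd.Timestamp(a), pd.Timestamp(b)
        n_imputed = len({d for d in report.imputed_dates() if lo <= d <= hi})
    return SeasonalClimateRecord(
        season=season.name,
        year=year,
        T=float(win["tavg"].mean()),
        DTR=float((win["tmax"] - win["tmin"]).mean()),
        R=float(win["rain"].sum()),
        S=float(win["sunshine"].sum()),
        n_days=expected,
        n_imputed=n_imputed,
    )


def aggregate_seasons(
    series: pd.DataFrame,
    seasons: Sequence[SeasonDefinition] = DEFAULT_SEASONS,
    years: Iterable[int] | None = None,
    report: QCReport | None = None,
) -> pd.DataFrame:
    """Aggregate every season window fully covered by the series.

    Returns a frame with columns ``season, year, T, DTR, R, S, n_days,
    n_imputed``, one row per (season, year).
    """
    df = series
    if "date" in df.columns:
        df = df.set_index(pd.to_datetime(df["date"]))
    lo, hi = df.index.min(), df.index.max()
    records = []
    for season in seasons:
        yrs = years if years is not None else range(lo.year, hi.year + 1)
        for year in yrs:
            a, b = season.window(year)
            if pd.Timestamp(a) < lo or pd.Timestamp(b) > hi:
                continue
            records.append(aggregate_season(df, season, year, report=report))
    return pd.DataFrame([r.__dict__ for r in records])
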