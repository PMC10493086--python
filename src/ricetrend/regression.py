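"""First-difference regression of yield anomalies on climate anomalies.

Year-to-year first differences Δv(y) = v(y+1) − v(y) strip the slowly
varying technology/management trend from a cultivar's yield series, so
that an ordinary least-squares fit of

    ΔY = β0 + βT·ΔT + βDTR·ΔDTR + βR·ΔR + βS·ΔS + ε

isolates the climate sensitivity of yield.  Differences are only formed
over *consecutive* calendar years both present for that cultivar —
differencing across a multi-year experiment gap would reintroduce the
very technology change the transform removes.  Absolute coefficients
(kg ha⁻¹ per unit) are normalised by the cultivar's average grain yield
into percent coefficients (% per unit) so cultivars of different yield
levels are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, InsufficientDataError

__all__ = [
    "CLIMATE_VARS",
    "first_difference",
    "FirstDifferenceSet",
    "build_first_differences",
    "FirstDifferenceYieldModel",
    "RegressionResult",
    "fit_delta_regression",
    "percent_coefficients",
]

CLIMATE_VARS = ("T", "DTR", "R", "S")

#: Default minimum number of difference pairs for the 5-parameter fit.
DEFAULT_MIN_PAIRS = 6


def first_difference(series: Mapping[int, float]) -> dict[int, float]:
    """Year-keyed first differences: Δ(y) = v(y+1) − v(y).

    Δ(y) exists iff both y and y+1 are present; gaps produce no bridging
    pair.  An empty result is allowed.
    """
    out: dict[int, float] = {}
    for y in sorted(series):
        if y + 1 in series:
            out[y] = series[y + 1] - series[y]
    return out


@dataclass(frozen=True)
class FirstDifferenceSet:
    """Aligned (ΔY, ΔT, ΔDTR, ΔR, ΔS) rows, one per consecutive-year pair.

    ``frame`` has index = the first year of each pair and columns
    ``dY, dT, dDTR, dR, dS``.
    """

    frame: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return len(self.frame)

    @property
    def years(self) -> list[int]:
        return list(self.frame.index)


def build_first_differences(
    yields: Mapping[int, float],
    climate: pd.DataFrame,
) -> FirstDifferenceSet:
    """Join yield and climate first differences on the pair's first year.

    Parameters
    ----------
    yields : mapping year -> kg/ha
    climate : DataFrame
        Seasonal climate levels with columns ``year, T, DTR, R, S``
        (already filtered to the cultivar's season).
    """
    dy = first_difference(yields)
    clim = climate.set_index("year") if "year" in climate.columns else climate
    rows = {}
    for y, d in dy.items():
        if y in clim.index and y + 1 in clim.index:
            rows[y] = {
                "dY": d,
                **{
                    f"d{v}": float(clim.at[y + 1, v] - clim.at[y, v])
                    for v in CLIMATE_VARS
                },
            }
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if frame.empty:
        frame = pd.DataFrame(columns=["dY", "dT", "dDTR", "dR", "dS"])
    return FirstDifferenceSet(frame)


@dataclass(frozen=True)
class RegressionResult:
    """Fitted first-difference regression of one cultivar-season.

    ``beta`` maps climate variable name -> kg/ha per unit; ``pct`` maps
    the same names to percent coefficients (% per unit, i.e. 100·β
    divided by the cultivar's average grain yield); ``bse`` carries the
    usual OLS standard errors (intercept under key ``0``).
    """

    cultivar: str
    season: str
    beta0: float
    beta: dict[str, float]
    bse: dict[str, float]
    pct: dict[str, float]
    n_pairs: int
    r2: float
    average_grain_yield: float

    @property
    def beta_T(self) -> float:
        return self.beta["T"]

    @property
    def beta_DTR(self) -> float:
        return self.beta["DTR"]

    @property
    def beta_R(self) -> float:
        return self.beta["R"]

    @property
    def beta_S(self) -> float:
        return self.beta["S"]

    def summary(self) -> str:
        head = (
            f"First-difference regression: {self.cultivar} ({self.season})\n"
            f"n_pairs={self.n_pairs}  r2={self.r2:.3f}  "
            f"avg yield={self.average_grain_yield:.1f} kg/ha\n"
            f"{'term':>6} {'beta (kg/ha/unit)':>18} {'se':>10} {'pct (%/unit)':>13}\n"
        )
        lines = [f"{'const':>6} {self.beta0:>18.4f} {self.bse['0']:>10.4f} {'':>13}"]
        for v in CLIMATE_VARS:
            lines.append(
                f"{v:>6} {self.beta[v]:>18.4f} {self.bse[v]:>10.4f} "
                f"{self.pct[v]:>13.4f}"
            )
        return head + "\n".join(lines)


def percent_coefficients(
    beta: Mapping[str, float], avg_yield: float
) -> dict[str, float]:
    """Percent coefficients: 100 · β / average grain yield, % per unit."""
    if avg_yield <= 0:
        raise ValueError(f"average grain yield must be positive, got {avg_yield}")
    return {v: 100.0 * b / avg_yield for v, b in beta.items()}


class FirstDifferenceYieldModel:
    """OLS model of yield first differences on climate first differences.

    Build either from a prepared :class:`FirstDifferenceSet` or from raw
    per-year series via :meth:`from_series`; :meth:`fit` returns a
    :class:`RegressionResult`.
    """

    def __init__(
        self,
        diffs: FirstDifferenceSet,
        avg_yield: float,
        cultivar: str = "",
        season: str = "",
        min_pairs: int = DEFAULT_MIN_PAIRS,
    ) -> None:
        if avg_yield <= 0:
            raise ValueError(f"average grain yield must be positive, got {avg_yield}")
        self.diffs = diffs
        self.avg_yield = float(avg_yield)
        self.cultivar = cultivar
        self.season = season
        self.min_pairs = min_pairs

    @classmethod
    def from_series(
        cls,
        yields: Mapping[int, float],
        climate: pd.DataFrame,
        cultivar: str = "",
        season: str = "",
        min_pairs: int = DEFAULT_MIN_PAIRS,
    ) -> "FirstDifferenceYieldModel":
        """Build from a year->yield map and a seasonal climate table.

        The average grain yield (denominator of the percent form) is the
        mean over *all* present years, not only differenced ones.
        """
        diffs = build_first_differences(yields, climate)
        avg = float(np.mean(list(yields.values())))
        return cls(diffs, avg, cultivar=cultivar, season=season, min_pairs=min_pairs)

    def _design(self) -> tuple[np.ndarray, np.ndarray]:
        f = self.diffs.frame
        X = f[[f"d{v}" for v in CLIMATE_VARS]].to_numpy(dtype=float)
        y = f["dY"].to_numpy(dtype=float)
        return X, y

    def fit(self) -> RegressionResult:
        n = self.diffs.n_pairs
        if n < self.min_pairs:
            raise InsufficientDataError(
                f"{self.cultivar or 'cultivar'} ({self.season or '?'}): "
                f"{n} difference pairs < required {self.min_pairs}"
            )
        X, y = self._design()
        Xc = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            bad = self._suspect_columns(Xc)
            raise CollinearityError(
                f"{self.cultivar or 'cultivar'} ({self.season or '?'}): design "
                f"matrix rank {rank} < {Xc.shape[1]}; suspect columns: {bad}"
            )
        res = sm.OLS(y, Xc).fit()
        beta = {v: float(res.params[i + 1]) for i, v in enumerate(CLIMATE_VARS)}
        bse = {"0": float(res.bse[0])}
        bse.update({v: float(res.bse[i + 1]) for i, v in enumerate(CLIMATE_VARS)})
        r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 0.0
        return RegressionResult(
            cultivar=self.cultivar,
            season=self.season,
            beta0=float(res.params[0]),
            beta=beta,
            bse=bse,
            pct=percent_coefficients(beta, self.avg_yield),
            n_pairs=n,
            r2=float(np.clip(r2, 0.0, 1.0)),
            average_grain_yield=self.avg_yield,
        )

    @staticmethod
    def _suspect_columns(Xc: np.ndarray) -> list[str]:
        """Name columns implicated in the rank deficiency via the null space."""
        names = ["const", *CLIMATE_VARS]
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        null = vt[s <= tol] if s.size else vt
        if null.size == 0:
            null = vt[-1:]
        weight = np.abs(null).max(axis=0)
        return [nm for nm, w in zip(names, weight) if w > 1e-8]


def fit_delta_regression(
    diffs: FirstDifferenceSet,
    avg_yield: float,
    cultivar: str = "",
    season: str = "",
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> RegressionResult:
    """Functional surface over :class:`FirstDifferenceYieldModel`."""
    return FirstDifferenceYieldModel(
        diffs, avg_yield, cultivar=cultivar, season=season, min_pairs=min_pairs
    ).fit()
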