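"""Projection of fitted coefficients into yield-change estimates.

A fitted climate sensitivity combines with the trend-implied total
climate change of a period into two figures:

* total relative yield change (%) = percent coefficient × ΔClimate_total
* annual actual yield change (kg/ha per year)
  = absolute coefficient × ΔClimate_total / number of years

with number of years = end − start + 1 (calendar years in the period,
so 20, 39 and 24 for the standard 1925–1944, 1945–1983 and 1996–2019
intervals), while the trend total uses the end − start span.  The two
figures satisfy ``annual = (total/100) × average grain yield / n_years``
whenever both come from the same β and ΔClimate.  Group-level values
are means (± sample SD) over member cultivars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .grouping import CultivarGroup
from .regression import CLIMATE_VARS, RegressionResult
from .trends import ClimateChangeSummary, SeasonalTrendModel, trend_total_change

__all__ = [
    "YieldChangeEstimate",
    "total_relative_change",
    "annual_actual_change",
    "period_delta",
    "project_members",
    "project_group",
]


@dataclass(frozen=True)
class YieldChangeEstimate:
    """Projected yield change of one cultivar for one climate variable."""

    season: str
    label: str  # cultivar or group id
    period: tuple[int, int]
    variable: str
    total_relative: float   # %
    annual_actual: float    # kg/ha per year

    @property
    def n_years(self) -> int:
        return self.period[1] - self.period[0] + 1


def total_relative_change(pct_beta: float, delta_total: float) -> float:
    """Total relative yield change (%): percent coefficient × ΔClimate."""
    return pct_beta * delta_total


def annual_actual_change(beta: float, delta_total: float, n_years: int) -> float:
    """Annual actual yield change (kg/ha/yr): β × ΔClimate / n_years."""
    if n_years < 1:
        raise ValueError(f"n_years must be >= 1, got {n_years}")
    return beta * delta_total / n_years


def period_delta(
    climate: pd.DataFrame,
    variable: str,
    season: str,
    period: tuple[int, int],
    mode: str = "period-local",
) -> ClimateChangeSummary:
    """Trend-implied total change of one climate variable over a period.

    ``mode="period-local"`` (default) refits the linear trend on the
    period's years only; ``mode="global"`` fits on the full record and
    applies the global slope over the period's span.  Both conventions
    are defensible readings of per-interval coefficient analyses; the
    output metadata records which was used.
    """
    df = climate
    if "season" in df.columns:
        df = df[df["season"] == season]
    col = {"T": "T", "DTR": "DTR", "R": "R", "S": "S"}[variable]
    start, end = period
    if mode == "period-local":
        sub = df[(df["year"] >= start) & (df["year"] <= end)]
    elif mode == "global":
        sub = df
    else:
        raise ValueError(f"unknown period_delta mode {mode!r}")
    if len(sub) < 3:
        raise InsufficientDataError(
            f"{variable} ({season}) {start}-{end}: only {len(sub)} years of climate"
        )
    fit = SeasonalTrendModel(
        sub["year"].to_numpy(float), sub[col].to_numpy(float),
        variable=variable, season=season,
    ).fit()
    return trend_total_change(fit, start, end)


def project_members(
    group: CultivarGroup,
    member_results: Sequence[RegressionResult],
    deltas: Mapping[str, ClimateChangeSummary],
) -> list[YieldChangeEstimate]:
    """Per-cultivar yield-change estimates for every climate variable.

    At this level the two figures are tied by the identity
    ``annual_actual = (total_relative/100) × average_grain_yield /
    n_years``, both being built from the same β and ΔClimate.
    """
    n_years = group.period[1] - group.period[0] + 1
    out = []
    for v in CLIMATE_VARS:
        d = deltas[v]
        if d.season != group.season or tuple(d.period) != tuple(group.period):
            raise ValueError(
                f"delta for {v} is {d.season} {d.period}, group is "
                f"{group.season} {group.period}"
            )
        for r in member_results:
            out.append(
                YieldChangeEstimate(
                    season=group.season,
                    label=r.cultivar,
                    period=tuple(group.period),
                    variable=v,
                    total_relative=total_relative_change(r.pct[v], d.delta_total),
                    annual_actual=annual_actual_change(
                        r.beta[v], d.delta_total, n_years
                    ),
                )
            )
    return out


def project_group(
    group: CultivarGroup,
    member_results: Sequence[RegressionResult],
    deltas: Mapping[str, ClimateChangeSummary],
) -> pd.DataFrame:
    """Project one group's yield changes for every climate variable.

    Parameters
    ----------
    group : CultivarGroup
    member_results : fitted regressions of the group's members
    deltas : variable -> ClimateChangeSummary for the group's season and
        period (a mismatch raises ValueError).

    Returns
    -------
    DataFrame with one row per variable: group mean and sample SD of the
    member-level total relative (%) and annual actual (kg/ha/yr)
    changes, plus ``n_years`` and the excluded flag.
    """
    n_years = group.period[1] - group.period[0] + 1
    estimates = project_members(group, member_results, deltas)
    rows = []
    for v in CLIMATE_VARS:
        ests = [e for e in estimates if e.variable == v]
        totals = np.array([e.total_relative for e in ests])
        annuals = np.array([e.annual_actual for e in ests])
        rows.append(
            {
                "season": group.season,
                "group": group.group_id,
                "period": f"{group.period[0]}-{group.period[1]}",
                "variable": v,
                "mean_total_relative": float(totals.mean()),
                "sd_total_relative": float(totals.std(ddof=1))
                if len(totals) > 1 else float("nan"),
                "mean_annual_actual": float(annuals.mean()),
                "sd_annual_actual": float(annuals.std(ddof=1))
                if len(annuals) > 1 else float("nan"),
                "n_years": n_years,
                "excluded": group.excluded,
            }
        )
    return pd.DataFrame(rows)
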