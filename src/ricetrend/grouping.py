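"""Cultivar grouping, group-level coefficient summaries and correlations.

Cultivars replaced one another over the decades of a long-term trial,
so per-cultivar climate sensitivities are summarised over groups of
cultivars with overlapping cultivation periods.  Grouping runs either
from an explicit configuration (reproducing a published membership) or
from the connected components of the interval-overlap graph.  The
module also computes Pearson correlation matrices: between climate
first-difference series, and between the yield first differences of
cultivar pairs within a group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .regression import CLIMATE_VARS, RegressionResult, first_difference
from .trends import significance_marker

__all__ = [
    "CultivarGroup",
    "GroupSummary",
    "CorrelationMatrix",
    "build_groups",
    "summarize_group",
    "climate_delta_correlations",
    "pairwise_yield_correlations",
]

logger = logging.getLogger(__name__)

Span = tuple[int, int]


@dataclass(frozen=True)
class CultivarGroup:
    group_id: str
    season: str
    members: tuple[str, ...]
    period: Span
    excluded: bool = False


@dataclass(frozen=True)
class GroupSummary:
    """Mean and sample SD (ddof=1) of members' percent coefficients.

    ``sd`` values are NaN for single-member groups (no sample SD)."""

    group_id: str
    season: str
    n_members: int
    mean: dict[str, float]
    sd: dict[str, float]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with per-pair n and markers."""

    labels: tuple[str, ...]
    r: np.ndarray
    n: np.ndarray
    markers: np.ndarray  # dtype object, significance marker strings

    def to_long(self) -> pd.DataFrame:
        rows = []
        k = len(self.labels)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "var_a": self.labels[i],
                        "var_b": self.labels[j],
                        "r": self.r[i, j],
                        "n": int(self.n[i, j]),
                        "marker": self.markers[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _spans_overlap(a: Sequence[Span], b: Sequence[Span]) -> bool:
    return any(s1 <= e2 and s2 <= e1 for (s1, e1) in a for (s2, e2) in b)


def build_groups(
    spans: Mapping[str, Sequence[Span] | Span],
    season: str = "",
    mode: str = "config",
    config_groups: Sequence[Mapping] | None = None,
) -> list[CultivarGroup]:
    """Group cultivars with overlapping cultivation periods.

    ``mode="config"`` reproduces an explicit membership list verbatim
    (each entry: ``id``, ``members``, ``period``, optional ``excluded``);
    ``mode="overlap"`` returns the connected components of the
    interval-overlap graph, one group per component, with the component
    hull as its period.

    ``spans`` maps cultivar id to one (first, last) span or a list of
    spans (interrupted cultivation).
    """
    norm: dict[str, list[Span]] = {}
    for cid, sp in spans.items():
        if sp and isinstance(sp[0], (tuple, list)):
            norm[cid] = [tuple(s) for s in sp]  # type: ignore[arg-type]
        else:
            norm[cid] = [tuple(sp)]  # type: ignore[list-item]
    if not norm:
        raise ConfigurationError("no cultivar spans given")

    if mode == "config":
        if not config_groups:
            raise ConfigurationError("config mode requires config_groups")
        out = []
        for g in config_groups:
            unknown = [m for m in g["members"] if m not in norm]
            if unknown:
                raise ConfigurationError(
                    f"group {g.get('id')}: unknown cultivars {unknown}"
                )
            out.append(
                CultivarGroup(
                    group_id=str(g["id"]),
                    season=str(g.get("season", season)),
                    members=tuple(g["members"]),
                    period=tuple(g["period"]),  # type: ignore[arg-type]
                    excluded=bool(g.get("excluded", False)),
                )
            )
        return out

    if mode != "overlap":
        raise ConfigurationError(f"unknown grouping mode {mode!r}")

    # Union-find over the interval-overlap graph.
    ids = sorted(norm)
    parent = {c: c for c in ids}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if _spans_overlap(norm[a], norm[b]):
                parent[find(a)] = find(b)
    comps: dict[str, list[str]] = {}
    for c in ids:
        comps.setdefault(find(c), []).append(c)
    groups = []
    for members in sorted(comps.values(), key=lambda m: min(s for c in m for s, _ in norm[c])):
        start = min(s for c in members for s, _ in norm[c])
        end = max(e for c in members for _, e in norm[c])
        groups.append(
            CultivarGroup(
                group_id=f"{start}-{end}",
                season=season,
                members=tuple(members),
                period=(start, end),
            )
        )
    return groups


def summarize_group(
    members: Sequence[RegressionResult] | Mapping[str, Mapping[str, float]],
    group_id: str = "",
    season: str = "",
) -> GroupSummary:
    """Mean and sample SD of members' percent coefficients per variable.

    ``members`` may be fitted :class:`RegressionResult` objects or a
    mapping cultivar -> {variable: pct} (useful when summarising
    published coefficient tables).
    """
    if isinstance(members, Mapping):
        pcts = [dict(v) for v in members.values()]
    else:
        pcts = [m.pct for m in members]
    if not pcts:
        raise ValueError("summarize_group needs at least one member")
    mean = {}
    sd = {}
    for v in CLIMATE_VARS:
        vals = np.array([p[v] for p in pcts], dtype=float)
        mean[v] = float(vals.mean())
        sd[v] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    return GroupSummary(
        group_id=group_id, season=season, n_members=len(pcts), mean=mean, sd=sd
    )


def _pairwise_pearson(columns: Mapping[str, Mapping[int, float]], min_n: int = 3) -> CorrelationMatrix:
    labels = tuple(columns)
    k = len(labels)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    markers = np.full((k, k), "", dtype=object)
    np.fill_diagonal(r, 1.0)
    for i in range(k):
        n[i, i] = len(columns[labels[i]])
    for i in range(k):
        for j in range(i + 1, k):
            a, b = columns[labels[i]], columns[labels[j]]
            common = sorted(set(a) & set(b))
            n[i, j] = n[j, i] = len(common)
            if len(common) < min_n:
                logger.warning(
                    "pair (%s, %s): only %d complete observations; undefined",
                    labels[i], labels[j], len(common),
                )
                continue
            x = np.array([a[y] for y in common])
            y = np.array([b[y] for y in common])
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            rr, p = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = float(rr)
            markers[i, j] = markers[j, i] = significance_marker(float(p))
    return CorrelationMatrix(labels=labels, r=r, n=n, markers=markers)


def climate_delta_correlations(
    climate: pd.DataFrame, season: str | None = None
) -> CorrelationMatrix:
    """Pearson correlations between climate first-difference series.

    ``climate`` holds seasonal levels (columns ``year, T, DTR, R, S``
    and optionally ``season``); differences are formed internally over
    consecutive years, and correlations use pairwise-complete pairs.
    """
    df = climate
    if season is not None and "season" in df.columns:
        df = df[df["season"] == season]
    cols = {}
    for v in CLIMATE_VARS:
        series = dict(zip(df["year"].astype(int), df[v].astype(float)))
        cols[f"d{v}"] = first_difference(series)
    return _pairwise_pearson(cols)


def pairwise_yield_correlations(
    group: CultivarGroup,
    series: Mapping[str, Mapping[int, float]],
    use_levels: bool = False,
) -> CorrelationMatrix:
    """Pearson correlations between member cultivars' yield anomalies.

    By default correlates yield *first differences* over the years both
    members were grown (consistent with the detrending logic); with
    ``use_levels=True`` raw yearly yields are correlated instead.
    Pairs with fewer than 3 overlapping observations are left undefined
    with a log entry.
    """
    cols: dict[str, Mapping[int, float]] = {}
    for m in group.members:
        s = dict(series[m])
        cols[m] = s if use_levels else first_difference(s)
    return _pairwise_pearson(cols)
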