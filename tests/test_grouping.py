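"""Tests of cultivar grouping, group summaries and correlation matrices."""

import numpy as np
import pandas as pd
import pytest

from ricetrend.errors import ConfigurationError
from ricetrend.grouping import (
    CultivarGroup,
    build_groups,
    climate_delta_correlations,
    pairwise_yield_correlations,
    summarize_group,
)
from ricetrend.reference import (
    CULTIVAR_SPANS,
    REFERENCE_GROUPS,
    REFERENCE_PCT_COEFFICIENTS,
)


def pearson_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))


class TestBuildGroups:
    def test_reference_config_reproduces_published_structure(self):
        for season in ("cool", "warm"):
            groups = build_groups(
                CULTIVAR_SPANS[season], season=season, mode="config",
                config_groups=REFERENCE_GROUPS[season],
            )
            assert [len(g.members) for g in groups] == [4, 4, 2, 4]
            flags = [g.excluded for g in groups]
            assert flags == [False, False, True, False]
            two = groups[2]
            assert two.period == (1977, 1983) and len(two.members) == 2

    def test_members_intersect_group_period(self):
        for season in ("cool", "warm"):
            groups = build_groups(
                CULTIVAR_SPANS[season], season=season, mode="config",
                config_groups=REFERENCE_GROUPS[season],
            )
            for g in groups:
                for m in g.members:
                    first, last = CULTIVAR_SPANS[season][m]
                    assert first <= g.period[1] and last >= g.period[0]

    def test_disjoint_spans_give_singletons(self):
        spans = {"A": (1, 5), "B": (7, 9), "C": (11, 12)}
        groups = build_groups(spans, mode="overlap")
        assert sorted(len(g.members) for g in groups) == [1, 1, 1]

    def test_transitive_overlap_chains_into_one_component(self):
        spans = {"A": (1, 5), "B": (4, 8), "C": (7, 10)}
        (g,) = build_groups(spans, mode="overlap")
        assert set(g.members) == {"A", "B", "C"}
        assert g.period == (1, 10)

    def test_config_groups_refine_overlap_components(self):
        for season in ("cool", "warm"):
            comps = build_groups(CULTIVAR_SPANS[season], season=season,
                                 mode="overlap")
            comp_of = {m: i for i, c in enumerate(comps) for m in c.members}
            for g in REFERENCE_GROUPS[season]:
                assert len({comp_of[m] for m in g["members"]}) == 1

    def test_unknown_member_rejected(self):
        with pytest.raises(ConfigurationError, match="NOPE"):
            build_groups(
                {"A": (1, 5)}, mode="config",
                config_groups=[{"id": "g", "members": ["NOPE"], "period": (1, 5)}],
            )


class TestSummarizeGroup:
    def test_published_cool_early_group_mean(self):
        season_tbl = REFERENCE_PCT_COEFFICIENTS["cool"]
        members = {m: season_tbl[m] for m in ("NM", "TCS2", "BK", "TCS6")}
        s = summarize_group(members)
        assert s.mean["T"] == pytest.approx((37.94 + 71.82 + 7.28 - 8.00) / 4)

    def test_published_warm_early_group_mean(self):
        season_tbl = REFERENCE_PCT_COEFFICIENTS["warm"]
        members = {m: season_tbl[m] for m in ("NM", "TCS2", "JG", "NY")}
        s = summarize_group(members)
        assert s.mean["T"] == pytest.approx((-16.28 - 15.55 - 5.22 - 4.57) / 4)

    def test_single_member_mean_is_value_and_sd_undefined(self):
        s = summarize_group({"X": {"T": 3.0, "DTR": 1.0, "R": 0.0, "S": -2.0}})
        assert s.mean["T"] == 3.0
        assert all(np.isnan(s.sd[v]) for v in ("T", "DTR", "R", "S"))

    def test_permutation_invariance(self):
        tbl = REFERENCE_PCT_COEFFICIENTS["cool"]
        a = summarize_group({m: tbl[m] for m in ("NM", "TCS2", "BK", "TCS6")})
        b = summarize_group({m: tbl[m] for m in ("TCS6", "BK", "NM", "TCS2")})
        for v in ("T", "DTR", "R", "S"):
            assert a.mean[v] == pytest.approx(b.mean[v], rel=1e-12)
            assert a.sd[v] == pytest.approx(b.sd[v], rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_group({})


class TestClimateDeltaCorrelations:
    def _climate(self, years, T, DTR=None, R=None, S=None):
        n = len(years)
        k = np.arange(n, dtype=float)
        return pd.DataFrame({
            "year": years,
            "T": T,
            "DTR": DTR if DTR is not None else 8.0 + np.sin(k),
            "R": R if R is not None else 500.0 + 40.0 * np.cos(2 * k),
            "S": S if S is not None else 850.0 + 25.0 * np.sin(3 * k + 1),
        })

    def test_series_against_itself_has_unit_r(self):
        rng = np.random.default_rng(0)
        T = rng.normal(20, 1, 8)
        clim = self._climate(list(range(2000, 2008)), T, DTR=T)
        cm = climate_delta_correlations(clim)
        i, j = cm.labels.index("dT"), cm.labels.index("dDTR")
        assert cm.r[i, j] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.diag(cm.r), 1.0)

    def test_matches_sigma_formula_oracle(self):
        rng = np.random.default_rng(5)
        years = list(range(2000, 2006))
        T = rng.normal(20, 1, 6)
        R = rng.normal(500, 50, 6)
        clim = self._climate(years, T, R=R)
        cm = climate_delta_correlations(clim)
        dT = np.diff(T)
        dR = np.diff(R)
        i, j = cm.labels.index("dT"), cm.labels.index("dR")
        assert cm.r[i, j] == pytest.approx(pearson_oracle(dT, dR), abs=1e-12)

    def test_matrix_is_symmetric_with_bounded_entries(self):
        rng = np.random.default_rng(9)
        years = list(range(1990, 2010))
        clim = self._climate(
            years,
            rng.normal(20, 1, 20), rng.normal(8, 1, 20),
            rng.normal(500, 80, 20), rng.normal(850, 60, 20),
        )
        cm = climate_delta_correlations(clim)
        assert np.allclose(cm.r, cm.r.T, equal_nan=True)
        finite = cm.r[np.isfinite(cm.r)]
        assert (np.abs(finite) <= 1 + 1e-12).all()


class TestPairwiseYieldCorrelations:
    def _group(self, members):
        return CultivarGroup("g", "cool", tuple(members), (2000, 2010))

    def test_identical_series_r_one(self):
        s = {y: 5000 + 100 * np.sin(y) for y in range(2000, 2008)}
        cm = pairwise_yield_correlations(self._group(["A", "B"]),
                                         {"A": s, "B": dict(s)})
        assert cm.r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_anomalies_r_minus_one(self):
        rng = np.random.default_rng(2)
        years = list(range(2000, 2008))
        vals = rng.normal(0, 100, len(years))
        a = {y: 5000 + v for y, v in zip(years, vals)}
        b = {y: 5000 - v for y, v in zip(years, vals)}
        cm = pairwise_yield_correlations(self._group(["A", "B"]), {"A": a, "B": b})
        assert cm.r[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_oracle_on_six_year_pair(self):
        rng = np.random.default_rng(3)
        years = list(range(2000, 2006))
        a = dict(zip(years, rng.normal(5000, 300, 6)))
        b = dict(zip(years, rng.normal(4500, 250, 6)))
        cm = pairwise_yield_correlations(self._group(["A", "B"]), {"A": a, "B": b})
        da = np.diff([a[y] for y in years])
        db = np.diff([b[y] for y in years])
        assert cm.r[0, 1] == pytest.approx(pearson_oracle(da, db), abs=1e-12)

    def test_levels_flag_uses_raw_yields(self):
        rng = np.random.default_rng(4)
        years = list(range(2000, 2006))
        a = dict(zip(years, rng.normal(5000, 300, 6)))
        b = dict(zip(years, rng.normal(4500, 250, 6)))
        cm = pairwise_yield_correlations(
            self._group(["A", "B"]), {"A": a, "B": b}, use_levels=True
        )
        xs = [a[y] for y in years]
        ys = [b[y] for y in years]
        assert cm.r[0, 1] == pytest.approx(pearson_oracle(xs, ys), abs=1e-12)

    def test_insufficient_overlap_left_undefined(self):
        a = {2000: 1.0, 2001: 2.0, 2002: 3.0}
        b = {2010: 1.0, 2011: 2.0}
        cm = pairwise_yield_correlations(self._group(["A", "B"]), {"A": a, "B": b})
        assert np.isnan(cm.r[0, 1])
        assert cm.n[0, 1] == 0
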