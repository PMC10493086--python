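"""Tests of the synthetic weather and yield generators."""

import numpy as np
import pandas as pd
import pytest

from ricetrend.errors import ConfigurationError, CoverageError
from ricetrend.regression import first_difference
from ricetrend.simulate import (
    FIXTURE_NAMES,
    CultivarSpec,
    WeatherScenario,
    YieldScenario,
    make_fixture,
    synth_weather,
    synth_yields,
)
from ricetrend.trends import fit_linear_trend
from ricetrend.weather import aggregate_seasons, impute

VALUE_COLS = ["tavg", "tmin", "tmax", "rain", "sunshine"]


def _noise_free(**kw):
    base = dict(
        start_year=2001, end_year=2005, missing_rate=0.0, anomaly_sd=0.0,
        dtr_anomaly_sd=0.0, sunshine_noise_sd=0.0, tavg_year_sd=0.0,
        dtr_year_sd=0.0, rain_year_sd=0.0, sunshine_year_sd=0.0,
        rain_prob=0.0, seed=1,
    )
    base.update(kw)
    return WeatherScenario(**base)


class TestSynthWeather:
    def test_noise_free_limit_is_deterministic_sinusoid_plus_trend(self):
        scn = _noise_free()
        df = synth_weather(scn)
        assert not df[VALUE_COLS].isna().any().any()
        assert (df["rain"] == 0).all()
        # Reconstruct the closed-form temperature from the scenario.
        doy = df["date"].dt.dayofyear.to_numpy(float)
        yrs = (df["date"].dt.year - scn.start_year).to_numpy(float)
        expected = (
            scn.baseline_tavg
            - scn.seasonal_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)
            + 0.5 * (scn.trend_tmin + scn.trend_tmax) * yrs
        )
        np.testing.assert_allclose(df["tavg"], expected, atol=1e-12)

    def test_record_invariants(self):
        df = synth_weather(WeatherScenario(start_year=2000, end_year=2009, seed=3))
        ok = df.dropna()
        assert (ok["tmin"] <= ok["tavg"] + 1e-12).all()
        assert (ok["tavg"] <= ok["tmax"] + 1e-12).all()
        assert (ok["rain"] >= 0).all()
        assert ok["sunshine"].between(0, 24).all()

    def test_one_row_per_calendar_day(self):
        df = synth_weather(WeatherScenario(start_year=2000, end_year=2003, seed=0))
        expected = pd.date_range("2000-01-01", "2003-12-31", freq="D")
        assert df["date"].tolist() == expected.tolist()

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        scn = WeatherScenario(start_year=2000, end_year=2004, seed=9)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        synth_weather(scn).to_csv(a, index=False)
        synth_weather(scn).to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self):
        scn1 = WeatherScenario(start_year=2000, end_year=2001, seed=1)
        scn2 = WeatherScenario(start_year=2000, end_year=2001, seed=2)
        assert not synth_weather(scn1)["tavg"].equals(synth_weather(scn2)["tavg"])

    def test_tmin_trend_dominates_warming_and_dtr_declines(self):
        # 95-year series with trends concentrated in the minimum
        # temperature: the seasonal tavg trend total should come out
        # near the closed-form (trend_tmin+trend_tmax)/2 * span, and
        # the DTR trend should be negative.
        scn = WeatherScenario(trend_tmin=0.016, trend_tmax=0.003,
                              missing_rate=0.0, seed=11)
        df = synth_weather(scn)
        seasonal = aggregate_seasons(df)
        cool = seasonal[seasonal["season"] == "cool"]
        fit = fit_linear_trend(zip(cool["year"], cool["T"]))
        span = scn.end_year - scn.start_year
        implied_total = 0.5 * (scn.trend_tmin + scn.trend_tmax) * span
        assert fit.beta1 * span == pytest.approx(implied_total, abs=0.45)
        dtr_fit = fit_linear_trend(zip(cool["year"], cool["DTR"]))
        assert dtr_fit.beta1 < 0

    def test_missing_rate_close_to_nominal(self):
        scn = WeatherScenario(missing_rate=0.0265, seed=5)
        df = synth_weather(scn)
        frac = df[VALUE_COLS].isna().all(axis=1).mean()
        assert frac == pytest.approx(0.0265, abs=0.005)

    @pytest.mark.parametrize(
        "kw",
        [
            {"missing_rate": 1.0},
            {"missing_rate": -0.1},
            {"rain_prob": 1.5},
            {"anomaly_sd": -1.0},
            {"end_year": 1900},
            {"ar1_coeff": 1.0},
        ],
    )
    def test_invalid_scenario_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            WeatherScenario(**kw)


class TestSynthYields:
    def test_pure_technology_trend_has_constant_differences(
        self, short_seasonal_climate
    ):
        cv = CultivarSpec(id="A", season="cool", first_year=2001, last_year=2010,
                          intercept=5000.0, tech_trend=10.0)
        table = synth_yields(YieldScenario([cv]), short_seasonal_climate)
        series = dict(zip(table["year"], table["yield"]))
        diffs = first_difference(series)
        assert all(d == pytest.approx(10.0) for d in diffs.values())

    def test_gap_years_are_absent_not_zero(self, short_seasonal_climate):
        cv = CultivarSpec(id="A", season="cool", first_year=2001, last_year=2010)
        table = synth_yields(
            YieldScenario([cv], gap_years={2004, 2005}), short_seasonal_climate
        )
        assert set(table["year"]) == set(range(2001, 2011)) - {2004, 2005}
        assert (table["yield"] > 0).all()

    def test_coverage_error_when_climate_too_short(self, short_seasonal_climate):
        cv = CultivarSpec(id="A", season="cool", first_year=1990, last_year=2010)
        with pytest.raises(CoverageError, match="A"):
            synth_yields(YieldScenario([cv]), short_seasonal_climate)

    def test_yields_follow_the_stated_linear_model(self, short_seasonal_climate):
        cv = CultivarSpec(id="A", season="warm", first_year=2002, last_year=2008,
                          intercept=1000.0, tech_trend=5.0, beta_T=40.0,
                          beta_DTR=-20.0, beta_R=0.3, beta_S=0.8)
        table = synth_yields(YieldScenario([cv]), short_seasonal_climate)
        clim = short_seasonal_climate.set_index(["season", "year"])
        for _, row in table.iterrows():
            c = clim.loc[("warm", row["year"])]
            expected = (1000.0 + 5.0 * (row["year"] - 2002) + 40.0 * c["T"]
                        - 20.0 * c["DTR"] + 0.3 * c["R"] + 0.8 * c["S"])
            assert row["yield"] == pytest.approx(expected, abs=1e-9)


class TestFixtures:
    def test_registry_lists_all_names(self):
        assert set(FIXTURE_NAMES) == {"toy-linear", "toy-gap", "toy-missingdays"}

    def test_unknown_name_raises_lookup_error(self):
        with pytest.raises(KeyError, match="no-such-fixture"):
            make_fixture("no-such-fixture")

    def test_toy_linear_truth_is_recovered_by_regression(self):
        from ricetrend.regression import FirstDifferenceYieldModel

        fx = make_fixture("toy-linear")
        clean, report = impute(fx.weather)
        seasonal = aggregate_seasons(clean, report=report)
        series = dict(zip(fx.yields["year"], fx.yields["yield"]))
        res = FirstDifferenceYieldModel.from_series(
            series, seasonal[seasonal["season"] == "cool"],
            cultivar="TOY1", season="cool",
        ).fit()
        for v in ("T", "DTR", "R", "S"):
            assert res.beta[v] == pytest.approx(fx.truth[f"beta_{v}"], abs=1e-7)

    def test_toy_gap_pair_count(self):
        from ricetrend.regression import build_first_differences

        fx = make_fixture("toy-gap")
        clean, report = impute(fx.weather)
        seasonal = aggregate_seasons(clean, report=report)
        series = dict(zip(fx.yields["year"], fx.yields["yield"]))
        assert len(series) == fx.truth["n_present_years"]
        diffs = build_first_differences(
            series, seasonal[seasonal["season"] == "cool"]
        )
        # one interior gap year: pairs = present years - 2
        assert diffs.n_pairs == fx.truth["n_pairs"]
        assert diffs.n_pairs == fx.truth["n_present_years"] - 2

    def test_toy_missingdays_qc_counts(self):
        fx = make_fixture("toy-missingdays")
        clean, report = impute(fx.weather)
        assert report.n_missing_replaced == 3 * 5  # 3 days x 5 variables
        assert report.n_missing_days == 3
        assert not clean.isna().any().any()
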