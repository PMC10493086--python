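"""End-to-end orchestration: config, stage sequencing, table writing.

``run_pipeline`` executes the full analysis from a single configuration:
weather QC → seasonal aggregation → climate trends → per-cultivar
first-difference regressions → group summaries and correlations →
yield-change projections, writing one CSV per stage plus a QC log and a
run manifest (config hash + package version).  Reruns on identical
inputs are bit-identical; any stage error aborts with a stage-named
message and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InsufficientDataError
from .grouping import (
    CultivarGroup,
    build_groups,
    climate_delta_correlations,
    pairwise_yield_correlations,
    summarize_group,
)
from .projection import period_delta, project_group
from .reference import ANALYSIS_PERIODS, CULTIVAR_SPANS, GAP_YEARS, REFERENCE_GROUPS
from .regression import CLIMATE_VARS, FirstDifferenceYieldModel
from .simulate import (
    CultivarSpec,
    WeatherScenario,
    YieldScenario,
    synth_weather,
    synth_yields,
)
from .trends import SeasonalTrendModel, trend_total_change
from .weather import DEFAULT_SEASONS, SeasonDefinition, aggregate_seasons, impute

__all__ = [
    "AnalysisConfig",
    "run_pipeline",
    "simulate_inputs",
    "default_weather_scenario",
    "default_yield_scenarios",
    "render_report",
]

logger = logging.getLogger(__name__)

OUTPUT_TABLES = (
    "seasonal_climate.csv",
    "climate_trends.csv",
    "regression_results.csv",
    "group_summary.csv",
    "correlations.csv",
    "yield_changes.csv",
)


def _parse_md(s: str) -> tuple[int, int]:
    m, d = s.split("-")
    return int(m), int(d)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    weather_csv: str
    yield_csv: str
    seasons: tuple[SeasonDefinition, ...] = DEFAULT_SEASONS
    groups: tuple[Mapping, ...] = ()
    spans: Mapping[str, Mapping[str, tuple[int, int]]] = field(default_factory=dict)
    periods: tuple[tuple[int, int], ...] = tuple(ANALYSIS_PERIODS)
    outlier_z: float = 4.0
    min_pairs: int = 6
    delta_mode: str = "period-local"
    percent_times_100: bool = True
    grouping_mode: str = "config"

    @classmethod
    def from_mapping(cls, data: Mapping, base_dir: Path | None = None) -> "AnalysisConfig":
        base = Path(base_dir) if base_dir else Path(".")
        try:
            weather_csv = str(base / data["weather_csv"])
            yield_csv = str(base / data["yield_csv"])
        except KeyError as exc:
            raise ConfigurationError(f"config missing required key {exc}") from None
        seasons = DEFAULT_SEASONS
        if isinstance(data.get("seasons"), list):
            seasons = tuple(
                SeasonDefinition(s["name"], _parse_md(s["start"]), _parse_md(s["end"]))
                for s in data["seasons"]
            )
        groups = tuple(data.get("groups", ()))
        spans = {
            season: {c: tuple(sp) for c, sp in by.items()}
            for season, by in data.get("spans", {}).items()
        }
        periods = tuple(tuple(p) for p in data.get("periods", ANALYSIS_PERIODS))
        return cls(
            weather_csv=weather_csv,
            yield_csv=yield_csv,
            seasons=seasons,
            groups=groups,
            spans=spans,
            periods=periods,
            outlier_z=float(data.get("outlier_z", 4.0)),
            min_pairs=int(data.get("min_pairs", 6)),
            delta_mode=str(data.get("delta_mode", "period-local")),
            percent_times_100=bool(data.get("percent_times_100", True)),
            grouping_mode=str(data.get("grouping_mode", "config")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_mapping(data, base_dir=path.parent)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _season_of(config: AnalysisConfig, name: str) -> SeasonDefinition:
    for s in config.seasons:
        if s.name == name:
            return s
    raise ConfigurationError(f"unknown season {name!r}")


def _write_csv(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, index=False)
    written.append(path)


def run_pipeline(config: AnalysisConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the output tables under ``out_dir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_pipeline(config, out, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_pipeline(config: AnalysisConfig, out: Path, written: list[Path]) -> dict:
    for key, path in (("weather", config.weather_csv), ("yield", config.yield_csv)):
        if not Path(path).exists():
            raise ConfigurationError(f"startup: {key} file not found: {path}")

    # --- stage: weather QC -------------------------------------------------
    weather = pd.read_csv(config.weather_csv, parse_dates=["date"])
    clean, report = impute(weather, outlier_z=config.outlier_z)
    (out / "qc_log.txt").write_text(report.to_log())
    written.append(out / "qc_log.txt")

    # --- stage: seasonal aggregation --------------------------------------
    seasonal = aggregate_seasons(clean, seasons=config.seasons, report=report)
    _write_csv(seasonal, out / "seasonal_climate.csv", written)

    # --- stage: climate trends ---------------------------------------------
    trend_rows = []
    for season in config.seasons:
        sub = seasonal[seasonal["season"] == season.name]
        for v in CLIMATE_VARS:
            fit = SeasonalTrendModel(
                sub["year"].to_numpy(float), sub[v].to_numpy(float),
                variable=v, season=season.name,
            ).fit()
            row = {
                "season": season.name,
                "variable": v,
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "p": fit.p_slope,
                "r2": fit.r2,
                "marker": fit.marker,
            }
            full_span = (int(sub["year"].min()), int(sub["year"].max()))
            row[f"delta_total_{full_span[0]}_{full_span[1]}"] = trend_total_change(
                fit, *full_span
            ).delta_total
            for period in config.periods:
                d = period_delta(seasonal, v, season.name, tuple(period),
                                 mode=config.delta_mode)
                row[f"delta_total_{period[0]}_{period[1]}"] = d.delta_total
            trend_rows.append(row)
    _write_csv(pd.DataFrame(trend_rows), out / "climate_trends.csv", written)

    # --- stage: first-difference regressions -------------------------------
    yields = pd.read_csv(config.yield_csv)
    pct_scale = 1.0 if config.percent_times_100 else 0.01
    results: dict[tuple[str, str], object] = {}
    reg_rows = []
    for (season_name, cultivar), grp in yields.groupby(["season", "cultivar"]):
        series = dict(zip(grp["year"].astype(int), grp["yield"].astype(float)))
        clim = seasonal[seasonal["season"] == season_name]
        model = FirstDifferenceYieldModel.from_series(
            series, clim, cultivar=str(cultivar), season=str(season_name),
            min_pairs=config.min_pairs,
        )
        try:
            res = model.fit()
        except InsufficientDataError as exc:
            logger.warning("regression skipped: %s", exc)
            continue
        results[(season_name, str(cultivar))] = res
        reg_rows.append(
            {
                "season": season_name,
                "cultivar": cultivar,
                "n_pairs": res.n_pairs,
                "beta0": res.beta0,
                **{f"beta_{v}": res.beta[v] for v in CLIMATE_VARS},
                **{f"pct_{v}": res.pct[v] * pct_scale for v in CLIMATE_VARS},
                "r2": res.r2,
            }
        )
    _write_csv(
        pd.DataFrame(reg_rows).sort_values(["season", "cultivar"]),
        out / "regression_results.csv", written,
    )

    # --- stage: grouping and correlations ----------------------------------
    groups: list[CultivarGroup] = []
    for season in config.seasons:
        spans = config.spans.get(season.name, {})
        season_groups = [g for g in config.groups if g.get("season") == season.name]
        if not spans and not season_groups:
            continue
        groups.extend(
            build_groups(
                spans,
                season=season.name,
                mode=config.grouping_mode,
                config_groups=season_groups or None,
            )
        )

    summary_rows = []
    corr_frames = []
    for g in groups:
        fitted = [results[(g.season, m)] for m in g.members
                  if (g.season, m) in results]
        if fitted:
            s = summarize_group(fitted, group_id=g.group_id, season=g.season)
            for v in CLIMATE_VARS:
                summary_rows.append(
                    {
                        "season": g.season,
                        "group": g.group_id,
                        "period": f"{g.period[0]}-{g.period[1]}",
                        "variable": v,
                        "mean_pct": s.mean[v] * pct_scale,
                        "sd_pct": s.sd[v] * pct_scale,
                        "excluded": g.excluded,
                    }
                )
        member_series = {
            m: dict(zip(
                yields[(yields["season"] == g.season) & (yields["cultivar"] == m)]["year"].astype(int),
                yields[(yields["season"] == g.season) & (yields["cultivar"] == m)]["yield"].astype(float),
            ))
            for m in g.members
        }
        cm = pairwise_yield_correlations(g, member_series)
        long = cm.to_long()
        long.insert(0, "season", g.season)
        corr_frames.append(long)
    for season in config.seasons:
        cm = climate_delta_correlations(seasonal, season.name)
        long = cm.to_long()
        long.insert(0, "season", season.name)
        corr_frames.append(long)
    _write_csv(pd.DataFrame(summary_rows), out / "group_summary.csv", written)
    _write_csv(
        pd.concat(corr_frames, ignore_index=True) if corr_frames
        else pd.DataFrame(columns=["season", "var_a", "var_b", "r", "n", "marker"]),
        out / "correlations.csv", written,
    )

    # --- stage: projection --------------------------------------------------
    proj_frames = []
    for g in groups:
        if g.excluded:
            logger.info("group %s (%s) excluded from projections", g.group_id, g.season)
            continue
        fitted = [results[(g.season, m)] for m in g.members
                  if (g.season, m) in results]
        if not fitted:
            continue
        deltas = {
            v: period_delta(seasonal, v, g.season, tuple(g.period),
                            mode=config.delta_mode)
            for v in CLIMATE_VARS
        }
        proj_frames.append(project_group(g, fitted, deltas))
    yield_changes = (
        pd.concat(proj_frames, ignore_index=True).drop(columns=["excluded"])
        if proj_frames
        else pd.DataFrame(
            columns=["season", "group", "period", "variable",
                     "mean_total_relative", "sd_total_relative",
                     "mean_annual_actual", "sd_annual_actual", "n_years"]
        )
    )
    _write_csv(yield_changes, out / "yield_changes.csv", written)

    manifest = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "delta_mode": config.delta_mode,
        "percent_times_100": config.percent_times_100,
        "outputs": sorted(p.name for p in written),
        "n_regressions": len(reg_rows),
        "n_groups": len(groups),
        "qc": {
            "missing_replaced": report.n_missing_replaced,
            "outliers_replaced": report.n_outliers_replaced,
            "unresolved": report.n_unresolved,
            "fraction_missing_days": report.fraction_missing_days,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Synthetic input generation
# ---------------------------------------------------------------------------


def default_weather_scenario(seed: int = 0) -> WeatherScenario:
    """The standard 95-year synthetic station scenario."""
    return WeatherScenario(seed=seed)


def default_yield_scenarios(seed: int = 0) -> list[YieldScenario]:
    """Per-season synthetic yield scenarios over the reference trial layout.

    Ground-truth sensitivities are fixed, documented values: cool-season
    yields respond positively to temperature and sunshine and negatively
    to DTR and rainfall; warm-season yields respond negatively to
    temperature (already above optimum).  Technology trend 15 kg/ha/yr,
    yield noise 300 kg/ha.
    """
    truth = {
        "cool": dict(intercept=3000.0, tech_trend=15.0, beta_T=100.0,
                     beta_DTR=-60.0, beta_R=-0.6, beta_S=1.5, noise_sd=300.0),
        "warm": dict(intercept=6200.0, tech_trend=15.0, beta_T=-80.0,
                     beta_DTR=-30.0, beta_R=-0.5, beta_S=1.0, noise_sd=300.0),
    }
    scenarios = []
    for i, season in enumerate(("cool", "warm")):
        cultivars = [
            CultivarSpec(id=cid, season=season, first_year=sp[0], last_year=sp[1],
                         **truth[season])
            for cid, sp in CULTIVAR_SPANS[season].items()
        ]
        scenarios.append(
            YieldScenario(cultivars, gap_years=GAP_YEARS[season], seed=seed + i + 1)
        )
    return scenarios


def simulate_inputs(
    out_dir: str | Path,
    weather_scenario: WeatherScenario | None = None,
    yield_scenarios: Sequence[YieldScenario] | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Generate pipeline-ready weather and yield CSVs plus a config file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wscn = weather_scenario or default_weather_scenario(seed=seed)
    yscns = list(yield_scenarios) if yield_scenarios is not None \
        else default_yield_scenarios(seed=seed)

    weather = synth_weather(wscn)
    weather_path = out / "weather.csv"
    weather.assign(date=weather["date"].dt.strftime("%Y-%m-%d")).to_csv(
        weather_path, index=False
    )

    clean, report = impute(weather)
    seasonal = aggregate_seasons(clean, report=report)
    tables = [synth_yields(s, seasonal) for s in yscns]
    yields = (pd.concat(tables, ignore_index=True) if tables
              else pd.DataFrame(columns=["cultivar", "season", "year", "yield"]))
    yield_path = out / "yields.csv"
    yields.to_csv(yield_path, index=False)

    config = {
        "weather_csv": "weather.csv",
        "yield_csv": "yields.csv",
        "periods": [list(p) for p in ANALYSIS_PERIODS],
        "spans": {
            season: {c: list(sp) for c, sp in CULTIVAR_SPANS[season].items()}
            for season in ("cool", "warm")
        },
        "groups": [
            dict(g, season=season, period=list(g["period"]))
            for season in ("cool", "warm")
            for g in REFERENCE_GROUPS[season]
        ],
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return {"weather": weather_path, "yields": yield_path, "config": config_path}


def render_report(run_dir: str | Path, decimals: int = 2) -> str:
    """Round the full-precision output tables into a compact text report."""
    run = Path(run_dir)
    chunks = []
    for name in OUTPUT_TABLES:
        path = run / name
        if not path.exists():
            continue
        df = pd.read_csv(path)
        chunks.append(f"== {name} ==\n{df.round(decimals).to_string(index=False)}\n")
    return "\n".join(chunks)
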