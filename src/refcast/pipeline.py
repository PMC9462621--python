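"""End-to-end orchestration: simulate -> decompose -> forecast -> evaluate
-> cohort statistics, with a reproducibility manifest.

A single global seed deterministically derives a named substream per stage
(via ``numpy.random.SeedSequence`` spawned with a stable stage ordering), so
any stage can be re-run in isolation with the same randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .arima import stl_arima_forecast
from .base import adapter_from_estimator
from .cohort import PeriodDefinition, default_periods, period_summary
from .comparators import (
    AdditiveRegressionForecaster,
    HistoricalAverageForecaster,
    RandomWalkForecaster,
)
from .arima import StlArimaForecaster
from .decomposition import stl_decompose
from .errors import InvalidConfigError, RefcastError
from .evaluation import CVPlan, cross_validate
from .synthetic import (
    PeriodProfile,
    SeriesGeneratorConfig,
    generate_monthly_series,
    generate_referral_records,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate_series", "simulate_records", "forecast", "evaluate", "cohort")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Named per-stage seeds derived deterministically from the global seed."""
    children = np.random.SeedSequence(global_seed).spawn(len(STAGES))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(STAGES, children)}


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    output_dir: str
    seed: int = 0
    series_csv: str | None = None          # load instead of simulating
    generator: SeriesGeneratorConfig | None = None
    n_records_per_period: int = 90
    horizon: int = 12
    level: float = 0.95
    grid: tuple = (3, 2, 3)
    cv_plan: CVPlan = field(default_factory=lambda: CVPlan(n_repetitions=20))
    models: tuple = ("stl_arima", "random_walk", "historical_average", "additive")
    periods: list[PeriodDefinition] = field(default_factory=default_periods)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise InvalidConfigError(f"{path}: config must be a mapping")
        if "generator" in data and data["generator"] is not None:
            data["generator"] = SeriesGeneratorConfig(**{
                **data["generator"],
                "seasonal_amplitudes": tuple(
                    tuple(h) for h in data["generator"].get(
                        "seasonal_amplitudes", ((1, 0.10, 0.05),))
                ),
                "shock_window": tuple(data["generator"]["shock_window"])
                if data["generator"].get("shock_window") else None,
            })
        if "cv_plan" in data and data["cv_plan"] is not None:
            plan = dict(data["cv_plan"])
            if "horizons" in plan:
                plan["horizons"] = tuple(plan["horizons"])
            data["cv_plan"] = CVPlan(**plan)
        if "periods" in data and data["periods"] is not None:
            data["periods"] = [PeriodDefinition(**p) for p in data["periods"]]
        if "grid" in data:
            data["grid"] = tuple(data["grid"])
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)


def _build_models(config: RunConfig):
    registry = {
        "stl_arima": lambda: StlArimaForecaster(level=config.level,
                                                p_max=config.grid[0],
                                                d_max=config.grid[1],
                                                q_max=config.grid[2]),
        "random_walk": lambda: RandomWalkForecaster(level=config.level),
        "historical_average": lambda: HistoricalAverageForecaster(level=config.level),
        "additive": lambda: AdditiveRegressionForecaster(level=config.level),
    }
    adapters = []
    for name in config.models:
        if name not in registry:
            raise InvalidConfigError(f"unknown model {name!r}; known: {sorted(registry)}")
        adapters.append(adapter_from_estimator(name, registry[name]()))
    return adapters


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write all artifacts plus a checksum manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds, "files": {}}

    def _run(stage: str, fn):
        try:
            return fn()
        except RefcastError as exc:
            raise RefcastError(
                f"stage {stage!r} failed [{type(exc).__name__}]: {exc}"
            ) from exc

    # --- series ---------------------------------------------------------
    def _series():
        if config.series_csv:
            return rio.read_series_csv(config.series_csv)
        gen = config.generator or SeriesGeneratorConfig()
        gen = dataclasses.replace(gen, seed=seeds["simulate_series"])
        return generate_monthly_series(gen)

    series = _run("simulate", _series)
    rio.write_series_csv(series, out / "series.csv")

    # --- records --------------------------------------------------------
    def _records():
        profiles = [
            PeriodProfile(start_month=p.start_month, end_month=p.end_month)
            for p in config.periods if p.name != "forecast"
        ]
        return generate_referral_records(
            config.n_records_per_period, profiles, seeds["simulate_records"]
        )

    records = _run("simulate", _records)
    rio.write_records_csv(records, out / "records.csv")

    # --- decomposition --------------------------------------------------
    decomp = _run("decompose", lambda: stl_decompose(series, period=12))
    decomp.to_frame().to_csv(out / "decomposition.csv", index=False)

    # --- forecast -------------------------------------------------------
    forecast = _run(
        "forecast",
        lambda: stl_arima_forecast(series, config.horizon, config.grid, config.level),
    )
    rio.write_forecast_csv(forecast, series.future_months(config.horizon),
                           out / "forecast.csv")

    # --- evaluation -----------------------------------------------------
    models = _build_models(config)
    plan = dataclasses.replace(config.cv_plan, seed=seeds["evaluate"])
    table = _run("evaluate", lambda: cross_validate(series, models, plan))
    table.to_csv(out / "scores.csv")

    # --- cohort statistics ----------------------------------------------
    summary = _run("cohort-stats",
                   lambda: period_summary(records, series, config.periods))
    summary["summary"].to_csv(out / "cohort_summary.csv", index=False)
    stats_json = {}
    for key in ("volume_kruskal_wallis", "grade_chi_square"):
        if key in summary:
            stats_json[key] = summary[key]
    if "grade_pairwise" in summary:
        stats_json["grade_pairwise"] = summary["grade_pairwise"].to_dict("records")
    (out / "cohort_stats.json").write_text(json.dumps(stats_json, indent=2, default=float))

    for f in sorted(out.glob("*.csv")) + [out / "cohort_stats.json"]:
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
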