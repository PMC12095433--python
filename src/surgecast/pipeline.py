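"""End-to-end pipeline orchestration.

Stage order: simulate (or ingest) -> exclude/split/impute -> comorbidity
encoding + decomposition -> LOS forest -> volume forecaster -> census model
grid -> report.  Model selection artifacts (imputer, vocabulary,
decomposition, historic mean LOS, forest) are fitted on the training window
for validation scoring, then refit on train+validation before the test window
is touched.  All randomness flows from named seeds in the configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .calendars import default_holidays
from .census import ForecastEvaluation, relative_error_report, run_model_grid
from .config import ForestSpec, GeneratorConfig, SarimaxSpec, SplitSpec
from .los import (
    LOSFeatureSchema,
    assemble_features,
    compute_historic_mean_los,
    evaluate_los,
    fit_forest,
    permutation_importance,
    predict_los,
)
from .preprocessing import (
    apply_imputer,
    build_onehot_matrix,
    chronological_split,
    exclude_invalid,
    fit_decomposition,
    fit_imputer,
    select_top_n_codes,
)
from .synthetic import encounters_from_csv, encounters_to_csv, generate_encounters, inject_missingness
from .volume import build_daily_counts, correlogram, rolling_forecast

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_report"]


def _default_generator() -> GeneratorConfig:
    return GeneratorConfig(holidays=default_holidays())


class PipelineConfig(BaseModel):
    """Single configuration object for a full pipeline run."""

    generator: GeneratorConfig = Field(default_factory=_default_generator)
    encounters_csv: Optional[str] = None  # ingest instead of simulating
    split: SplitSpec = Field(default_factory=SplitSpec)
    top_n_codes: int = 1750
    n_components: int = 12
    decomposition_method: str = "truncated_svd"
    forest: ForestSpec = Field(default_factory=ForestSpec)
    volume_spec: SarimaxSpec = Field(default_factory=lambda: SarimaxSpec(P=0, D=1, Q=1, m=7, exog_names=("holidays",)))
    refit_census_models: bool = False
    include_bounds: bool = True
    importance_repeats: int = 10
    seed: int = 0

    model_config = {"frozen": True}

    def content_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    encounters: pd.DataFrame
    calendar: Any
    ground_truth: dict | None
    exclusion_report: dict
    los_val_evaluation: Any
    los_test_evaluation: Any
    los_baseline_rmse: float
    feature_importance: pd.DataFrame
    predicted_los: np.ndarray
    volume_result: Any
    volume_correlogram: Any
    grid: list[ForecastEvaluation]
    relative_error: dict
    manifest: dict = dc_field(default_factory=dict)


def _fit_los_stage(window: pd.DataFrame, cfg: PipelineConfig, eval_table: pd.DataFrame):
    """Fit imputer/vocabulary/decomposition/forest on one window, score another."""
    imputer = fit_imputer(window)
    window = apply_imputer(imputer, window)
    eval_table = apply_imputer(imputer, eval_table)

    vocab = select_top_n_codes(window, cfg.top_n_codes)
    matrix = build_onehot_matrix(window, vocab)
    k = min(cfg.n_components, min(matrix.shape))
    decomposition = fit_decomposition(matrix, cfg.decomposition_method, k)
    historic = compute_historic_mean_los(window)
    schema = LOSFeatureSchema.fit(window, k)

    X_fit, y_fit = assemble_features(window, decomposition, historic, schema)
    X_eval, y_eval = assemble_features(eval_table, decomposition, historic, schema)
    forest = fit_forest(X_fit, y_fit, cfg.forest)
    evaluation = evaluate_los(forest, X_eval, y_eval)

    baseline_pred = historic.lookup(eval_table["surgery_type"])
    baseline_rmse = float(np.sqrt(np.mean((baseline_pred - y_eval) ** 2)))
    artifacts = {
        "imputer": imputer,
        "decomposition": decomposition,
        "historic": historic,
        "schema": schema,
        "forest": forest,
    }
    return artifacts, evaluation, baseline_rmse, (X_eval, y_eval)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in dependency order and return all stage outputs."""
    manifest: dict[str, Any] = {
        "config_hash": config.content_hash(),
        "package_version": __version__,
        "stage_seconds": {},
        "warnings": [],
    }

    def timed(name: str):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, *exc):
                manifest["stage_seconds"][name] = round(time.perf_counter() - self_inner.t0, 3)

        return _T()

    with timed("simulate"):
        if config.encounters_csv is not None:
            encounters = encounters_from_csv(config.encounters_csv)
            from .calendars import generate_calendar

            calendar = generate_calendar(
                int(encounters["day_index"].max()) + 1, config.generator.day0_weekday, config.generator.holidays
            )
            ground_truth = None
        else:
            encounters, calendar, ground_truth = generate_encounters(config.generator)
            encounters = inject_missingness(encounters, config.generator.missingness_rates, seed=config.seed + 1)

    with timed("preprocess"):
        encounters, exclusion_report = exclude_invalid(encounters)
        split = config.split
        train, val, test = chronological_split(encounters, split)

    with timed("fit_los"):
        # validation protocol: fit on train, score on validation
        _, val_eval, _, _ = _fit_los_stage(train, config, val)
        # final protocol: refit on train+validation, score on test
        trainval = pd.concat([train, val], ignore_index=True)
        artifacts, test_eval, baseline_rmse, (X_test, y_test) = _fit_los_stage(trainval, config, test)
        importance = permutation_importance(
            artifacts["forest"], X_test, y_test, n_repeats=config.importance_repeats, seed=config.seed + 2
        )
        # per-case LOS predictions for the whole calendar (schedule-known inputs)
        all_imputed = apply_imputer(artifacts["imputer"], encounters)
        X_all, _ = assemble_features(all_imputed, artifacts["decomposition"], artifacts["historic"], artifacts["schema"])
        predicted_los = predict_los(artifacts["forest"], X_all)

    with timed("forecast_volume"):
        counts = build_daily_counts(all_imputed, calendar)
        vol_corr = correlogram(counts, max_lag=28)
        holiday_series = [
            type(counts)(calendar=calendar, values=calendar.holiday_indicator.astype(float), name="holidays")
        ]
        volume_result = rolling_forecast(
            counts,
            config.volume_spec,
            exog=holiday_series,
            origin_start=split.val_end_day - 1,
            step=7,
            horizon=7,
            refit=False,
        )

    with timed("forecast_beds"):
        # the observed census uses imputed LOS for the handful of missing values
        grid = run_model_grid(
            all_imputed,
            calendar,
            split,
            predicted_los,
            artifacts["historic"],
            los_fit_window_observed=apply_imputer(artifacts["imputer"], trainval)["los_days"].to_numpy(float),
            refit=config.refit_census_models,
            include_bounds=config.include_bounds,
        )
        from .census import build_census

        observed = build_census(all_imputed, calendar)
        bound_exogs = {"perfect_census", "surgery_mean_census"}
        candidates = [
            ev for ev in grid if np.isfinite(ev.rmse) and not (set(ev.exog_names) & bound_exogs)
        ]
        best = min(candidates, key=lambda ev: ev.rmse)
        relative = relative_error_report(best, capacity_reference=float(observed.values.max()), observed=observed)

    return PipelineResult(
        config=config,
        encounters=encounters,
        calendar=calendar,
        ground_truth=ground_truth,
        exclusion_report=exclusion_report,
        los_val_evaluation=val_eval,
        los_test_evaluation=test_eval,
        los_baseline_rmse=baseline_rmse,
        feature_importance=importance,
        predicted_los=predicted_los,
        volume_result=volume_result,
        volume_correlogram=vol_corr,
        grid=grid,
        relative_error=relative,
        manifest=manifest,
    )


_PROTOCOL_LABEL = {"long_term": "> 2 weeks", "two_week": "2 weeks", "same_day": "Same day"}


def render_report(
    grid: list[ForecastEvaluation],
    los_evaluation: Any = None,
    volume_result: Any = None,
) -> tuple[str, dict]:
    """Human-readable grid table plus a full-precision JSON-ready report."""
    lines = []
    header = f"{'Forecasting Time Point':<24}{'Model':<28}{'Exogenous Variable':<38}{'RMSE':>8}{'SD':>8}"
    lines.append(header)
    lines.append("-" * len(header))
    if not grid:
        lines.append("(no grid evaluations)")
    for ev in grid:
        exog = ", ".join(ev.exog_names) if ev.exog_names else "none"
        lines.append(
            f"{_PROTOCOL_LABEL.get(ev.protocol, ev.protocol):<24}{ev.spec_label:<28}{exog:<38}"
            f"{ev.rmse:>8.2f}{ev.sd:>8.2f}"
        )
    report: dict[str, Any] = {"grid": [ev.to_dict() for ev in grid]}
    if los_evaluation is not None:
        report["los"] = {"rmse": los_evaluation.rmse, "mae": los_evaluation.mae, "strata": los_evaluation.strata}
        lines.append("")
        lines.append(f"LOS model: RMSE {los_evaluation.rmse:.2f} d, MAE {los_evaluation.mae:.2f} d")
    if volume_result is not None:
        report["volume"] = {"rolling_rmse": volume_result.rmse, "n_forecasts": volume_result.n_forecasts}
        lines.append(f"Volume model: rolling 1-week-ahead RMSE {volume_result.rmse:.2f} cases/day")
    return "\n".join(lines), report


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, str]:
    """Write stage outputs and the manifest; returns file digests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    encounters_to_csv(result.encounters, out / "encounters.csv")
    result.calendar.to_frame().to_csv(out / "calendar.csv", index=False)
    if result.ground_truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(result.ground_truth, indent=1))
    pd.DataFrame(
        {"case_id": result.encounters["case_id"], "predicted_los_days": result.predicted_los}
    ).to_csv(out / "predicted_los.csv", index=False)
    result.feature_importance.to_csv(out / "feature_importance.csv", index=False)
    text, report = render_report(result.grid, result.los_test_evaluation, result.volume_result)
    (out / "report.txt").write_text(text + "\n")
    report["relative_error"] = result.relative_error
    (out / "report.json").write_text(json.dumps(report, indent=1))

    digests = {}
    for path in sorted(out.iterdir()):
        digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    result.manifest["output_digests"] = digests
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
    return digests
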