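"""Masked RMSE, walk-forward test evaluation, configuration comparison.

The headline metric is root-mean-squared error in mg/dL, pooled over all
horizon positions of all test windows — but computed only over
sensor-recorded targets: samples that were gap-filled during
preprocessing carry an ``imputed`` provenance flag and are excluded, so
the error reflects real glucose, not the interpolator.

Walk-forward evaluation applies a frozen trained model to consecutive
non-overlapping test windows (stride = history length) with no
retraining between steps.  ``compare_configurations`` repeats the full
train-and-evaluate cycle per (feature configuration, horizon, seed) and
reports the seed-median RMSE per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import PatientRecord, ValidationError
from .dataset import (
    FeatureConfig,
    WindowSpec,
    apply_standardizer,
    assemble_feature_matrix,
    fit_standardizer,
    holdout_split,
    make_windows,
)
from .forecaster import (
    ModelSpec,
    TrainedForecaster,
    TrainingSpec,
    build_forecaster,
    predict_horizon,
    train_forecaster,
)
from .physio import CarbKineticsParams, InsulinKineticsParams

log = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """One evaluation run's results and bookkeeping counts."""

    patient_id: str
    config_name: str
    horizon_minutes: int
    rmse: float
    n_evaluated: int
    n_masked: int
    per_example_rmse: np.ndarray = field(repr=False)
    per_step_rmse: np.ndarray = field(repr=False)
    seed: int | None = None

    @property
    def n_total(self) -> int:
        return self.n_evaluated + self.n_masked


def rmse_masked(
    predictions: np.ndarray,
    actuals: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """RMSE over evaluable positions only (mask True = evaluable).

    An all-masked input is an error, not zero — a silent 0 would read as
    a perfect forecast.
    """
    predictions = np.asarray(predictions, float)
    actuals = np.asarray(actuals, float)
    if predictions.shape != actuals.shape:
        raise ValidationError(
            f"shape mismatch: {predictions.shape} vs {actuals.shape}"
        )
    if mask is None:
        mask = np.ones(predictions.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != predictions.shape:
        raise ValidationError("mask shape must match predictions")
    if not mask.any():
        raise ValidationError("no evaluable positions (all masked)")
    err = predictions[mask] - actuals[mask]
    return float(np.sqrt(np.mean(err**2)))


def walk_forward_evaluate(
    model: TrainedForecaster,
    test_matrix: np.ndarray,
    test_target,
    window_spec: WindowSpec,
    patient_id: str = "",
    config_name: str = "",
    seed: int | None = None,
) -> EvalReport:
    """Apply a frozen model to consecutive non-overlapping test windows.

    ``test_matrix``/``test_target`` come from
    :func:`~glucoforecast.dataset.assemble_feature_matrix` on the test
    part.  Imputed and out-of-range target positions are masked out of
    the pooled RMSE; per-example and per-horizon-step breakdowns are
    returned alongside.
    """
    if window_spec.horizon_len != model.horizon_len:
        raise ValidationError(
            f"window horizon {window_spec.horizon_len} does not match the "
            f"model's {model.horizon_len}"
        )
    inputs, outputs, mask = make_windows(test_matrix, test_target, window_spec)
    preds = predict_horizon(model, inputs)
    rmse = rmse_masked(preds, outputs, mask)
    sq = (preds - outputs) ** 2
    with np.errstate(invalid="ignore"):
        per_example = np.sqrt(
            np.where(mask, sq, 0.0).sum(axis=1)
            / np.maximum(mask.sum(axis=1), 1)
        )
        per_example[~mask.any(axis=1)] = np.nan
        step_counts = mask.sum(axis=0)
        per_step = np.sqrt(
            np.where(mask, sq, 0.0).sum(axis=0) / np.maximum(step_counts, 1)
        )
        per_step[step_counts == 0] = np.nan
    report = EvalReport(
        patient_id=patient_id,
        config_name=config_name,
        horizon_minutes=window_spec.horizon_minutes,
        rmse=rmse,
        n_evaluated=int(mask.sum()),
        n_masked=int((~mask).sum()),
        per_example_rmse=per_example,
        per_step_rmse=per_step,
        seed=seed,
    )
    log.info(
        "walk-forward: %d examples, %d evaluated / %d masked positions, "
        "RMSE %.2f mg/dL", len(inputs), report.n_evaluated, report.n_masked,
        rmse,
    )
    return report


def persistence_baseline_rmse(
    test_matrix: np.ndarray, test_target, window_spec: WindowSpec
) -> float:
    """Naive forecast: repeat the last observed CGM value over the horizon."""
    inputs, outputs, mask = make_windows(test_matrix, test_target, window_spec)
    preds = np.repeat(inputs[:, -1, 0:1], window_spec.horizon_len, axis=1)
    return rmse_masked(preds, outputs, mask)


def train_and_evaluate(
    record: PatientRecord,
    config: FeatureConfig,
    window_spec: WindowSpec,
    model_spec: ModelSpec,
    training_spec: TrainingSpec,
    carb_params: CarbKineticsParams | None = None,
    insulin_params: InsulinKineticsParams | None = None,
    train_fraction: float = 0.8,
    train_stride: int = 1,
) -> tuple[TrainedForecaster, EvalReport]:
    """Full cycle on one preprocessed record: fit, then walk-forward test.

    The training part is split chronologically into train/validation
    (default 80/20); the standardizer is fit on the training block only.
    Training windows slide with ``train_stride`` (default 1, the dense
    sliding-window scheme used during window-size tuning — it multiplies
    the number of training examples by the history length); test
    evaluation always uses the non-overlapping walk-forward geometry.
    """
    matrix, target = assemble_feature_matrix(
        record, config, carb_params, insulin_params, part="train"
    )
    tr_idx, val_idx = holdout_split(len(matrix), train_fraction)
    state = fit_standardizer(matrix[tr_idx])
    z = apply_standardizer(state, matrix)
    z_target = (target.values - state.mean[0]) / state.sd[0]

    train_windows = WindowSpec(window_spec.history_len,
                               window_spec.horizon_len, train_stride)
    tx, ty, _ = make_windows(z[tr_idx], z_target[tr_idx], train_windows,
                             target_provenance=target.provenance[tr_idx],
                             tail="strict")
    if len(val_idx) >= window_spec.history_len + window_spec.horizon_len:
        vx, vy, _ = make_windows(z[val_idx], z_target[val_idx], train_windows,
                                 target_provenance=target.provenance[val_idx],
                                 tail="strict")
        validation = (vx, vy)
    else:
        validation = None

    net = build_forecaster(model_spec, len(config.channels))
    model = train_forecaster(net, tx, ty, training_spec, state,
                             validation=validation, model_spec=model_spec)

    test_matrix, test_target = assemble_feature_matrix(
        record, config, carb_params, insulin_params, part="test"
    )
    report = walk_forward_evaluate(
        model, test_matrix, test_target, window_spec,
        patient_id=record.patient_id, config_name=config.name,
        seed=training_spec.seed,
    )
    return model, report


def compare_configurations(
    record: PatientRecord,
    configs: list[FeatureConfig],
    horizons_min: tuple[int, ...] = (30, 60),
    model_spec: ModelSpec | None = None,
    training_spec: TrainingSpec | None = None,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    carb_params: CarbKineticsParams | None = None,
    insulin_params: InsulinKineticsParams | None = None,
) -> tuple[pd.DataFrame, list[EvalReport]]:
    """Train/evaluate every (config, horizon, seed) cell; median per cell.

    Returns a tidy DataFrame (one row per cell run) whose groupby median
    reproduces the configuration-comparison grid, plus the full reports.
    """
    model_spec = model_spec or ModelSpec()
    training_spec = training_spec or TrainingSpec()
    rows, reports = [], []
    for horizon in horizons_min:
        if horizon % 5 != 0:
            raise ValidationError("horizon must be a multiple of 5 minutes")
        spec_h = ModelSpec(**{**_asdict(model_spec), "horizon_len": horizon // 5})
        wspec = WindowSpec(horizon_len=horizon // 5)
        for config in configs:
            for seed in seeds:
                tspec = TrainingSpec(**{**_asdict(training_spec), "seed": seed})
                _, report = train_and_evaluate(
                    record, config, wspec, spec_h, tspec,
                    carb_params, insulin_params,
                )
                reports.append(report)
                rows.append({
                    "patient": record.patient_id,
                    "config": config.name,
                    "horizon_min": horizon,
                    "seed": seed,
                    "rmse": report.rmse,
                    "n_evaluated": report.n_evaluated,
                })
    table = pd.DataFrame(rows)
    return table, reports


def median_grid(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy comparison table to config × horizon seed-medians."""
    return table.pivot_table(index="config", columns="horizon_min",
                             values="rmse", aggfunc="median")


def _asdict(spec) -> dict:
    from dataclasses import asdict
    return asdict(spec)
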