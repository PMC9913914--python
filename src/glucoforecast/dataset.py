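"""Feature-matrix assembly, windowing, splits and standardisation.

A forecaster example pairs ``history_len`` consecutive multivariate
samples (default 6, i.e. the last half hour of a 5-min grid) with the
next ``horizon_len`` glucose values (6 for a 30-min prediction horizon,
12 for 60 min).  Arrays follow the ``[examples, samples_per_example,
channels]`` convention.

Two split schemes are provided: a simple chronological holdout and a
rolling-origin scheme with a constant validation size where each
successive training set is a superset of the previous one (the semantics
of scikit-learn's ``TimeSeriesSplit``: with ``k`` splits of ``n``
samples, validation size ``floor(n/(k+1))`` and training sizes
``n − (k−i)·val_size``).  For n = 11,611 and k = 5 this yields training
sizes 1,936 / 3,871 / 5,806 / 7,741 / 9,676 with validation 1,935.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler

from .data_model import PatientRecord, Provenance, SampledSeries, ValidationError
from .physio import (
    CarbKineticsParams,
    InsulinKineticsParams,
    active_insulin_series,
    operative_carbs_series,
)

CHANNELS = ("cgm", "operative_carbs", "active_insulin")

_CONFIGS = {
    "C-01": ("cgm",),
    "C-02": ("cgm", "operative_carbs"),
    "C-03": ("cgm", "operative_carbs", "active_insulin"),
}


@dataclass(frozen=True)
class FeatureConfig:
    """Named input-channel configuration.

    C-01 is univariate CGM; C-02 adds operative carbs; C-03 adds active
    insulin.  Channel order is fixed with CGM first (the target channel).
    """

    name: str
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.name not in _CONFIGS:
            raise ValidationError(
                f"unknown configuration {self.name!r}; expected one of "
                f"{sorted(_CONFIGS)}"
            )
        expected = _CONFIGS[self.name]
        if self.channels == ():
            object.__setattr__(self, "channels", expected)
        elif tuple(self.channels) != expected:
            raise ValidationError(
                f"{self.name} must use channels {expected}, got {self.channels}"
            )

    @staticmethod
    def by_name(name: str) -> "FeatureConfig":
        return FeatureConfig(name)


@dataclass(frozen=True)
class WindowSpec:
    """Windowing geometry: history length, horizon length and stride."""

    history_len: int = 6
    horizon_len: int = 6   # 6 → 30-min PH, 12 → 60-min PH
    stride: int | None = None  # default = history_len (non-overlapping)

    def __post_init__(self) -> None:
        if self.stride is None:
            object.__setattr__(self, "stride", self.history_len)
        if min(self.history_len, self.horizon_len, self.stride) < 1:
            raise ValidationError("history_len, horizon_len, stride must be >= 1")

    @property
    def horizon_minutes(self) -> int:
        return self.horizon_len * 5


@dataclass(frozen=True)
class SplitPlan:
    """Rolling-origin split geometry over ``n_total`` ordered samples."""

    n_total: int
    k: int
    val_size: int
    train_sizes: tuple[int, ...]

    def split_indices(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, val_idx) for split i; validation follows training."""
        tr = self.train_sizes[i]
        return np.arange(tr), np.arange(tr, tr + self.val_size)


def rolling_origin_splits(n_total: int, k: int = 5) -> SplitPlan:
    """Plan k expanding-window splits with constant validation size."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    val_size = n_total // (k + 1)
    if val_size < 1:
        raise ValidationError(
            f"n_total={n_total} too small for k={k} splits (need >= {k + 1})"
        )
    train_sizes = tuple(n_total - (k - i) * val_size for i in range(k))
    return SplitPlan(n_total, k, val_size, train_sizes)


def holdout_split(n_total: int, train_fraction: float = 0.8) -> tuple[np.ndarray, np.ndarray]:
    """Chronological holdout: the first ``train_fraction`` of samples train."""
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must lie in (0, 1)")
    cut = int(n_total * train_fraction)
    return np.arange(cut), np.arange(cut, n_total)


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def assemble_feature_matrix(
    record: PatientRecord,
    config: FeatureConfig,
    carb_params: CarbKineticsParams | None = None,
    insulin_params: InsulinKineticsParams | None = None,
    part: str = "train",
) -> tuple[np.ndarray, SampledSeries]:
    """Build the [samples × channels] matrix for one part of a record.

    The CGM part must already be preprocessed (regular grid, fully
    defined).  Physiological channels are computed on the same grid in
    the configuration's channel order; the target is the CGM series with
    its provenance intact so evaluation can mask imputed samples.
    """
    cgm = record.train_cgm if part == "train" else record.test_cgm
    if not isinstance(cgm, SampledSeries):
        raise ValidationError(
            f"{part} CGM is still irregular; run preprocessing first"
        )
    if np.any(~np.isfinite(cgm.values)):
        raise ValidationError(f"{part} CGM contains undefined samples; impute first")
    grid = cgm.grid
    columns = []
    for channel in config.channels:
        if channel == "cgm":
            columns.append(cgm.values)
        elif channel == "operative_carbs":
            # an empty meal log is legal; the channel is simply zero
            columns.append(
                operative_carbs_series(record.meals, grid, carb_params).values
            )
        elif channel == "active_insulin":
            columns.append(
                active_insulin_series(record.boluses, grid, insulin_params).values
            )
        else:  # pragma: no cover - guarded by FeatureConfig
            raise ValidationError(f"unknown channel {channel!r}")
    return np.column_stack(columns), cgm


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def make_windows(
    matrix: np.ndarray,
    target: SampledSeries | np.ndarray,
    spec: WindowSpec,
    target_provenance: np.ndarray | None = None,
    tail: str = "mask",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slice a feature matrix into (inputs, outputs, target_mask).

    Examples start at offsets 0, stride, 2·stride, …; each pairs
    ``history_len`` input rows with the immediately following
    ``horizon_len`` target values.  ``target_mask`` is True where a
    target position is evaluable: a sensor-recorded (non-imputed) sample
    inside the series.

    Tail policy — ``"mask"`` (default) keeps every window whose history
    fits, masking target positions that would fall past the end of the
    series (this reproduces the block-count arithmetic n/stride of the
    study design, e.g. 9288 rows → 1548 examples at history 6, stride 6);
    ``"strict"`` keeps only windows whose history and horizon both fit.
    """
    if tail not in ("mask", "strict"):
        raise ValidationError("tail must be 'mask' or 'strict'")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 1:
        matrix = matrix[:, None]
    if isinstance(target, SampledSeries):
        target_values = target.values
        prov = target.provenance
    else:
        target_values = np.asarray(target, dtype=float)
        prov = (target_provenance if target_provenance is not None
                else np.zeros(len(target_values), dtype=np.int8))
    n = matrix.shape[0]
    if len(target_values) != n:
        raise ValidationError("matrix and target lengths differ")
    h, H, s = spec.history_len, spec.horizon_len, spec.stride
    min_rows = h + (H if tail == "strict" else 0)
    if n < min_rows:
        raise ValidationError(
            f"series of {n} rows too short; need at least {min_rows} "
            f"(history {h}" + (f" + horizon {H})" if tail == "strict" else ")")
        )
    last_offset = n - h if tail == "mask" else n - h - H
    offsets = np.arange(0, last_offset + 1, s)
    n_ex = len(offsets)
    inputs = np.stack([matrix[o:o + h] for o in offsets])
    outputs = np.zeros((n_ex, H))
    mask = np.zeros((n_ex, H), dtype=bool)
    for i, o in enumerate(offsets):
        stop = min(o + h + H, n)
        m = stop - (o + h)
        outputs[i, :m] = target_values[o + h: stop]
        mask[i, :m] = prov[o + h: stop] == Provenance.OBSERVED
    return inputs, outputs, mask


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------

@dataclass
class StandardizerState:
    """Per-channel z-scoring fit on training rows only."""

    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.mean)


def fit_standardizer(matrix: np.ndarray) -> StandardizerState:
    """Estimate per-channel mean/sd from TRAINING rows.

    A zero-variance channel is rejected — it cannot be z-scored and
    usually signals an assembly bug (e.g. an all-zero feature on a record
    with no events standardised jointly with CGM).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 1:
        matrix = matrix[:, None]
    scaler = StandardScaler().fit(matrix)
    sd = np.sqrt(scaler.var_)
    if np.any(sd <= 0):
        bad = np.nonzero(sd <= 0)[0].tolist()
        raise ValidationError(f"channel(s) {bad} have zero variance")
    return StandardizerState(mean=np.asarray(scaler.mean_), sd=sd)


def apply_standardizer(state: StandardizerState, matrix: np.ndarray) -> np.ndarray:
    """(x − mean) / sd per channel; works on 2-D [n, C] or 3-D [n, T, C]."""
    matrix = np.asarray(matrix, dtype=float)
    return (matrix - state.mean) / state.sd


def invert_standardizer(
    state: StandardizerState, matrix: np.ndarray, channel: int = 0
) -> np.ndarray:
    """Map standardised values of one channel back to original units."""
    return np.asarray(matrix, dtype=float) * state.sd[channel] + state.mean[channel]
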