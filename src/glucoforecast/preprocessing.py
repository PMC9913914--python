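"""CGM preprocessing: grid regularisation, gap imputation, median smoothing.

CGM sensors nominally sample every 5 minutes, but sensor changes break the
cadence and leave runs of missing samples.  The pipeline restores time
coherence first (inserting explicitly-missing slots), then fills gaps —
forward-fill for isolated single gaps, linear interpolation for runs of
two or more — and optionally median-smooths the *training* profile to
suppress sensor spikes.  Test data must never be smoothed, and imputed
test samples are excluded from error computation downstream; every stage
therefore records per-sample provenance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import (
    GridSpec,
    Provenance,
    SampledSeries,
    TimedPoints,
    ValidationError,
)

log = logging.getLogger(__name__)


def regularize_grid(
    points: TimedPoints,
    interval: pd.Timedelta = pd.Timedelta(minutes=5),
) -> SampledSeries:
    """Map irregular observations onto a regular grid anchored at the first.

    Every observation lands in its nearest grid slot, unaltered; slots
    that receive no observation are flagged ``inserted_missing`` with an
    undefined (NaN) value.  Two observations competing for one slot is an
    error — that indicates duplicate or sub-interval sampling, which this
    stage must not silently average away.
    """
    if interval <= pd.Timedelta(0):
        raise ValidationError("interval must be positive")
    if len(points) == 0:
        return SampledSeries(GridSpec(pd.Timestamp("1970-01-01"), interval, 0),
                             np.empty(0), np.empty(0, dtype=np.int8))
    times = points.times
    if len(times) > 1 and (not times.is_monotonic_increasing or times.has_duplicates):
        raise ValidationError("observation times must be strictly increasing")
    start = times[0]
    slots = np.floor((times - start) / interval + 0.5).astype(int)
    uniq, counts = np.unique(slots, return_counts=True)
    if np.any(counts > 1):
        clash = uniq[counts > 1]
        raise ValidationError(
            f"{clash.size} grid slot(s) receive multiple observations "
            f"(first collision at slot {clash[0]}, "
            f"t={start + int(clash[0]) * interval})"
        )
    n = int(slots[-1]) + 1
    values = np.full(n, np.nan)
    prov = np.full(n, Provenance.INSERTED_MISSING, dtype=np.int8)
    values[slots] = points.values
    prov[slots] = Provenance.OBSERVED
    n_inserted = n - len(points)
    log.info("regularize_grid: %d observed, %d inserted missing", len(points), n_inserted)
    return SampledSeries(GridSpec(start, interval, n), values, prov)


def _missing_runs(prov: np.ndarray) -> list[tuple[int, int]]:
    """[(start, stop)) index ranges of consecutive inserted_missing slots."""
    missing = prov == Provenance.INSERTED_MISSING
    runs = []
    i, n = 0, len(prov)
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def impute_series(series: SampledSeries) -> SampledSeries:
    """Fill missing runs: forward-fill for length-1 runs, linear for ≥ 2.

    An isolated missing sample takes the previous observed value; longer
    runs are linearly interpolated between the bracketing observations,
    so every imputed value lies within its brackets' range.  Observed
    samples are never altered.  Leading or trailing missing runs have no
    bracket and are an error — truncate the series to its observed span
    first.
    """
    n = series.grid.n_samples
    if n == 0:
        return series.copy()
    runs = _missing_runs(series.provenance)
    for lo, hi in runs:
        if lo == 0 or hi == n:
            raise ValidationError(
                "leading/trailing missing run cannot be imputed; truncate the "
                "series to its observed span first"
            )
    out = series.copy()
    for lo, hi in runs:
        if hi - lo == 1:
            out.values[lo] = out.values[lo - 1]  # forward fill, limit 1
        else:
            left, right = out.values[lo - 1], out.values[hi]
            k = np.arange(1, hi - lo + 1)
            out.values[lo:hi] = left + (right - left) * k / (hi - lo + 1)
        out.provenance[lo:hi] = Provenance.IMPUTED
    n_imputed = sum(hi - lo for lo, hi in runs)
    log.info("impute_series: %d samples imputed in %d runs", n_imputed, len(runs))
    return out


def median_smooth(series: SampledSeries, window: int = 5) -> SampledSeries:
    """Centered running-median filter; edges use shrunken windows.

    Replaces spike-like extremes with the local median.  Samples whose
    value actually changed are re-flagged ``smoothed``.  Intended for
    TRAINING data only — smoothing test data would leak the very noise
    profile the evaluation is meant to measure.
    """
    if window % 2 == 0 or window < 3:
        raise ValidationError("window must be an odd integer >= 3")
    vals = series.values
    if np.any(~np.isfinite(vals)):
        raise ValidationError("median_smooth requires a fully defined series")
    half = window // 2
    n = len(vals)
    out = series.copy()
    smoothed = np.empty(n)
    for i in range(n):
        smoothed[i] = np.median(vals[max(0, i - half): i + half + 1])
    changed = smoothed != vals
    out.values = smoothed
    out.provenance[changed] = Provenance.SMOOTHED
    log.info("median_smooth: window=%d, %d samples changed", window, int(changed.sum()))
    return out


def align_features(
    reference: SampledSeries,
    others: dict[str, TimedPoints],
) -> dict[str, SampledSeries]:
    """Resample irregular auxiliary series onto the reference CGM grid.

    Each observation maps to the nearest reference slot when it lies
    within half an interval of it; interior gaps are then imputed with the
    same forward-fill/linear rules as the CGM.  Leading/trailing gaps stay
    missing (there is nothing to bracket them).  An empty input series
    yields an all-missing output with a warning.
    """
    import warnings

    grid = reference.grid
    aligned: dict[str, SampledSeries] = {}
    for name, pts in others.items():
        values = np.full(grid.n_samples, np.nan)
        prov = np.full(grid.n_samples, Provenance.INSERTED_MISSING, dtype=np.int8)
        if len(pts) == 0:
            warnings.warn(f"feature {name!r} has no observations; all-missing",
                          stacklevel=2)
            aligned[name] = SampledSeries(grid, values, prov)
            continue
        offset = (pts.times - grid.start) / grid.interval
        slots = np.floor(offset + 0.5).astype(int)
        within = np.abs(offset - slots) <= 0.5
        ok = within & (slots >= 0) & (slots < grid.n_samples)
        values[slots[ok]] = pts.values[ok]
        prov[slots[ok]] = Provenance.OBSERVED
        series = SampledSeries(grid, values, prov)
        # impute interior runs only; edges stay missing
        runs = [r for r in _missing_runs(prov) if r[0] > 0 and r[1] < grid.n_samples]
        for lo, hi in runs:
            if hi - lo == 1:
                series.values[lo] = series.values[lo - 1]
            else:
                left, right = series.values[lo - 1], series.values[hi]
                k = np.arange(1, hi - lo + 1)
                series.values[lo:hi] = left + (right - left) * k / (hi - lo + 1)
            series.provenance[lo:hi] = Provenance.IMPUTED
        aligned[name] = series
    return aligned


def preprocess_cgm(
    points: TimedPoints,
    interval: pd.Timedelta = pd.Timedelta(minutes=5),
    smooth_window: int | None = None,
) -> SampledSeries:
    """Convenience pipeline: regularise → impute → (optionally) smooth.

    Pass ``smooth_window`` only for training data.  Leading/trailing
    missing runs are impossible here because the grid is anchored at the
    first observation and ends at the last.
    """
    series = regularize_grid(points, interval)
    series = impute_series(series)
    if smooth_window is not None:
        series = median_smooth(series, smooth_window)
    return series
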