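"""Core domain types and the patient-record XML dialect.

Time-stamped diabetes self-management data come in two flavours: periodic
series sampled on a (nominally) 5-minute grid — continuous glucose
monitoring (CGM) in mg/dL, heart rate, skin temperature — and event logs
recorded only when something happens: a meal (grams of carbohydrate) or a
rapid-acting bolus insulin dose (units).  The types here carry both,
together with per-sample provenance so that downstream stages can tell a
sensor reading from a gap-filled value.

The reader/writer pair speaks a compact XML dialect modelled on the Ohio
T1DM interchange format: a ``<patient id=...>`` root holding
``<glucose_level>``, ``<meal>`` and ``<bolus>`` containers whose
``<event>`` children carry ``ts`` plus ``value`` / ``carbs`` / ``dose``
attributes.  Timestamps are strict ``DD-MM-YYYY HH:MM:SS``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable

import numpy as np
import pandas as pd
from lxml import etree

TS_FORMAT = "%d-%m-%Y %H:%M:%S"

#: Nominal CGM sampling interval.
DEFAULT_INTERVAL = pd.Timedelta(minutes=5)

#: CGM sensor dynamic range, mg/dL.
CGM_MIN, CGM_MAX = 40.0, 400.0


class Provenance(IntEnum):
    """Per-sample origin of a value in a :class:`SampledSeries`."""

    OBSERVED = 0          # came from the sensor / source record
    INSERTED_MISSING = 1  # grid slot with no observation; value undefined
    IMPUTED = 2           # filled by forward-fill or interpolation
    SMOOTHED = 3          # altered by the median filter


class FormatError(ValueError):
    """Raised when an input file does not conform to the XML dialect."""


class ValidationError(ValueError):
    """Raised when record contents violate a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A regular sampling grid: sample ``k`` lives at ``start + k*interval``.

    The grid covers the half-open span ``[start, start + n_samples*interval)``;
    event times are instants and may fall anywhere inside it.
    """

    start: pd.Timestamp
    interval: pd.Timedelta = DEFAULT_INTERVAL
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.interval <= pd.Timedelta(0):
            raise ValidationError("grid interval must be positive")
        if self.n_samples < 0:
            raise ValidationError("n_samples must be >= 0")

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(
            self.start + np.arange(self.n_samples) * self.interval
        )

    @property
    def end(self) -> pd.Timestamp:
        """Exclusive end of the grid span."""
        return self.start + self.n_samples * self.interval

    def slot_of(self, t: pd.Timestamp) -> int:
        """Nearest grid slot to instant ``t`` (round-half-up)."""
        return int(np.floor((t - self.start) / self.interval + 0.5))


@dataclass
class SampledSeries:
    """Values on a :class:`GridSpec` with per-sample provenance.

    ``values[k]`` is NaN exactly where ``provenance[k]`` is
    ``INSERTED_MISSING``; every other provenance implies a defined value.
    """

    grid: GridSpec
    values: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.provenance = np.asarray(self.provenance, dtype=np.int8)
        n = self.grid.n_samples
        if len(self.values) != n or len(self.provenance) != n:
            raise ValidationError(
                f"values/provenance length must equal grid.n_samples={n}"
            )
        defined = self.provenance != Provenance.INSERTED_MISSING
        if np.any(~np.isfinite(self.values[defined])):
            raise ValidationError(
                "non-finite value with provenance other than inserted_missing"
            )

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.grid.times

    def copy(self) -> "SampledSeries":
        return SampledSeries(self.grid, self.values.copy(), self.provenance.copy())

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.provenance == Provenance.INSERTED_MISSING))

    @property
    def observed_mask(self) -> np.ndarray:
        return self.provenance == Provenance.OBSERVED


def series_from_values(
    values: Iterable[float],
    start: pd.Timestamp | str = "2025-01-01",
    interval: pd.Timedelta = DEFAULT_INTERVAL,
) -> SampledSeries:
    """Convenience constructor: fully observed series from a value array."""
    values = np.asarray(list(values), dtype=float)
    grid = GridSpec(pd.Timestamp(start), interval, len(values))
    return SampledSeries(grid, values, np.zeros(len(values), dtype=np.int8))


@dataclass
class TimedPoints:
    """An irregular time/value series, as read straight from a record."""

    times: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValidationError("times and values must have equal length")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class EventSeries:
    """Irregular, strictly time-ordered events with positive magnitudes."""

    kind: str  # "meal" (grams) or "bolus" (insulin units)
    times: pd.DatetimeIndex
    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("meal", "bolus"):
            raise ValidationError(f"unknown event kind {self.kind!r}")
        self.times = pd.DatetimeIndex(self.times)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if len(self.times) != len(self.magnitudes):
            raise ValidationError("times and magnitudes must have equal length")
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise ValidationError(f"{self.kind} event times must be increasing")
        if len(self.times) > 1 and self.times.has_duplicates:
            raise ValidationError(f"duplicate {self.kind} event timestamps")
        if np.any(self.magnitudes <= 0):
            raise ValidationError(f"{self.kind} magnitudes must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @staticmethod
    def empty(kind: str) -> "EventSeries":
        return EventSeries(kind, pd.DatetimeIndex([]), np.empty(0))


@dataclass
class PatientRecord:
    """One patient's CGM (train/test) plus meal and bolus event logs.

    Straight after reading, ``train_cgm``/``test_cgm`` are irregular
    :class:`TimedPoints`; after preprocessing they are regular
    :class:`SampledSeries`.  Either part may be empty when only one file
    was read.
    """

    patient_id: str
    train_cgm: SampledSeries | TimedPoints
    test_cgm: SampledSeries | TimedPoints
    meals: EventSeries
    boluses: EventSeries
    extra_series: dict[str, TimedPoints] = field(default_factory=dict)

    def with_(self, **kwargs) -> "PatientRecord":
        return replace(self, **kwargs)


def _span(series: SampledSeries | TimedPoints):
    if isinstance(series, SampledSeries):
        if series.grid.n_samples == 0:
            return None
        return series.grid.start, series.grid.end
    if len(series) == 0:
        return None
    return series.times[0], series.times[-1]


def validate_record(record: PatientRecord) -> list[str]:
    """Check structural invariants; return human/machine-readable findings.

    An empty list means the record is internally consistent.  Findings are
    strings of the form ``"<code>: <detail>"`` so callers can match on the
    leading code.
    """
    findings: list[str] = []
    for part, name in ((record.train_cgm, "train"), (record.test_cgm, "test")):
        if isinstance(part, TimedPoints) and len(part) > 1:
            t = part.times
            if not t.is_monotonic_increasing or t.has_duplicates:
                bad = t[1:][np.diff(t.asi8) <= 0]
                findings.append(
                    f"non_monotone_cgm: {name} CGM timestamps not strictly "
                    f"increasing at {list(bad[:5])}"
                )
    for ev in (record.meals, record.boluses):
        if np.any(ev.magnitudes <= 0):
            idx = np.nonzero(ev.magnitudes <= 0)[0]
            findings.append(
                f"nonpositive_magnitude: {ev.kind} events {idx.tolist()} have "
                f"magnitude <= 0"
            )
    tr, te = _span(record.train_cgm), _span(record.test_cgm)
    if tr and te:
        lo, hi = max(tr[0], te[0]), min(tr[1], te[1])
        if lo < hi:
            findings.append(
                f"train_test_overlap: train span {tr} overlaps test span {te}"
            )
    if tr or te:
        spans = [s for s in (tr, te) if s]
        lo = min(s[0] for s in spans)
        hi = max(s[1] for s in spans)
        for ev in (record.meals, record.boluses):
            if len(ev) and (ev.times[0] < lo or ev.times[-1] > hi):
                findings.append(
                    f"event_outside_span: {ev.kind} events fall outside the "
                    f"recorded CGM span [{lo}, {hi}]"
                )
    return findings


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------

_MAGNITUDE_ATTR = {"meal": "carbs", "bolus": "dose"}

# containers in the source dialect that we parse but do not model
_EXTRA_PERIODIC = ("basis_heart_rate", "heart_rate", "basis_skin_temperature")
_IGNORED = ("basal", "finger_stick", "exercise", "sleep", "work")


def _parse_ts(raw: str, context: str) -> pd.Timestamp:
    try:
        return pd.Timestamp(pd.to_datetime(raw, format=TS_FORMAT))
    except (ValueError, TypeError) as exc:
        raise FormatError(
            f"bad timestamp {raw!r} in <{context}> (expected DD-MM-YYYY HH:MM:SS)"
        ) from exc


def _events_from(root, tag: str, kind: str) -> EventSeries:
    container = root.find(tag)
    if container is None:
        return EventSeries.empty(kind)
    attr = _MAGNITUDE_ATTR[kind]
    times, mags = [], []
    for ev in container.iter("event"):
        ts = ev.get("ts")
        raw = ev.get(attr)
        if ts is None or raw is None:
            raise FormatError(f"<event> in <{tag}> missing ts/{attr} attribute")
        times.append(_parse_ts(ts, tag))
        try:
            mags.append(float(raw))
        except ValueError as exc:
            raise FormatError(f"non-numeric {attr}={raw!r} in <{tag}>") from exc
    order = np.argsort(np.asarray(times, dtype="datetime64[ns]"), kind="stable")
    times = pd.DatetimeIndex(np.asarray(times, dtype="datetime64[ns]")[order])
    mags = np.asarray(mags, dtype=float)[order]
    return EventSeries(kind, times, mags)


def read_ohio_xml(path, role: str = "train") -> PatientRecord:
    """Read one patient file in the Ohio-style XML dialect.

    ``role`` says whether the file's glucose trace is the training or the
    test portion; the other portion comes back empty.  Glucose is returned
    as irregular :class:`TimedPoints` — grid regularisation is a separate,
    downstream step — and no values are invented or altered.
    """
    if role not in ("train", "test"):
        raise ValueError("role must be 'train' or 'test'")
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "patient":
        raise FormatError(f"root element is <{root.tag}>, expected <patient>")
    patient_id = root.get("id", "")

    times, values = [], []
    gl = root.find("glucose_level")
    if gl is not None:
        for ev in gl.iter("event"):
            ts, val = ev.get("ts"), ev.get("value")
            if ts is None or val is None:
                raise FormatError("<event> in <glucose_level> missing ts/value")
            times.append(_parse_ts(ts, "glucose_level"))
            try:
                values.append(float(val))
            except ValueError as exc:
                raise FormatError(f"non-numeric glucose value {val!r}") from exc
    idx = pd.DatetimeIndex(times)
    if len(idx) > 1 and (not idx.is_monotonic_increasing or idx.has_duplicates):
        diffs = np.diff(idx.asi8)
        bad = idx[1:][diffs <= 0]
        raise ValidationError(
            f"glucose_level timestamps not strictly increasing "
            f"({len(bad)} violations, first at {bad[0]})"
        )
    cgm = TimedPoints(idx, np.asarray(values, dtype=float))

    extra: dict[str, TimedPoints] = {}
    for tag in _EXTRA_PERIODIC:
        node = root.find(tag)
        if node is None:
            continue
        ts_list, vals = [], []
        for ev in node.iter("event"):
            ts_list.append(_parse_ts(ev.get("ts"), tag))
            vals.append(float(ev.get("value")))
        extra[tag] = TimedPoints(pd.DatetimeIndex(ts_list), np.asarray(vals))
    for tag in _IGNORED:
        if root.find(tag) is not None:
            warnings.warn(
                f"container <{tag}> present but carries no pipeline semantics; "
                "ignored",
                stacklevel=2,
            )

    empty = TimedPoints(pd.DatetimeIndex([]), np.empty(0))
    return PatientRecord(
        patient_id=patient_id,
        train_cgm=cgm if role == "train" else empty,
        test_cgm=cgm if role == "test" else empty,
        meals=_events_from(root, "meal", "meal"),
        boluses=_events_from(root, "bolus", "bolus"),
        extra_series=extra,
    )


def _fmt_ts(t: pd.Timestamp) -> str:
    return t.strftime(TS_FORMAT)


def _fmt_num(x: float) -> str:
    return repr(float(x))


def write_ohio_xml(record: PatientRecord, path, role: str = "train") -> None:
    """Write one patient file; ``read_ohio_xml(path, role)`` round-trips it.

    The glucose trace for ``role`` is written (a regular series emits only
    its defined samples, so gaps survive a round trip as absent stamps);
    meal and bolus containers are always written, empty or not.
    """
    if role not in ("train", "test"):
        raise ValueError("role must be 'train' or 'test'")
    cgm = record.train_cgm if role == "train" else record.test_cgm
    root = etree.Element("patient", id=record.patient_id)
    gl = etree.SubElement(root, "glucose_level")
    if isinstance(cgm, SampledSeries):
        defined = cgm.provenance != Provenance.INSERTED_MISSING
        times = cgm.times[defined]
        values = cgm.values[defined]
    else:
        times, values = cgm.times, cgm.values
    for t, v in zip(times, values):
        etree.SubElement(gl, "event", ts=_fmt_ts(t), value=_fmt_num(v))
    for ev in (record.meals, record.boluses):
        container = etree.SubElement(root, ev.kind)
        attr = _MAGNITUDE_ATTR[ev.kind]
        for t, m in zip(ev.times, ev.magnitudes):
            etree.SubElement(container, "event", ts=_fmt_ts(t), **{attr: _fmt_num(m)})
    for name, pts in record.extra_series.items():
        container = etree.SubElement(root, name)
        for t, v in zip(pts.times, pts.values):
            etree.SubElement(container, "event", ts=_fmt_ts(t), value=_fmt_num(v))
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


def combine_records(train: PatientRecord, test: PatientRecord) -> PatientRecord:
    """Merge two one-part records (train file + test file) into one.

    Event logs are concatenated and de-duplicated on (time, magnitude).
    """
    if train.patient_id != test.patient_id:
        raise ValidationError(
            f"patient ids differ: {train.patient_id!r} vs {test.patient_id!r}"
        )

    def merge(a: EventSeries, b: EventSeries) -> EventSeries:
        if len(a) == 0:
            return b
        if len(b) == 0:
            return a
        df = pd.DataFrame(
            {"t": a.times.append(b.times), "m": np.concatenate([a.magnitudes, b.magnitudes])}
        ).drop_duplicates().sort_values("t")
        return EventSeries(a.kind, pd.DatetimeIndex(df["t"]), df["m"].to_numpy())

    return PatientRecord(
        patient_id=train.patient_id,
        train_cgm=train.train_cgm,
        test_cgm=test.test_cgm,
        meals=merge(train.meals, test.meals),
        boluses=merge(train.boluses, test.boluses),
        extra_series={**train.extra_series, **test.extra_series},
    )
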