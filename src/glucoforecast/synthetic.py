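"""Seeded synthetic type-1-diabetes patient simulator.

Real CGM traces from insulin-pump wearers are access-restricted, so the
package carries a generator whose output has the statistical structure the
pipeline assumes: a 5-min CGM grid with sensor-change gaps and spike
noise, meal-driven rises, bolus-driven falls, a circadian baseline and
AR(1) sensor/physiology noise, plus matching meal and bolus event logs.

The glucose trace is an additive superposition

    cgm = baseline + circadian + Σ meal effects − Σ insulin effects + noise

clipped to the 40–400 mg/dL sensor range.  Meal effects use the operative
-carbs absorption kernel and insulin effects the IOB activity kernel from
:mod:`glucoforecast.physio` — the very curves the pipeline extracts as
features — so multivariate feature configurations are informative by
construction.  This is bookkeeping realism, not physiology: there are no
glucose–insulin ODEs, no exercise or stress, and effects add linearly.

Everything is driven by one ``numpy`` PCG64 generator, so a seed pins the
record bit-for-bit across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    CGM_MAX,
    CGM_MIN,
    EventSeries,
    GridSpec,
    PatientRecord,
    Provenance,
    SampledSeries,
    ValidationError,
)
from .physio import (
    CarbKineticsParams,
    InsulinKineticsParams,
    carb_curve_single,
    iob_fraction,
)

SAMPLES_PER_DAY = 288  # 24 h on a 5-min grid
_WAKING_HOURS = (7.0, 22.0)  # meals drawn uniformly over this span


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated patient.

    Defaults give a plausibly noisy adult profile: ~3.5 meals/day of
    20–90 g carbs, each gram raising glucose ~2.5 mg/dL at absorption
    peak; boluses at 0.1 U/g taken 15 min pre-meal, each unit lowering
    glucose ~35 mg/dL at activity peak; about one sensor gap every two
    days; rare ±40 mg/dL spike artefacts.
    """

    seed: int = 0
    days: int = 14
    baseline_mgdl: float = 120.0
    circadian_amp_mgdl: float = 15.0
    ar_coeff: float = 0.95
    noise_sd_mgdl: float = 3.0
    meal_rate_per_day: float = 3.5
    carb_range_g: tuple[float, float] = (20.0, 90.0)
    carb_gain_mgdl_per_g: float = 2.5
    bolus_ratio_u_per_g: float = 0.1
    insulin_gain_mgdl_per_u: float = 35.0
    gap_rate_per_day: float = 0.5
    gap_len_range: tuple[int, int] = (2, 24)
    spike_prob: float = 0.005
    spike_amp_mgdl: float = 40.0
    start: pd.Timestamp = pd.Timestamp("2025-01-01 00:00:00")
    test_fraction: float = 0.2
    carb_params: CarbKineticsParams = field(default_factory=CarbKineticsParams)
    insulin_params: InsulinKineticsParams = field(
        default_factory=InsulinKineticsParams.adult
    )

    def __post_init__(self) -> None:
        if self.days <= 0:
            raise ValidationError("days must be positive")
        if not 0 <= self.ar_coeff < 1:
            raise ValidationError("ar_coeff must lie in [0, 1)")
        for name in ("circadian_amp_mgdl", "noise_sd_mgdl", "meal_rate_per_day",
                     "carb_gain_mgdl_per_g", "bolus_ratio_u_per_g",
                     "insulin_gain_mgdl_per_u", "gap_rate_per_day",
                     "spike_prob", "spike_amp_mgdl"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


# components stored per simulated record, keyed by id(record) being fragile;
# attach directly to the record object instead
_COMPONENTS_ATTR = "_glucoforecast_components"


def _unit_carb_kernel(n: int, params: CarbKineticsParams) -> np.ndarray:
    """Absorption curve of a 1 g meal over n samples (peak value 1)."""
    return carb_curve_single(np.arange(n), 1.0, params)


def _unit_insulin_kernel(n: int, params: InsulinKineticsParams,
                         minutes_per_sample: float) -> np.ndarray:
    """IOB activity curve sampled on the grid, normalised to unit peak."""
    t = np.arange(n) * minutes_per_sample
    iob = iob_fraction(t, params)
    act = np.empty_like(iob)
    act[:-1] = iob[:-1] - iob[1:]   # activity per sample interval
    act[-1] = 0.0
    peak = act.max()
    return act / peak if peak > 0 else act


def simulate_patient(config: SimulationConfig) -> PatientRecord:
    """Generate one seeded synthetic patient record.

    The last ``test_fraction`` of days (at least one) becomes the test
    part; the split lands on a day boundary so train and test grids never
    overlap.  Identical configs produce identical records.
    """
    rng = np.random.default_rng(config.seed)
    n = config.days * SAMPLES_PER_DAY
    interval = pd.Timedelta(minutes=5)
    grid = GridSpec(config.start, interval, n)
    hours = (np.arange(n) * 5.0 / 60.0) % 24.0

    # circadian: lowest pre-dawn, highest late afternoon
    circadian = config.circadian_amp_mgdl * np.sin(2 * np.pi * (hours - 10.0) / 24.0)

    # AR(1) noise with stationary variance noise_sd^2 / (1 - ar^2)
    innov = rng.normal(0.0, config.noise_sd_mgdl, size=n)
    noise = np.empty(n)
    acc = 0.0
    for k in range(n):
        acc = config.ar_coeff * acc + innov[k]
        noise[k] = acc

    # meal / bolus events
    meal_times: list[pd.Timestamp] = []
    meal_grams: list[float] = []
    w0, w1 = _WAKING_HOURS
    for day in range(config.days):
        n_meals = rng.poisson(config.meal_rate_per_day)
        offsets = np.sort(rng.uniform(w0, w1, size=n_meals))
        for h in offsets:
            slot = day * SAMPLES_PER_DAY + int(round(h * 12.0))
            slot = min(slot, n - 1)
            t = config.start + slot * interval
            if meal_times and t <= meal_times[-1]:
                continue  # collapsed onto the previous meal's slot; drop
            meal_times.append(t)
            meal_grams.append(float(rng.uniform(*config.carb_range_g)))
    meals = EventSeries("meal", pd.DatetimeIndex(meal_times), np.asarray(meal_grams))

    bolus_times, bolus_units = [], []
    if config.bolus_ratio_u_per_g > 0:
        for t, g in zip(meal_times, meal_grams):
            bt = max(t - pd.Timedelta(minutes=15), config.start)
            if bolus_times and bt <= bolus_times[-1]:
                continue
            bolus_times.append(bt)
            bolus_units.append(config.bolus_ratio_u_per_g * g)
    boluses = EventSeries("bolus", pd.DatetimeIndex(bolus_times),
                          np.asarray(bolus_units))

    # event effects via the physiological kernels
    carb_kernel = _unit_carb_kernel(config.carb_params.end_sample + 1,
                                    config.carb_params)
    ins_kernel = _unit_insulin_kernel(
        int(config.insulin_params.td / 5) + 2, config.insulin_params, 5.0
    )
    meal_effect = np.zeros(n)
    for t, g in zip(meals.times, meals.magnitudes):
        s = grid.slot_of(t)
        span = min(len(carb_kernel), n - s)
        meal_effect[s:s + span] += config.carb_gain_mgdl_per_g * g * carb_kernel[:span]
    insulin_effect = np.zeros(n)
    for t, u in zip(boluses.times, boluses.magnitudes):
        s = grid.slot_of(t)
        span = min(len(ins_kernel), n - s)
        insulin_effect[s:s + span] += (
            config.insulin_gain_mgdl_per_u * u * ins_kernel[:span]
        )

    # spikes count as noise (sensor artefacts)
    spikes = np.zeros(n)
    hit = rng.random(n) < config.spike_prob
    signs = rng.choice([-1.0, 1.0], size=n)
    spikes[hit] = signs[hit] * config.spike_amp_mgdl
    noise = noise + spikes

    pre_clip = (config.baseline_mgdl + circadian + meal_effect
                - insulin_effect + noise)
    cgm = np.clip(pre_clip, CGM_MIN, CGM_MAX)
    prov = np.zeros(n, dtype=np.int8)

    # sensor gaps: Poisson count over the whole span, uniform starts
    n_gaps = rng.poisson(config.gap_rate_per_day * config.days)
    for _ in range(n_gaps):
        length = int(rng.integers(config.gap_len_range[0],
                                  config.gap_len_range[1] + 1))
        lo = int(rng.integers(1, max(2, n - length - 1)))
        prov[lo:lo + length] = Provenance.INSERTED_MISSING
    cgm = cgm.copy()
    cgm[prov == Provenance.INSERTED_MISSING] = np.nan

    test_days = max(1, int(round(config.test_fraction * config.days)))
    split = (config.days - test_days) * SAMPLES_PER_DAY
    train_grid = GridSpec(config.start, interval, split)
    test_grid = GridSpec(config.start + split * interval, interval, n - split)
    record = PatientRecord(
        patient_id=f"sim{config.seed:04d}",
        train_cgm=SampledSeries(train_grid, cgm[:split], prov[:split]),
        test_cgm=SampledSeries(test_grid, cgm[split:], prov[split:]),
        meals=meals,
        boluses=boluses,
    )
    full_prov = np.zeros(n, dtype=np.int8)
    components = {
        "meal_effect": SampledSeries(grid, meal_effect, full_prov.copy()),
        "insulin_effect": SampledSeries(grid, -insulin_effect, full_prov.copy()),
        "circadian": SampledSeries(grid, circadian, full_prov.copy()),
        "noise": SampledSeries(grid, noise, full_prov.copy()),
        "pre_clip_cgm": SampledSeries(grid, pre_clip, full_prov.copy()),
    }
    setattr(record, _COMPONENTS_ATTR, components)
    return record


def ground_truth_components(record: PatientRecord) -> dict[str, SampledSeries]:
    """Latent components of a simulated record.

    Returns meal_effect, insulin_effect (negative-signed), circadian,
    noise and the pre-clip CGM; baseline + meal_effect + insulin_effect +
    circadian + noise equals pre_clip_cgm exactly.  Only records produced
    by :func:`simulate_patient` carry these.
    """
    components = getattr(record, _COMPONENTS_ATTR, None)
    if components is None:
        raise ValidationError(
            "record was not produced by simulate_patient; no ground truth"
        )
    return components
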