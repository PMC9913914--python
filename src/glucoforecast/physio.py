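"""Event-to-continuous physiological feature transforms.

Meal and bolus records are sparse events, but their glycaemic effect is
extended in time.  Two standard kinetic models turn them into continuous
features aligned with the CGM grid:

* **Operative carbohydrates** — a piecewise-linear absorption profile.
  On a 5-min sample scale a meal of ``C_meal`` grams contributes nothing
  for the first 3 samples (≈15 min digestion lag), rises at a rate of
  11.1 % of ``C_meal`` per sample until it peaks — almost exactly at
  ``C_meal`` — at the 12th sample (60 min), then decays at 2.8 % of
  ``C_meal`` per sample, reaching zero 3 h after the peak.

* **Active insulin** — dose times the insulin-on-board (IOB) fraction of
  the standard exponential-decay bolus model.  Given a peak activity time
  ``tp`` and a duration of insulin action ``td`` (rapid-acting presets:
  65 min child / 75 min adult, 6 h DIA), the decay time constant is
  ``tau = tp*(1 - tp/td)/(1 - 2*tp/td)``, the rise-time factor
  ``a = 2*tau/td`` and the scale ``S = 1/(1 - a + (1 + a)*exp(-td/tau))``.
  IOB(0) = 1, IOB(td) = 0, and the activity curve (−dIOB/dt) peaks at tp.

Overlapping events superpose linearly; doubling a meal or a dose doubles
its contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import EventSeries, GridSpec, Provenance, SampledSeries


@dataclass(frozen=True)
class CarbKineticsParams:
    """Piecewise-linear carbohydrate absorption profile, sample-indexed."""

    alpha_inc: float = 0.111    # rise rate, fraction of C_meal per sample
    alpha_dec: float = 0.028    # decay rate, fraction of C_meal per sample
    delay_samples: int = 3      # zero-effect digestion lag
    peak_sample: int = 12       # sample at which the curve attains C_meal
    end_sample: int = 48        # first sample at which the curve is 0 again
    sample_interval: pd.Timedelta = pd.Timedelta(minutes=5)

    def __post_init__(self) -> None:
        if not (0 < self.alpha_inc <= 1 and 0 < self.alpha_dec <= 1):
            raise ValueError("alpha_inc and alpha_dec must lie in (0, 1]")
        if not (0 <= self.delay_samples < self.peak_sample < self.end_sample):
            raise ValueError("need delay_samples < peak_sample < end_sample")


@dataclass(frozen=True)
class InsulinKineticsParams:
    """Exponential-IOB bolus model parameters with derived constants.

    ``tp`` is the peak activity time and ``td`` the duration of insulin
    action, both in minutes.  ``tau``, ``a`` and ``S`` are derived on
    construction and must not be supplied.
    """

    tp: float = 75.0   # adult rapid-acting preset; child preset is 65
    td: float = 360.0  # duration of insulin action (6 h)
    tau: float = field(init=False)
    a: float = field(init=False)
    S: float = field(init=False)

    def __post_init__(self) -> None:
        tau, a, S = insulin_shape_params(self.tp, self.td)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "S", S)

    @staticmethod
    def adult() -> "InsulinKineticsParams":
        return InsulinKineticsParams(tp=75.0, td=360.0)

    @staticmethod
    def child() -> "InsulinKineticsParams":
        return InsulinKineticsParams(tp=65.0, td=360.0)


def insulin_shape_params(tp: float, td: float) -> tuple[float, float, float]:
    """Derive (tau, a, S) of the exponential IOB model from (tp, td).

    Raises a domain error when ``tp >= td/2`` — the time-constant
    expression has a pole at ``1 - 2*tp/td = 0``.
    """
    if not 0 < tp < td / 2:
        raise ValueError(
            f"need 0 < tp < td/2 (got tp={tp}, td={td}): the time-constant "
            "denominator 1 - 2*tp/td must be positive"
        )
    tau = tp * (1 - tp / td) / (1 - 2 * tp / td)
    a = 2 * tau / td
    S = 1.0 / (1 - a + (1 + a) * math.exp(-td / tau))
    return tau, a, S


#: Named parameter presets, also exposed through the CLI.
PRESETS = {
    "carb_default": CarbKineticsParams(),
    "insulin_adult": InsulinKineticsParams.adult(),
    "insulin_child": InsulinKineticsParams.child(),
}


# ---------------------------------------------------------------------------
# operative carbohydrates
# ---------------------------------------------------------------------------

def carb_curve_single(
    k: int | np.ndarray,
    c_meal: float,
    params: CarbKineticsParams | None = None,
) -> float | np.ndarray:
    """Operative carbs (grams) ``k`` samples after a single ``c_meal``-gram meal.

    Vectorised over ``k``; the result is clamped to ``[0, c_meal]``, which
    absorbs the ~0.1 % round-off of the printed rates (9*0.111 = 0.999,
    1 - 36*0.028 = -0.008).
    """
    params = params or CarbKineticsParams()
    if c_meal <= 0:
        raise ValueError("c_meal must be positive")
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("sample offset k must be non-negative")
    rise = (k - params.delay_samples + 1) * params.alpha_inc * c_meal
    decay = (1.0 - (k - params.peak_sample) * params.alpha_dec) * c_meal
    out = np.where(
        k < params.delay_samples,
        0.0,
        np.where(k < params.peak_sample, rise, np.where(k < params.end_sample, decay, 0.0)),
    )
    out = np.clip(out, 0.0, c_meal)
    return float(out) if out.ndim == 0 else out


def operative_carbs_series(
    meals: EventSeries,
    grid: GridSpec,
    params: CarbKineticsParams | None = None,
) -> SampledSeries:
    """Superpose single-meal absorption curves onto a sampling grid.

    Each meal is snapped to its nearest grid slot so the kernel argument
    stays an integer sample offset; slots before all meals are zero.
    """
    params = params or CarbKineticsParams()
    values = np.zeros(grid.n_samples)
    k_all = np.arange(grid.n_samples)
    for t, grams in zip(meals.times, meals.magnitudes):
        slot = grid.slot_of(t)
        if slot >= grid.n_samples:
            continue
        k = k_all - slot
        active = k >= 0
        values[active] += carb_curve_single(k[active], grams, params)
    return SampledSeries(grid, values, np.zeros(grid.n_samples, dtype=np.int8))


# ---------------------------------------------------------------------------
# insulin on board
# ---------------------------------------------------------------------------

def iob_fraction(
    t: float | np.ndarray,
    params: InsulinKineticsParams | None = None,
) -> float | np.ndarray:
    """Fraction of a bolus still active ``t`` minutes after injection.

    Equals 1 at t = 0, decays monotonically and reaches 0 at t = td
    (exactly, by the scale factor's construction); 0 beyond td.
    """
    params = params or InsulinKineticsParams.adult()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since bolus must be non-negative")
    tau, td, a, S = params.tau, params.td, params.a, params.S
    bracket = (t**2 / (tau * td * (1 - a)) - t / tau - 1) * np.exp(-t / tau) + 1
    frac = 1.0 - S * (1 - a) * bracket
    frac = np.where(t > td, 0.0, np.clip(frac, 0.0, 1.0))
    return float(frac) if frac.ndim == 0 else frac


def insulin_activity(
    t_minutes: np.ndarray,
    params: InsulinKineticsParams | None = None,
) -> np.ndarray:
    """Activity curve −dIOB/dt by central differences on the given grid."""
    params = params or InsulinKineticsParams.adult()
    iob = iob_fraction(t_minutes, params)
    return -np.gradient(iob, t_minutes)


def active_insulin_series(
    boluses: EventSeries,
    grid: GridSpec,
    params: InsulinKineticsParams | None = None,
) -> SampledSeries:
    """Active insulin (units) on a grid: Σ dose_i · IOB(t − t_i).

    Boluses are snapped to their nearest grid slot; a 4 U bolus therefore
    contributes exactly 4.0 at its own slot and 0 from td onwards.
    """
    params = params or InsulinKineticsParams.adult()
    values = np.zeros(grid.n_samples)
    minutes_per_slot = grid.interval / pd.Timedelta(minutes=1)
    k_all = np.arange(grid.n_samples)
    for t, dose in zip(boluses.times, boluses.magnitudes):
        slot = grid.slot_of(t)
        if slot >= grid.n_samples:
            continue
        dt = (k_all - slot) * minutes_per_slot
        active = dt >= 0
        values[active] += dose * iob_fraction(dt[active], params)
    return SampledSeries(grid, values, np.zeros(grid.n_samples, dtype=np.int8))
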