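# Methods

## Problem and pipeline

Forecasting blood glucose 30–60 minutes ahead from a continuous glucose
monitor (CGM) is a multistep sequence-to-sequence regression problem.
Glucose responds to meals and bolus insulin with lags of tens of minutes
to hours, but both are recorded as point events; representing them as
sparse spikes (or binary flags) gives a learner almost nothing to work
with. The pipeline therefore (1) restores time coherence of the CGM,
(2) converts events into continuous kinetic features on the same grid,
(3) slices windowed examples, and (4) trains a recurrent forecaster whose
error is scored only on sensor-recorded targets.

## Preprocessing

* **Grid regularisation.** The 5-min grid is anchored at the first
  observation (the anchor is otherwise arbitrary; midnight anchoring
  would shift every slot by a constant). Each observation maps to its
  nearest slot; collisions (two observations in one slot) abort rather
  than average, since they indicate duplicate or sub-interval data the
  caller should resolve. Empty slots are explicit `inserted_missing`
  samples with undefined values.
* **Imputation.** A single missing slot takes the previous value
  (forward fill with limit 1); runs of two or more are linearly
  interpolated between their brackets. Linear filling keeps imputed
  values inside the bracketing range and avoids the overshoot of
  higher-order interpolants on sensor data. Leading/trailing runs have no
  bracket and are an error by design: truncation is the caller's,
  visible, decision. Test data are imputed too — windows must be
  contiguous — but imputed test targets are masked out of the error (see
  Evaluation).
* **Median smoothing.** A centred running median (edges use shrunken
  windows) suppresses isolated sensor spikes. The kernel width is not
  dictated by anything physical; the default of 5 samples (25 min)
  removes 1–2-sample spikes without flattening genuine meal rises, and is
  configurable. Smoothing is applied to training data only: smoothing the
  test series would alter the very targets the evaluation measures.

## Event-to-continuous transforms

* **Operative carbs** (piecewise linear, sample-indexed): zero for the
  first 3 samples after a meal, rise of 11.1 % of the meal's grams per
  sample to a peak equal to the meal size at sample 12 (60 min), decay of
  2.8 % per sample reaching zero at sample 48 (3 h after the peak). The
  printed rates do not multiply out exactly (9 × 0.111 = 0.999;
  1 − 36 × 0.028 = −0.008), so values are clamped to `[0, C_meal]`; the
  clamp is what makes the peak exactly `C_meal` and the tail exactly
  zero. The bound of the decay branch places "zero after 3 h" at three
  hours *after the peak* (4 h after the meal), and the implementation
  follows that bound. A single absorption profile is used for all meals;
  glycaemic-index-specific curves are out of scope.
* **Active insulin**: dose × IOB(t) under the exponential
  insulin-on-board model, parameterised by peak activity time `tp`
  (65 min child / 75 min adult presets) and duration of insulin action
  `td` (360 min default). The derived constants are
  `τ = tp(1 − tp/td)/(1 − 2tp/td)`, `a = 2τ/td`,
  `S = 1/(1 − a + (1 + a)e^{−td/τ})`; the scale factor S is constructed
  so that IOB(td) = 0 exactly, and `tp < td/2` is enforced (the τ
  expression has a pole at `tp = td/2`). Tiny negative floating-point
  residues near `td` are clipped to zero, which is why a 1-min scan first
  reaches `IOB ≤ 1e−9` exactly at `td`.
* **Superposition.** Overlapping meals or boluses add linearly, and both
  transforms are linear in event magnitude. Linearity is the only
  combination rule consistent with scaling a single event, and it makes
  the brute-force oracle (sum of shifted single-event curves) an exact
  cross-check. Events are snapped to their nearest grid slot so the
  kernel argument stays an integer sample offset.

## Windowing and splits

* Windows pair 6 history samples (30 min) with the following 6 or 12
  targets. The default stride for *evaluation* equals the history length
  (non-overlapping blocks), which reproduces the block-count arithmetic
  of the study design: 9288 rows → 1548 examples, 2322 → 387. That
  arithmetic counts windows by their history alone, so the final windows'
  targets can run past the end of the series; those positions are masked
  out of evaluation (tail policy `"mask"`). A `"strict"` policy that
  requires history *and* horizon to fit is available and is the default
  nowhere except where bleeding past the end would be wrong (building
  training windows).
* *Training* windows slide with stride 1 by default, the dense scheme
  used during window-size tuning; it multiplies the number of training
  examples by the history length and measurably improves convergence at
  small data sizes.
* **Rolling-origin validation:** k = 5 expanding splits with constant
  validation size `floor(n/(k+1))` and training sizes `n − (k−i)·val`
  (scikit-learn `TimeSeriesSplit` semantics); for n = 11,611 this gives
  1936/3871/5806/7741/9676 with validation 1935. A chronological 80/20
  holdout is provided as the lighter alternative and is what
  `train_and_evaluate` uses. Windows are always built inside a block, so
  none bridges a train/validation boundary.
* **Standardisation** is per channel, fit on training rows only;
  zero-variance channels are rejected rather than silently passed
  through.

## Forecaster

Stacked LSTM: recurrent layer 1 (default 128 units, sequence-emitting) →
leaky ReLU (slope 0.01) → dropout (0.2) → recurrent layer 2 (64 units,
final state) → dropout → dense linear head of `horizon_len` units. The
leaky-ReLU and dropout stages follow the recurrent layer's output rather
than replacing its internal activations. A single-layer variant
(`stacked=False`) and a true bidirectional wrapper
(`bidirectional=True`) exist; bidirectionality is off by default —
reading a forecast window right-to-left is nonstandard for pure
forecasting and is provided for completeness only. Dropout rate,
leaky-ReLU slope and the epoch budget are conventional defaults
(0.2 / 0.01 / 100 with early stopping, patience 10), all configurable.

Training minimises MSE on standardised targets with Adam (lr 0.001,
batch 128 by default). Because no deep-learning framework is a
dependency, the backend (LSTM forward/backward-through-time, dropout,
Adam) is implemented in numpy inside the package; its gradients are
validated against central finite differences in the test suite, and all
randomness flows through one seeded PCG64 generator, so a seed fixes the
trained weights bit-for-bit. Non-finite losses abort with a diagnostic
(pointing at input scaling and learning rate) instead of training
through NaNs.

## Evaluation

RMSE in mg/dL, pooling every horizon position of every walk-forward
window into one mean — a single comparable number per (configuration,
horizon) — with a per-step breakdown reported alongside. Only
sensor-recorded targets count: imputed and past-the-end positions are
masked, and an all-masked evaluation is an error rather than zero. The
walk-forward scheme applies frozen weights to consecutive
non-overlapping test windows with no refitting between steps.
`compare_configurations` repeats training over a seed list and reports
the per-cell seed median, which is robust to the occasional bad
optimisation run; the seeds used are recorded in the tidy output table.

## Synthetic patients

The simulator emulates the *statistical shape* of pump-wearer records,
not the physiology: glucose = baseline (120 mg/dL) + circadian sinusoid
(amplitude 15) + meal effects − insulin effects + AR(1) noise
(innovation sd 3, coefficient 0.95 → stationary sd ≈ 9.6), clipped to
the 40–400 mg/dL sensor range. Meal effects use the operative-carbs
kernel (gain 2.5 mg/dL per gram at peak) and insulin effects the
unit-normalised IOB activity kernel (35 mg/dL per unit at peak); meals
arrive Poisson-like (~3.5/day in waking hours, 20–90 g) with boluses
0.1 U/g fifteen minutes earlier. Sensor realism: missing runs
(~0.5 gaps/day of 2–24 samples) and rare ±40 mg/dL spikes. The last 20 %
of days form the test part, split on a day boundary.

Because the simulator reuses the package's own kinetic kernels, the
multivariate configurations are informative *by construction*: passing
the C-03 ≤ C-01 comparison shows the pipeline extracts and exploits the
event information, not that real patients obey these kernels. Linearity
of effects, absence of glucose–insulin feedback, exercise and stress are
the main departures from real data, so absolute RMSE values on synthetic
patients say nothing about clinical accuracy.

## Problem sizes used in tests

Desk-scale choices, made once: 14-day patients (≈4000 samples, the scale
at which the compact model converges past the persistence baseline),
compact 32/16-unit networks, learning rate 3e-3, ≤60 epochs with early
stopping, and five paired (patient, training-seed) runs for the
configuration comparison — patient seeds 100–104 with training seeds
0–4. The analytic kinetics checks run on single events in seconds.

## Known limitations

* The XML reader supports the compact dialect documented in the README,
  not every field of the public releases (basal, finger sticks and
  activity containers are ignored with a warning; self-reported meal
  times are taken at face value, with no correction for reporting lag).
* One carb-absorption profile for all meals; no basal-insulin kinetics.
* The numpy training loop is single-threaded BLAS-bound; it is sized for
  desk-scale experiments, not for large hyperparameter sweeps.
* Error-grid and event-detection metrics (hypo/hyperglycaemia) are not
  implemented; the package reports RMSE only.
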