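# Methods

`copgait` estimates the *global* centre of pressure (COP) during treadmill
walking — the point of application of the net ground reaction force,
expressed in a pelvis-centred frame, whose trace over gait cycles is the
butterfly-shaped *gaitogram* — directly from raw wearable-sensor signals,
with no sensor fusion, de-biasing or biomechanical modelling in between.
This note records the models, the synthetic data that stands in for
laboratory recordings, and the numerical and design choices a maintainer
would want to know about.

## Signal representation

Each of the seven body-worn sensors (lower back, both thighs, shanks and
feet; location labels 2–8) contributes nine channels per 10 ms sample, the
*GAM* stack:

* **G** — body-frame angular velocity ω (rad/s),
* **A** — the earth gravity direction expressed in the sensor frame
  (unit-normalized, dimensionless),
* **M** — the earth magnetic-field direction in the sensor frame (unit).

A and M are kept as unit *directions* rather than physical magnitudes: the
regressors are scale-free after fitting, and unit vectors make converted
motion-capture data and simulated sensor data commensurate.

The representation is lossless for orientation: one (A, M) pair determines
the attitude via QUEST, implemented here as the symmetric eigenvalue
solution of Wahba's problem (largest eigenvector of Davenport's K matrix,
equal weights for the two observations) — the formulation that stays robust
with exactly two vector observations.  Quaternions are Hamilton,
scalar-first, mapping sensor frame → earth frame; a physical sensor
therefore measures earth vectors rotated by the conjugate.  The G channel
is synthesized from orientation tracks through ω = 2·vec(q* ⊗ q̇), with q̇
by central differences after a sign-alignment pass (q and −q encode the
same rotation; alignment removes the spurious discontinuities before
differencing).

Two numerical facts shape the tests around this block:

* sign-invariant quaternion distances use the chord form
  2·arcsin(‖q₁ ∓ q₂‖/2); the textbook 2·arccos(|q₁·q₂|) loses half the
  significant digits near zero and floors at ~1e-8 rad;
* the central-difference ω carries an O(dt²) secular term (the discarded
  scalar part of q* ⊗ q̇), so re-integrating ω reproduces a 10 s, ≤2 Hz
  track to ~1e-2 rad at 100 Hz and ~5e-5 rad at 1 kHz.  The (A, M) → QUEST
  round trip, by contrast, is exact to machine precision and is the primary
  consistency check.

Marker-triplet input (motion-capture style) is supported: the triplet frame
is x along p₂−p₁, z along (p₂−p₁)×(p₃−p₁), y completing the right-handed
set; a per-segment mounting quaternion (identity by default) absorbs the
fixed rotation between a marker frame and the corresponding sensor frame,
since no universal value exists for it.

## Models

Both regressors map the most recent signal history to the 2-D COP (x
anterior, y lateral, mm), both components fitted jointly.

**Linear baseline.**  Multivariate least squares on a flat design matrix:
per channel, the samples at lags 0…h−1 (h = 1 or 10; 10 samples = 0.1 s at
100 Hz, the history length beyond which no gain was found).  The solve is
`lstsq` with an rcond cutoff of 1e-8, i.e. the minimum-norm solution with
numerically-null directions dropped — without the cutoff, noiseless
synthetic sessions (whose channels are heavily collinear) let round-off in
near-null directions leak into test predictions at the 1e-4 mm level.
Weighted refits (used by calibration) scale rows by √w.

**LSTM.**  A single layer of 100 LSTM units reads the 10-sample window
(hidden state reset per window, so predictions are order-independent and
the memory is hard-capped at 0.1 s), followed by a linear readout of the
last hidden state.  The cell is implemented in NumPy (forward,
backprop-through-time, Adam) in float64; training is bit-reproducible for a
fixed seed.  Defaults: Glorot-uniform initialization with forget-gate bias
1.0, Adam at learning rate 0.001, batch 256, and a patience rule (stop
after 10 epochs without train-loss improvement, keep the best-epoch
weights) standing in for "train until the error stops decreasing".
Inputs are z-scored per feature on the training data.  The two targets are
also z-scored *inside* the optimizer and predictions mapped back to mm:
with the fixed 0.001 learning rate, mm-scale readout weights would need
~10⁴ Adam steps just to grow to magnitude, which the compact training
budgets here do not contain.  The per-output scaling reweights the two
components in the loss slightly; reported errors are always in mm.

**Calibration (`fine_tune`).**  A short quiet-standing recording of a new
subject adapts a pooled model: the linear model refits on original +
calibration rows with the calibration upweighted 10×; the LSTM continues
Adam on the calibration windows alone at 0.1× the base learning rate for at
most 50 epochs.  The LSTM variant tracks the full-batch calibration loss
and starts from the pre-tune weights as incumbent, so the tuned model is
never worse on the calibration set than the model it started from.
Calibration duration defaults to 30 s, with 60 s one flag away (both are
common choices for standing-calibration protocols).

## Error metric

Lateral and anterior RMS errors are reported separately;
`total = sqrt((lateral² + anterior²)/2)` pools the squared component errors
— the convention under which published result-table totals reproduce
exactly from their printed lateral/anterior cells (17.3 & 25.5 → 21.8).
Averages over subjects are unweighted means.

## Synthetic gait generator

The laboratory data this method targets (instrumented-treadmill COP +
seven IMUs) is not publicly deposited, so the package carries a seeded
generator used by every study and test.  What it emulates:

* **Protocols.**  The healthy 9-step schedule (quiet standing; 0.38, 0.5,
  0.8 m/s walking with 0/10/15 %BW mediolateral perturbations; quiet
  standing; 2280 s total) and the reduced 6-step schedule for stroke
  subjects, reproduced verbatim; arbitrary custom schedules for scaled-down
  runs.
* **The butterfly.**  One COP cycle template is built piecewise — during
  single support the COP dwells at ±step_width/2 laterally while sweeping
  anteriorly over ±0.2·step_length; during double support it crosses
  diagonally to the other foot — then circularly Gaussian-smoothed
  (σ = 0.015 cycle).  Defaults (cadence 1.4 steps/s, step length 500 mm,
  step width 100 mm, double-support fraction 0.25 at the 0.5 m/s reference
  speed) give excursions of roughly ±100 mm anterior and ±50 mm lateral,
  plausible for slow treadmill walking; they are configuration, not claims
  about any particular cohort.  For a symmetric gait the template is
  mirror-symmetrized exactly, so lateral COP means vanish to float
  precision over whole cycles; the `asymmetry` parameter (0–1) skews
  left/right dwell and excursion the way hemiparetic gait distorts the
  butterfly.
* **Kinematics.**  All segments are driven by one cycle clock whose rate
  and amplitudes scale with √(speed/0.5).  The trunk is pelvis-driven in a
  strong sense: its roll/pitch carry the first four cycle harmonics of the
  lateral/anterior COP templates (the global COP is tied to centre-of-mass
  motion, which the pelvis approximates), while limb segments carry generic
  first/second-harmonic flexion sinusoids with side-specific phases.  Two
  consequences are deliberate and testable: the lower back is the single
  most informative sensor, and a linear model faces an irreducible residual
  (the template's harmonics above four) that the LSTM, which can
  reconstruct the phase and apply the full nonlinear template, does not —
  mirroring the ordering of the two models on real data.
* **Perturbations.**  150 ms mediolateral force pulses (10/15 %BW, 3 mm per
  %BW of COP deflection, randomized sign, ≥6 s recovery spacing) appear
  only inside perturbation-labelled steps, with a small matching
  balance-response roll of the trunk.
* **Noise.**  Zero-mean Gaussian noise with sd = 3% of each channel's RMS
  (the observed fluctuation size of a static sensor relative to walking
  signals) is added to the GAM channels only; the treadmill-side ground
  truth (COP, pelvis track) is treated as the reference instrument and
  kept clean.  The kinematics and noise streams are seeded independently,
  so changing the noise level never changes the motion.
* **Cohorts.**  Subjects draw unit-mean lognormal factors (CV =
  `inter_subject_sd`) on cadence, step length/width and double support,
  plus a habitual postural lean: a constant COP offset with a matching
  static trunk tilt (0.002 rad/mm).  The lean is what standing calibration
  can genuinely correct — the synthetic analogue of the posture and sensor
  placement differences that motivate calibrating transferred models.

A linear-truth variant (`simulate_linear_session`) replaces the butterfly
with a COP that is an *exact* linear map of the current clean channels.
The generating weights are drawn inside the well-conditioned subspace of
the feature matrix (singular values ≥ 1e-3 of the largest), which makes the
target exactly learnable from either half of a split; the analytic noise
floor of the best linear predictor under input noise,
WᵀCW − WᵀC(C+D)⁻¹CW (C the clean-feature covariance, D the injected noise
covariance), accounts for channel redundancy — weight spread across
correlated channels averages their noise, so this floor is the correct
benchmark, not the naive per-channel propagation.

What the generator does **not** emulate: force balance and GRF magnitudes
(no dynamics), soft-tissue artefact, magnetometer disturbances
(hard/soft-iron effects), treadmill-belt dynamics, or non-stationary gait
drift.  Tests passing on this data certify the pipeline's correctness and
the claimed orderings (LSTM < linear error; back > limb sensors;
calibration helps transfer), not clinical-grade absolute accuracies.

## Study designs

* **Intra-subject**: first 50% of every protocol step trains, the last 50%
  tests; windows never straddle step boundaries and are rebuilt per split.
* **Train-set size**: uniformly-placed contiguous blocks (contiguity avoids
  the leakage of randomly interleaved train/test samples in a smooth time
  series), repeated per size; mean ± sd of test RMS.
* **Sensor ablation**: all 2⁷−1 = 127 non-empty sensor subsets, retrained
  from scratch per subset (linear model by default; the sweep is cheap).
  Best-per-count comparisons use a 0.005 mm tolerance: above ~3 sensors the
  curve is flat and the test-half RMS of nested fits carries an O(p/n)
  overfitting tail of ~0.001 mm, far below the 0.1 mm at which placement
  tables are read.
* **Transfer**: leave-one-subject-out — case A fits one model on all other
  subjects pooled; case B additionally fine-tunes on the held-out subject's
  first 30 s of quiet standing.

## Problem sizes

Studies and tests run on scaled-down sessions chosen so the whole suite
executes in minutes on one CPU core: 60–150 s single-subject sessions
(6,000–15,000 samples), 300 s for learning curves, 6-subject cohorts of
180 s each for transfer, and LSTM budgets of 25–120 epochs.  At these sizes
every qualitative result is stable across seeds; the linear studies are
bit-reproducible and the LSTM studies loss-trace-reproducible for a fixed
seed.  The transfer acceptance battery uses the linear model; the LSTM
calibration path is exercised at unit-test scale.

## Known limitations

* The pelvis-frame transform is translation-only (axes stay
  treadmill-aligned); whether pelvis yaw should also be removed is left
  configurable; lateral/anterior error components are conventionally
  reported in treadmill-aligned axes.
* The NumPy LSTM is single-threaded and float64 — deliberately simple and
  reproducible, not fast; hidden sizes beyond a few hundred units would
  want a compiled backend.
* Perturbation-recovery segments are included in train/test (exclusion is
  not implemented).
* No significance testing across subjects; reported numbers are means.
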