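# Methods

This note documents the models implemented in `wristemg`, the choices
made where the design was genuinely open, and what the synthetic data
do and do not establish.

## Synthetic sEMG model

Real surface EMG is, to a useful first approximation, amplitude-
modulated band-limited noise: the interference pattern of many motor
units looks Gaussian at moderate contraction levels, with most energy
between roughly 20 and 450 Hz.  The generator reproduces exactly that
and nothing more.  Each channel carries white Gaussian noise passed
through a 4th-order Butterworth band-pass (20–450 Hz, zero-phase), then
rescaled so that the channel's expected mean absolute value equals

    MAV_c = profile[movement, c] × (base_amplitude + load_gain × load).

Because a linear filter preserves Gaussianity, E[|X|] = σ√(2/π) gives
the required σ per channel.  Rescaling uses the realised (empirical)
standard deviation of the filtered carrier, so the per-recording MAV is
very close to its target even at short durations; convergence with
duration is tested explicitly.

Parameters and defaults:

* `sampling_rate` = 1000 Hz.  Armband hardware rates vary; 1 kHz is a
  common choice for myoelectric control and is configurable.
* `activation_profile`: each active movement has 2 dominant channels
  (factor 1.0), 2 moderate (0.5), 4 weak (0.15), with the dominant pair
  rotating around the 8-electrode ring; RELAX is uniformly 0.05.  This
  mimics the channel-specific bursts of real armband data, guarantees
  pairwise-distinct rows (classes separable in expectation), and keeps
  RELAX strictly below every movement on every channel — both are
  enforced as validation invariants.
* `base_amplitude` = 1 signal unit, `load_gain` = 0.02 units/N: a 50 N
  load doubles the amplitude.  Signal units are arbitrary but
  consistent across modules; no absolute calibration is claimed.
* Per-recording seeds in `generate_dataset` are spawned from the config
  seed (`SeedSequence.spawn`), so datasets are reproducible yet free of
  shared noise realisations.

The generator makes movement classes separable *by construction* in
expected-MAV space and makes MAV affine in load — the two premises the
classifier and the static force model rely on.  It deliberately omits
motor-unit dynamics, electrode shift, crosstalk structure, fatigue, and
non-stationarity, so passing tests demonstrate the pipeline's internal
correctness, not its accuracy on human recordings.

The kinematics generator produces an out-and-back minimum-jerk angle
trajectory (10τ³ − 15τ⁴ + 6τ⁵ in each half), centred in the trace; the
movement occupies half the trace in slow mode and a quarter in fast
mode, so fast mode halves the movement time and quadruples the peak
angular acceleration (1/T² scaling).  The angular acceleration is
returned analytically and checked against the second difference.

## Features

The five time-domain features use the conventions stated in the README
formulas, including two deliberate non-standard details:

* ZC and WL are normalised by the window length N (rates per sample
  rather than raw counts/sums).  This changes only a constant factor at
  fixed window length and is kept as part of the feature contract.
* The ZC difference condition uses |xᵢ − xᵢ₊₁| > x_th.  Without the
  absolute value the condition would depend on the sign ordering of the
  crossing, which contradicts its symmetric intent as a noise guard.
* VAR divides by N (population convention), not N−1.

Windowing defaults to 200 ms windows with a 50 ms step — standard
myoelectric-control practice, short enough for responsive control and
long enough for stable amplitude estimates.  The ZC threshold defaults
to 0.01 × the per-window RMS, an adaptive noise floor; an absolute
threshold can be configured instead.  Column order is channel-major
(`ch1_MAV … ch8_WL`) and stable.

## ReliefF selection

The canonical multiclass ReliefF: features are min-max scaled to [0,1]
(making weights scale-invariant; constant columns get weight exactly
0), distances are Manhattan, and for each instance the k nearest hits
and, per other class, k nearest misses update each weight by
−diff/(m·k) and +[P(C)/(1−P(own))]·diff/(m·k) respectively.  Defaults:
k = 10 and exhaustive iteration over all instances, which removes
sampling noise at the few-hundred-window scale this package targets
(a seeded subsample is available for larger data).  Selection keeps the
top 2 features per channel; boundary ties resolve by the fixed feature
order MAV < RMS < VAR < ZC < WL so output is deterministic.

## Classifier

A from-scratch numpy MLP so the backward pass can be verified against
central finite differences (tested to 1e-5 relative on random 4-3-3-2
networks, sigmoid and ReLU).  Choices where the classical BPNN recipe
leaves room:

* Hidden width from M = round(√(m+n)) + a (half-up rounding, a ∈
  [0,10]); both hidden layers share the width.  16 inputs and 7 outputs
  with a = 10 give 15.
* Sigmoid hidden activations (the classical choice; ReLU available),
  softmax output feeding the cross-entropy.
* Full-batch gradient descent.  The step uses the cross-entropy
  *summed* over the training set; with the conventional learning rate
  of 1e-3 this is equivalent to mean-loss descent with an effective
  step of n_train/1000, which converges comfortably within 5,000
  iterations at the 336-sample training size used throughout.  The
  reported loss curve is the per-sample mean, so a balanced 7-class
  problem starts near ln 7 ≈ 1.95.
* Glorot-uniform initialisation (±√(6/(fan_in+fan_out))), seeded; zero
  biases.  Stratified 80/20 split.  Features are z-scored with
  training-set statistics stored in the model; `forward`/`predict`
  expect raw features and standardise internally (a test guards
  against double standardisation).
* Probabilities are clamped at 1e-12 before logs; argmax ties resolve
  to the earlier label in the fixed label order.
* Non-finite training loss aborts with a diagnostic rather than
  returning a silently broken model.

## Decision smoothing

The vote window and the trigger run length are both 5.  Open details
and their resolutions:

* Vote ties keep the previous output when it is among the tied labels
  (minimising command chatter), else the tied label occurring earliest
  in the window.
* The first four frames vote over the partial window instead of
  waiting, so the smoothed stream is length-preserving — convenient for
  frame-aligned evaluation.
* The trigger emits once when a run of five identical non-RELAX voted
  results completes and re-arms only after the run breaks, so a held
  posture issues exactly one command.  RELAX is the rest state, not a
  robot instruction, and never triggers.

Under an iid error model at per-frame accuracy p, a 5-window majority
is correct whenever at most 2 frames err, giving the closed-form lower
bound Σ_{k≤2} C(5,k)(1−p)^k p^{5−k} (≈ 0.993 at p = 0.907); the bound
is conservative because split errors often lose the plurality anyway.
This binomial oracle anchors the smoothing tests.

## Force models

The static model regresses external load (N, response) on mean MAV
(predictor) by ordinary least squares, matching the published model
form F = slope·MAV + intercept; the published coefficient set for the
four directions is stored as a fixture (`PRINTED_STATIC_MODELS`).  The
flexion model is taken to use the flexion MAV (the source's subscript
there appears to be a typo).  The dynamic model is the rigid-body
identity F₀ + mg + m·r·β̈ with g = 9.81 m/s² and r = 0.07 m (both
configurable); masses may be specified via the weight force, m = G/g.
MAV-to-force traces average the per-window MAV across channels by
default (a channel subset can be given); the window for force
estimation defaults to 1 s, longer than the recognition window because
force tracking favours amplitude stability over latency.

RMSE figures for force tracking on human subjects depend on recorded
human data and are not reproduced here; the package instead verifies
the computation by (a) parameter recovery — fitting synthetic load
tables (10 loads × 3 reps, 0.5 N noise) recovers the generating
coefficients to within 0.05 in slope and 0.8 N in intercept in each of
100 seeds; (b) exact limiting cases — m = 0 reduces the dynamic model
to F₀, β̈ ≡ 0 to F₀ + mg; and (c) an end-to-end check that models
fitted from generated recordings predict held-out loads to < 1 N mean
absolute error.

## Evaluation

Accuracies from outcome counts are exact rationals
(`fractions.Fraction`); percent display rounds half-up to one decimal
and never feeds back into computation (1777/1800 → 98.7%).

## Problem sizes

Tests and the acceptance script run at desk scale: 60 analysis windows
per movement (one 3.15 s recording each at the default windowing),
≤ 5,000 training iterations, 100,000-frame label streams for the voting
null, and 100 seeds for force-model recovery.  These sizes were chosen
so the whole suite completes in seconds while keeping every statistical
check far from its tolerance boundary.

## Known limitations

* The generator's amplitude-only coding makes the classification task
  easier than real armband data, where classes overlap; the ≥ 97.4%
  held-out accuracy is a plumbing check on a separable set, not a
  claim about human sEMG.
* ReliefF's exhaustive mode is O(n²) in instances; use the sampled mode
  beyond a few thousand windows.
* The static force models are per-direction affine maps; they do not
  model co-contraction, fatigue drift, or electrode-placement changes.
* The CLI exchanges plain-text CSV/JSON only; no streaming or hardware
  I/O.
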