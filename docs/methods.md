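# Methods

This note documents the models, numerical choices and known limitations of
`squatmon`. It complements the README, which describes what the package
does; here we explain how, and why the defaults are what they are.

## Conventions

All accelerometer channels are specific force in m/s² in the sensor frame
(g = 9.80665 m/s²; a stationary level sensor reads (0, 0, +g)); gyroscopes
are rad/s in the sensor frame; magnetometer samples are normalized to unit
direction on read, since attitude estimation uses the field direction
only. The Earth frame is ENU (+z up, horizontal magnetic component due
north with a 60° downward inclination in the simulator). Orientation is a
unit quaternion q mapping sensor-frame vectors into the Earth frame,
renormalized after every update step.

## Attitude estimation and gravity removal

The Mahony complementary filter propagates q with the gyroscope and
corrects it with a proportional–integral feedback on the direction error
e = â × v̂, where â is the normalized accelerometer reading and
v̂ = Rᵀẑ the predicted gravity direction. In 9-axis mode a magnetometer
term is added using the standard horizontal-reference construction, which
constrains yaw without disturbing roll/pitch. Defaults: kp = 2.0 s⁻¹,
ki = 0.1 s⁻², integral clamped at 0.2 rad/s (anti-windup).

Two refinements matter in practice:

* **Accelerometer validity gate.** The correction weight tapers linearly
  to zero as |‖a‖ − g| approaches 0.3 g. During the dynamic phase of a
  squat the specific force does not point along gravity; an ungated filter
  chases it and accrues ~5° of attitude error (~0.1 g of fake "gravity-free"
  acceleration). Gated, the filter coasts on the gyroscope through the
  movement and re-anchors during the slow phases. The width is
  configurable; 0.3 g passes squat-scale dynamics while still accepting
  quiet-standing samples.
* **Initialization.** Roll/pitch come from the first 0.5 s accelerometer
  mean; with a magnetometer present, yaw comes from the horizontal field
  component (TRIAD). Gravity-only initialization leaves yaw arbitrary, and
  a near-180° yaw error sits close to the magnetometer term's unstable
  equilibrium: convergence is then slow and the wound-up integral
  transiently biases roll/pitch. TRIAD initialization removes the problem
  at its source. A 5 s warm-up window is still excluded from all
  downstream segmentation.

Gravity removal is algebraically exact when the orientation is exact
(rotate to Earth frame, subtract (0, 0, g), rotate back); the tests verify
≤ 1e-9 m/s² residual over 100 random static attitudes, so all observed
error in the 36-signal output is attributable to attitude estimation.

## Repetition segmentation

A repetition is a valley-then-peak pair of a driver signal, delimited by
the zero crossing before the valley and after the peak. The driver is the
sacrum's Earth-vertical gravity-free acceleration, low-passed at 2 Hz
(6th-order zero-phase Butterworth), then integrated once to a vertical
velocity. On velocity, the valley/peak are maximum descent/ascent speed
and the zero crossings are the standing turn-points — exactly the
repetition boundaries. On raw acceleration the zero crossings fall
mid-descent and mid-ascent, a quarter period away from the boundaries, so
the velocity form is the default (`SegmentationParams.driver` switches
back).

Integration drift is removed by subtracting a centered rolling median of
the velocity. A fixed window beats against the repetition period, so
detection runs twice: a first pass with a 4 s window yields the extrema,
their median spacing estimates the period, and a second pass locks the
window to two periods (the median of a periodic zero-mean waveform over
two periods is zero). An optional 0.15 Hz high-pass is available for very
drifty data but is off by default: its step-response droop shifts the
boundary crossings by ~0.1–0.3 s.

Extrema come from `scipy.signal.find_peaks` with prominence ≥ 0.5 × the
driver's IQR. The minimum-separation constraint (default 1.0 s) applies
within each kind only: the valley and peak of one fast repetition are
legitimately closer than that, so across kinds the sequence is merely
forced to alternate (runs of same-kind extrema collapse to the most
prominent). Zero-crossing searches are bounded to ~1.2 half-cycles around
each extremum; when an offset baseline leaves no sign change there, the
nearest sample inside the zero band (default 0.05 driver units) is used,
then the midpoint to the adjacent extremum. Boundary-incomplete cycles at
the trial edges are dropped and logged.

Accuracy: on noise-free simulator trials boundaries land within 0.06 s of
the configured cycle edges. With 5 % driver noise the counts stay exact,
but boundary localization degrades to ~0.3–0.4 s worst-case — inherently:
the standing transitions are stationary points of the whole kinematic
chain, vertical acceleration is ≈ 0 there and velocity leaves zero
cubically, so a zero crossing under noise is ambiguous within ±0.2 s. The
class-discriminative content of a window is insensitive to boundary
wobble of this size (the classification results below are unaffected).

## Feature bank

375 features per sensor, 2250 over the montage. Derived signals per
sensor: time-domain triaxial {0g acceleration, angular velocity, and
their jerks (first difference × rate)} plus the Euclidean magnitude of
each; frequency-domain one-sided amplitude spectra (2|X|/n, so
length-invariant for tones) of the triaxial 0g acceleration, acceleration
jerk and angular velocity, and of all four magnitude signals. Statistics:

* both domains: mean, SD, median absolute deviation, max, min, SMA (mean
  across-axis sum of absolute values), energy (mean of squares), IQR,
  entropy;
* time only: Burg AR(4) coefficients per axis (via
  `statsmodels.regression.linear_model.burg`) and Pearson correlations of
  the axis pairs xy/xz/yz;
* frequency only: maxInds (frequency in Hz of the largest amplitude bin),
  power-weighted mean frequency, and the skewness/kurtosis of the
  amplitude values.

That yields 40 per time-domain triaxial signal, 13 per time-domain
magnitude, 37 per frequency-domain triaxial, 13 per frequency-domain
magnitude: 4·40 + 4·13 + 3·37 + 4·13 = 375. The registry ships as
`feature_manifest.tsv` (index, sensor, signal, statistic, axis) and the
emitted row length is checked against it at extraction time.

Choices not fixed by the statistic names: time-domain entropy uses a
16-bin histogram on the segment's own range (a constant signal has
entropy 0); frequency-domain entropy is the Shannon entropy of the
power-normalized spectrum; maxInds is reported as a frequency rather than
a bin index so that it, like every other statistic, is invariant to
segment length — repetitions last between roughly 2 and 5 s and are
deliberately not resampled to a common length. Time-domain statistics are
computed on 2 Hz-smoothed windows (squat kinematics live below 2 Hz);
spectra are taken from the 20 Hz windows, since a 2 Hz-filtered signal
has almost no spectrum left to summarize. Any non-finite statistic (e.g.
moments of a degenerate spectrum) is set to 0 and logged, so tables never
contain missing values.

Scaling is the robust (median/IQR) transform, fitted on training rows
only; zero-IQR features are flagged constant and given scale 1. Recursive
feature elimination uses a linear maximal-margin base estimator
(coefficient-magnitude ranking, eliminating 5 % of remaining features per
round); the default target of 769 of 2250 columns matches the reduction
ratio of the original study, and a sweep mode picks the count maximizing
stratified CV accuracy. An optional row screen (reject > 1 % non-finite
raw features or durations outside 1–10 s) exists but is off by default;
it documents a plausible, not an attested, rule.

## Classifiers and metrics

DT (Gini, unlimited depth), RF (100 trees), KNN (k = 5, Euclidean), SVM
(RBF, C = 1, one-vs-rest, probability estimates enabled) and MLP (one
hidden layer of 100 ReLU units, softmax output, ≤ 500 epochs), all
seed-controlled through scikit-learn. Evaluation: stratified 70/30 split
and stratified 10-fold CV. The macro metrics treat the confusion matrix
with actual classes along rows and predicted along columns and average
the one-vs-rest accuracy, specificity, sensitivity and precision over the
six classes; classes with a zero denominator are excluded from that
metric's mean with a warning rather than contributing NaN. Probability
vectors always cover all six classes in label order; advice codes list
every error class at or above the mixed-error threshold (default 0.25),
which is what enables combined feedback such as KOT + RH.

## Sensor agreement

Streams from co-located sensor pairs are lag-aligned by maximizing the
normalized cross-correlation of a driver channel (alignment peaks below
0.2 fall back to zero lag with a warning). Per channel, agreement is the
Pearson R and the magnitude squared coherence |P_ab|²/(P_aa·P_bb) from
Welch estimates with 2 s Hann windows at 50 % overlap, summarized as the
mean over 0.1–5 Hz — squat energy lies below 5 Hz, and 2 s windows keep
≥ 2 windows even on short trials (a single window's coherence is
identically 1, hence the hard error below two). The conventional 0.5
coherence threshold is exposed as a report flag, not a failure.

## The squat simulator

An articulated chain — foot-fixed ankle, shank, thigh, pelvis, trunk —
performs raised-cosine knee-flexion cycles (activation
c(t) = (1 − cos 2πt/T)/2), with a frontal-plane knee degree of freedom
for valgus. Default conditions: 3 s repetitions, 1.5 rad peak knee
flexion, 0.35 rad trunk lean, 6 s standing lead-in (covering the filter
warm-up) and 3 s tail; anthropometry shank 0.43 m, thigh 0.42 m, trunk
0.50 m, 0.30 m lateral stance. Error classes perturb the base kinematics
as listed in the module docstring, scaled by a severity in [0, 1]
(default 0.8); severity 0 is exactly the correct pattern, and the mean
angular deviation from it is monotone in severity. Sensor positions and
orientations follow the segment frames; accelerometers render
Rᵀ(a_kin + gẑ) with a_kin from double numerical differentiation of the
site positions (second-order central differences; relative error ~3e-5 at
100 Hz against the closed-form pendulum reduction), gyroscopes from the
quaternion derivative, magnetometers from the fixed Earth field. White
Gaussian noise (defaults: 0.10 m/s², 0.01 rad/s, 0.005 unitless) and a
constant per-sensor gyro bias (SD 0.005 rad/s) are drawn from the config
seed, making trials bit-reproducible. The benchmark generator jitters
depth, period and trunk lean per subject (5 % fractional SD).

What the simulator does *not* emulate: soft-tissue artifact, sensor
mounting misalignment, magnetic disturbances, fatigue-induced drift of
technique, inter-repetition variability within a trial, and barbell load
kinetics. Classes are therefore cleanly separated, and the end-to-end
benchmark (6 classes × 5 subjects × 10 reps) is recovered by the MLP at
essentially perfect CV accuracy. Passing it shows the pipeline is
internally consistent — signals rendered with embedded gravity are
reconstructed, segmented, featurized and classified back to their
generating labels — not that comparable accuracy would be reached on
human recordings.

## Real-time path

The online monitor repeats the batch chain causally: single-pass
Butterworth filters (state carried per channel), incremental Mahony
updates, and a leaky integrator (0.15 Hz corner) for the velocity driver.
Cycle detection is a hysteresis state machine (default 0.08 m/s): confirm
valley, confirm peak, then wait for the trailing zero crossing plus a
0.25 s guard before closing the window — trading a quarter second of
latency for boundary stability. Windows outside 1–10 s are rejected.
Because causal filters shift phase where the batch path does not,
borderline windows can classify differently; the suite checks ≥ 80 %
label agreement between the two paths rather than identity.

## Problem sizes

Defaults were chosen so the whole test suite and the acceptance script
each run comfortably on a single CPU: the benchmark is 30 trials of ~40 s
at 100 Hz (300 repetitions, a 300 × 2250 table), cross-validation is
10-fold on that table, and the smaller fixtures use 2 subjects × 5 reps.
All sizes are parameters; nothing in the code depends on these values.

## Known limitations

* The Mahony gains are tuned for squat-like motion at 100 Hz; very slow
  rates or sustained high-acceleration activities would need retuning
  (the gate would starve the corrector).
* Segmentation assumes one dominant vertical oscillation per repetition;
  exercises without a vertical signature (e.g. pure rotations) need a
  different driver channel.
* Boundary localization under heavy noise is limited to ~±0.2 s by the
  stationarity of the standing transitions (see above).
* The RFE default count (769) is a ratio carried over from the original
  study design, not re-derived per dataset; use the sweep mode when the
  feature/sample ratio differs materially.
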