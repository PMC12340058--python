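# Methods

This note records the models, conventions and numerical choices behind
`footgait`, and what the synthetic validation does and does not establish.

## Coordinate conventions and units

Sensor frame: x medial/lateral, y anterior/posterior (the foot's long
axis), z superior/inferior. Canonical units everywhere: seconds, m/s²,
deg/s, metres, degrees. The global coordinate system (GCS) has Z up,
defined by the mean accelerometer direction over quiet standing; gravity
is therefore exactly (0, 0, −g) in the GCS with g estimated from the
first 15 s of standing (constant 9.80665 m/s² is used for synthesis).
Foot pitch is the elevation of the sensor-y axis above the ground plane,
dorsiflexion (toes up) positive, re-zeroed at each cycle's foot flat so
0° means foot parallel to the ground.

## Event detection

Both channels are filtered once, up front, with a 4th-order Butterworth
low-pass at 10 Hz applied forward and backward (`filtfilt`). "Zero-phase
4th order" is read as 4th-order *coefficients* run twice — an effective
8th-order magnitude, −6 dB at the cutoff; the alternative reading
(2nd-order run twice) is a one-line `FilterConfig` change. Everything
downstream (detection, orientation, integration) consumes the filtered
signals.

Mid-swing peaks are local maxima of filtered ωx ≥ 70 deg/s separated by
≥ 0.4 s (double-peak suppression; the slowest plausible stride in this
population is well under 2.5 s). Zero crossings are located by linear
interpolation between samples and rounded to the nearest index; peaks
without both flanking crossings (recording edges) are dropped, as are
cycles with non-alternating crossings. If the trace's dominant peaks are
negative (mirrored mounting of a left-foot sensor), the channel is
sign-flipped after an |max|-vs-|min| polarity check.

## Orientation and stride reconstruction

The orientation filter is a deliberately minimal error-state design:
quaternion propagation by the midpoint gyro rate, plus a small
accelerometer tilt correction (default gain 0.02 per sample, ~0.5 s time
constant at 100 Hz) applied only when ‖acc‖ is within 5% of 1 g — during
foot flat and standing, when the accelerometer is a trustworthy
inclinometer. Yaw is unobservable without a magnetometer and is allowed
to drift; the per-stride heading alignment (below) removes its effect.
The initial attitude is the shortest rotation taking the mean standing
accelerometer direction to GCS +Z.

Per stride (foot flat to next foot flat): gravity-free acceleration
R·acc + (0,0,−g) is integrated twice with the trapezoidal rule.
Corrections, in order: (1) ZUPT — subtract the linear-in-time
interpolant between the endpoint velocities, making both exactly zero
(the canonical foot-IMU linear drift model); (2) height — subtract a
linear ramp on Z so both endpoints return to Z = 0 (level-ground
assumption); (3) heading — rotate about GCS Z only (never tilting the
vertical) so the endpoint-to-endpoint displacement lies on +Y. Segments
shorter than 4 samples are dropped with a warning.

## Parameters, screening, summaries

Cycle k spans heel contacts k→k+1. Two stride times are kept because
their definitions differ: HC→HC (cadence, stance %, timing
normalisations) and TO→TO (gait speed). Stride length is the 3-D
distance between the bracketing foot-flat positions; walk ratio is
(stride length·1000/2)/cadence in mm/(steps/min); swing foot speed is
the mean 3-D velocity norm over TO→HC (the forward-component mean is a
documented alternative, not implemented). Pitch quantities are evaluated
on [HC_k, HC_{k+1}), times measured from HC_k.

Screening is a single pass: the stride-time band (mean ± 2·sample SD) is
computed once over all cycles including prospective outliers, then the
pitch box (max ≤ +50°, min ≥ −80°) is applied to the remainder; the
first 50 survivors in temporal order are kept (deterministic tie-break).
Fewer than 50 survivors is an error unless `allow_short` is set. CV uses
the sample SD (n−1) over |mean| so negative-mean parameters (e.g. pitch
at toe-off) still get positive CVs; a zero mean yields an undefined CV,
reported as missing and excluded from correlation.

## Association statistics

Shapiro-Wilk (scipy's Royston implementation) gates the method per pair:
Pearson only when *both* variables pass at α = 0.05 — the conservative,
conventional rule when one variable fails. Spearman uses average ranks
for ties and the t approximation (df = n−2) for p, standard at n ≈ 55.
No multiple-testing correction is applied across the 36 correlations by
default. Parameters missing (or constant) for too many subjects are
dropped with a warning rather than poisoning the table.

The a priori sample size solves, by Brent's method on real-valued n,
Power(n) = Φ((z_r − z_c)√(n−3)) + Φ((−z_r − z_c)√(n−3)) = 0.80, with
z_r = atanh(r) + r/(2(n−1)) and z_c = atanh(r_c), r_c the critical
correlation from the two-sided t quantile at n−2 df. For r = 0.37,
α = 0.05, power 0.80 the root is n ≈ 54.19; the integer part, 54, is
returned by default. Note the usual "round up" convention would give 55;
`rounding="ceil"|"nearest"` are exposed for that choice.

## Synthetic data: what it emulates, what it does not

The generator builds a sagittal-plane world: ≥ 30 s quiet standing, then
strides in which the foot is strictly stationary through each stance and
advances during swing with a minimum-jerk horizontal displacement and a
Hann (sin²) vertical clearance bump — C¹ velocity everywhere, bounded
accelerations. Pitch is a monotone cubic (PCHIP) through the event
knots: 0° at FF, the plantarflexion trough at TO, the dorsiflexion peak
at HC. Defaults follow the spatiotemporal profile of community-dwelling
older women: stride time 1.23 s, stance fraction 0.713, stride length
1.0 m, pitch −48.8°/+18.5°, step clearance 0.12 m, 100 Hz, 5%
multiplicative lognormal cycle jitter (keeps times/lengths positive with
a controllable CV); grip strength is lognormal around 0.28 N/kg with SD
0.10.

Two generator-design details matter for interpretation:

* **Events sit on pitch extrema.** With zero-crossing detection on ωx,
  the detected TO/HC *are* the pitch-rate zero crossings, i.e. the pitch
  extrema. The generator therefore defines its true TO/HC at the trough
  and peak (a toe-off-at-peak-plantarflexion model), all event times
  snapped to the sample grid. Auxiliary pitch knots at ±δ (≤ 0.08 s)
  around each extremum keep the signal locally symmetric so zero-phase
  filtering does not displace the crossings; noise-free detection is
  then sample-exact. Real signals have extra wiggles that separate the
  extremum from the event by a few percent of the cycle — the synthetic
  world does not reproduce that.
* **Degenerate extremum timings.** Because the window maximum sits at
  the window boundary (HC), the timing-of-maximum parameter is bistable
  between ~0% and ~100% of the cycle under noise, and timing-of-minimum
  coincides with stance %. Tests therefore assert pitch *values*, not
  extremum *timings*; timing columns are reported but their synthetic
  CVs are not meaningful.

Motion is sagittal-only by default (roll/yaw identically zero), there is
no contralateral foot (no double-support modelling), no turning, no
slopes, and sensor error is white noise plus a constant gyro bias (no
random walk, scale factor or misalignment). Passing tests establish
algorithmic correctness — filters, event logic, integration and
corrections, statistics — under those idealised conditions, not
field-data performance.

Cohorts use a single-latent-factor Gaussian copula: each targeted
parameter's latent is r·g + √(1−r²)·ε with r = 2 sin(πρ/6), so the
population Spearman between grip strength and the parameter equals ρ
exactly and the implied correlation matrix is positive semi-definite by
construction. Marginals are clipped to physiological bounds (e.g.
stance fraction 0.55–0.85, dorsiflexion peak below the +50° screening
limit); the bounds sit in far tails, leaving targets intact (verified at
n = 2000).

## Problem sizes and determinism

Validation runs use 10–55 subjects at 50–60 cycles each and 100 Hz —
minutes-long recordings that exercise every code path while keeping the
whole suite fast. Every stochastic element (jitter, sensor noise,
cohort draws) flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give bit-identical
recordings, tables and CSVs.

## Known limitations

* The orientation filter is a fixed-gain complementary/error-state
  design, not a full covariance-propagating Kalman filter; gains are
  exposed in `OrientationConfig`.
* Stride length error grows with gyro bias (sub-linearly up to 1 deg/s
  on default synthetic data, regression-tested); larger biases or
  long-heading walks without foot flats would need bias estimation.
* Eligibility filtering (female sex, GDS ≤ 1, BMI ≤ 30) and the
  grip-strength normalisation (max force / body mass) are fixed rules
  mirroring the target population; other cohorts need their own rules.
* CV-vs-strength associations in synthetic cohorts are driven solely by
  the cycle-jitter parameter; real gait variability has structure
  (fatigue, turning, terrain) the generator does not model.
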