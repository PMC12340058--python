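# footgait

Foot-mounted IMU gait analysis for studying how walking relates to muscle
strength in older adults.

A single inertial sensor strapped to the foot (3-axis accelerometer +
3-axis gyroscope) records natural walking outside the lab. `footgait`
turns those signals into interpretable gait measures and relates them to
hand grip strength, the standard clinical proxy for overall muscle
strength:

1. **Gait events.** Signals are low-pass filtered (4th-order Butterworth,
   10 Hz, forward–backward for zero phase lag). The mediolateral angular
   velocity ωx shows one large positive peak per stride in mid swing
   (threshold ≥ 70 deg/s); toe-off (TO) is the negative→positive zero
   crossing before the peak, heel contact (HC) the positive→negative
   crossing after it, and foot flat (FF) the midpoint of HC and the next
   TO.
2. **Stride trajectories.** Orientation comes from an error-state filter
   (gyro propagation + accelerometer tilt correction gated near 1 g);
   gravity is calibrated from 15 s of quiet standing. Between consecutive
   foot flats the gravity-free acceleration is double-integrated with a
   zero-velocity update (ZUPT: v(FF) = 0 at both ends), a linear height
   de-drift (Z(FF) = 0, level ground), and a heading rotation aligning each
   stride's displacement with +Y.
3. **Gait parameters.** 18 per-cycle measures — gait speed
   (stride length / TO→TO stride time), height-normalised stride length,
   cadence (120 / HC→HC stride time), stride/stance/swing times, stance %,
   sagittal foot-pitch angles at HC and TO, pitch extremes with their
   values/timings, pitch range, walk ratio (step length / cadence), and
   mean swing-phase foot speed. Cycles with stride times outside the
   subject's mean ± 2 SD or pitch outside [−80°, +50°] are dropped; the
   first 50 surviving cycles give per-subject means and coefficients of
   variation (CV = SD/|mean| × 100).
4. **Association statistics.** Each statistic is correlated with grip
   strength (N/kg): Pearson if both variables pass Shapiro-Wilk normality,
   Spearman otherwise; effect size is Cohen's r = |r| (negligible < 0.1 ≤
   small < 0.3 ≤ medium < 0.5 ≤ large). The a priori sample size for a
   two-sided correlation test is computed from the Fisher-z power equation.

A synthetic-gait generator (`footgait.synth`) produces recordings with
exact ground-truth events, trajectories and parameters, plus cohorts whose
gait co-varies with grip strength at chosen rank correlations through a
Gaussian copula — so the whole pipeline is testable without field data.

## Worked example

```python
import numpy as np
import footgait as fg

spec = fg.GaitSpec(n_cycles=52, stride_length_m=1.0, cycle_jitter_cv=0.0, seed=41)
truth = fg.simulate_foot_motion(spec)
rec = fg.trajectory_to_imu(truth, fg.NoiseSpec(seed=17))  # noise + 0.5 deg/s gyro bias

cycles, extras = fg.analyze_recording(rec, height_m=1.57)
print(len(cycles), np.median(cycles["stride_length_m"]))
```

prints `52 0.997...`: all 52 strides of true length 1.000 m are found and
reconstructed with ~0.3% median error despite sensor noise and gyro bias,
because the ZUPT/de-drift corrections close every stride exactly (endpoint
speed 0, endpoint height drift 0).

Running `python examples/cohort_correlation.py` simulates a 55-subject
cohort (the size the power analysis suggests), pushes every recording
through the pipeline and prints the mean-parameter correlation table, e.g.

```
      variable     mean       sd        r  p_value   method interpretation
    gait_speed    0.808    0.180    0.487    0.000 spearman         medium
    stance_pct   71.298    2.942   -0.572    0.000 spearman          large
```

— stronger grip goes with faster gait and a smaller stance fraction; the
recovered coefficients sit on the generator's programmed targets (0.49 and
−0.57 here). The other examples cover event detection
(`simulate_and_detect.py`, sample-exact on noise-free data), stride
reconstruction (`stride_reconstruction.py`) and single-subject screening
and summaries (`subject_summary.py`).

A thin CLI mirrors the library:
`footgait simulate | events | extract | summarize | correlate | power | run`
(see `footgait --help`).

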