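"""Reconstruct stride trajectories by ZUPT dead reckoning.

Runs the full single-recording pipeline on a noisy synthetic walk (sensor
noise plus a 0.5 deg/s gyro bias) and reports how well the 1.0 m strides
are recovered after zero-velocity updates and height de-drifting.
"""

import numpy as np

import footgait as fg

spec = fg.GaitSpec(n_cycles=52, stride_length_m=1.0, cycle_jitter_cv=0.0, seed=41)
truth = fg.simulate_foot_motion(spec)
rec = fg.trajectory_to_imu(truth, fg.NoiseSpec(seed=17))  # noise + gyro bias

cycles, extras = fg.analyze_recording(rec, height_m=1.57)
lengths = cycles["stride_length_m"].to_numpy()
err = np.abs(lengths - 1.0)

print(f"{len(cycles)} strides reconstructed (true length 1.000 m)")
print(f"median recovered length: {np.median(lengths):.3f} m")
print(f"median absolute error:   {100 * np.median(err):.2f} %")

s = next(s for s in extras["strides"] if s is not None)
print("one stride after corrections:")
print(f"  endpoint speed:        {np.linalg.norm(s.vel[-1]):.1e} m/s (ZUPT -> exactly 0)")
print(f"  endpoint height drift: {abs(s.pos[-1, 2] - s.pos[0, 2]):.1e} m")
print(f"  lateral endpoint drift:{abs(s.pos[-1, 0]):.1e} m (Y-aligned heading)")
# The corrections close every stride exactly; the residual length error
# comes only from orientation error accumulated between foot flats.
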