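import pytest

import footgait as fg


@pytest.fixture(scope="session")
def clean_spec() -> fg.GaitSpec:
    """Jitter-free gait: every cycle identical, events on exact grid points."""
    return fg.GaitSpec(n_cycles=20, cycle_jitter_cv=0.0, seed=1)


@pytest.fixture(scope="session")
def clean_truth(clean_spec) -> fg.GroundTruth:
    return fg.simulate_foot_motion(clean_spec)


@pytest.fixture(scope="session")
def clean_recording(clean_truth) -> fg.ImuRecording:
    return fg.trajectory_to_imu(clean_truth, fg.NoiseSpec.none())


@pytest.fixture(scope="session")
def clean_analysis(clean_recording):
    """(cycles, extras) of the noise-free recording, height 1.6 m."""
    return fg.analyze_recording(clean_recording, height_m=1.6)


@pytest.fixture(scope="session")
def clean_true_cycles(clean_truth):
    return clean_truth.cycle_parameters(height_m=1.6)


@pytest.fixture(scope="session")
def jittered_noisy_analysis():
    """A realistic recording: 5% cycle jitter plus sensor noise and gyro bias."""
    spec = fg.GaitSpec(n_cycles=56, cycle_jitter_cv=0.05, seed=7)
    truth = fg.simulate_foot_motion(spec)
    rec = fg.trajectory_to_imu(truth, fg.NoiseSpec(seed=7))
    cycles, extras = fg.analyze_recording(rec, height_m=1.57)
    return spec, truth, cycles, extras
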