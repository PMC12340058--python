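import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import footgait as fg
from footgait.errors import DataError
from footgait.parameters import PARAMETER_NAMES, ScreeningConfig, screen_outliers


class TestCycleParameterIdentities:
    """The defining identities must hold for every emitted record."""

    def test_partition_and_ratios(self, clean_analysis):
        cycles, _ = clean_analysis
        fs = 100.0
        assert len(cycles) > 0
        np.testing.assert_allclose(
            cycles["stance_time"] + cycles["swing_time"], cycles["stride_time_hc"],
            atol=2.0 / fs,
        )
        np.testing.assert_allclose(
            cycles["stance_pct"], 100 * cycles["stance_time"] / cycles["stride_time_hc"],
            atol=1e-9,
        )
        np.testing.assert_allclose(cycles["cadence"], 120.0 / cycles["stride_time_hc"], atol=1e-9)
        np.testing.assert_allclose(
            cycles["walk_ratio"], (cycles["stride_length_m"] * 500) / cycles["cadence"],
            atol=1e-9,
        )
        np.testing.assert_allclose(
            cycles["gait_speed"], cycles["stride_length_m"] / cycles["stride_time_to"],
            atol=1e-9,
        )

    def test_pitch_orderings(self, jittered_noisy_analysis):
        *_, cycles, _ = jittered_noisy_analysis
        assert (cycles["pitch_min"] <= cycles["pitch_at_to"] + 1e-9).all()
        assert (cycles["pitch_min"] <= cycles["pitch_at_hc"] + 1e-9).all()
        assert (cycles["pitch_at_hc"] <= cycles["pitch_max"] + 1e-9).all()
        np.testing.assert_allclose(
            cycles["pitch_range"], cycles["pitch_max"] - cycles["pitch_min"], atol=1e-9
        )

    def test_recovers_ground_truth(self, clean_analysis, clean_true_cycles):
        cycles, _ = clean_analysis
        tc = clean_true_cycles.iloc[: len(cycles)]
        np.testing.assert_allclose(cycles["stride_time_hc"], tc["stride_time_hc"], atol=0.011)
        np.testing.assert_allclose(cycles["stance_pct"], tc["stance_pct"], atol=1.0)
        np.testing.assert_allclose(cycles["pitch_min"], tc["pitch_min"], atol=1.0)
        np.testing.assert_allclose(cycles["pitch_max"], tc["pitch_max"], atol=1.0)
        np.testing.assert_allclose(
            cycles["stride_length_norm"], tc["stride_length_norm"], rtol=0.03
        )


def _cycles_frame(stride_times, pitch_max=None, pitch_min=None):
    n = len(stride_times)
    df = pd.DataFrame({name: np.ones(n) for name in PARAMETER_NAMES})
    df["stride_time_hc"] = np.asarray(stride_times, dtype=float)
    df["pitch_max"] = 20.0 if pitch_max is None else np.asarray(pitch_max, dtype=float)
    df["pitch_min"] = -45.0 if pitch_min is None else np.asarray(pitch_min, dtype=float)
    df["stride_length_m"] = 1.0
    df["stride_time_to"] = df["stride_time_hc"]
    df["cycle_index"] = np.arange(n)
    return df


class TestScreening:
    def test_single_gross_outlier_dropped(self):
        # mean/SD of {1.0 x 49, 3.0} put only the 3.0 s cycle outside +/- 2 SD
        times = np.array([1.0] * 49 + [3.0])
        mean, sd = times.mean(), times.std(ddof=1)
        assert np.sum(np.abs(times - mean) > 2 * sd) == 1   # oracle: direct count
        retained, report = screen_outliers(
            _cycles_frame(times), ScreeningConfig(n_cycles_required=49)
        )
        assert report["stride_time_outliers"] == 1
        assert 3.0 not in retained["stride_time_hc"].values

    def test_pitch_bounds_dropped_regardless_of_stride_time(self):
        pm = np.full(60, 20.0)
        pm[[10, 40]] = 55.0
        pmin = np.full(60, -45.0)
        pmin[25] = -85.0
        retained, report = screen_outliers(
            _cycles_frame(np.ones(60), pitch_max=pm, pitch_min=pmin),
            ScreeningConfig(allow_short=True),
        )
        assert report["pitch_bound_outliers"] == 3
        assert report["n_survivors"] == 57
        assert len(retained) == 50  # first-50 rule still applies

    def test_first_fifty_of_clean_sixty(self):
        df = _cycles_frame(1.0 + 0.001 * np.arange(60))
        retained, report = screen_outliers(df)
        assert len(retained) == 50
        np.testing.assert_array_equal(retained["cycle_index"], np.arange(50))
        assert report["stride_time_outliers"] == 0 and report["pitch_bound_outliers"] == 0

    def test_too_few_survivors_errors_unless_allowed(self):
        df = _cycles_frame(np.ones(10))
        with pytest.raises(DataError, match="survive"):
            screen_outliers(df)
        with pytest.warns(UserWarning):
            retained, _ = screen_outliers(df, ScreeningConfig(allow_short=True))
        assert len(retained) == 10

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        times=st.lists(st.floats(0.5, 3.0), min_size=5, max_size=40),
        k1=st.floats(0.5, 2.0),
        k2=st.floats(2.0, 4.0),
    )
    def test_band_monotonicity(self, times, k1, k2):
        """Widening the stride-time band never removes survivors."""
        df = _cycles_frame(times)
        r1, _ = screen_outliers(df, ScreeningConfig(stride_sd_k=k1, allow_short=True))
        r2, _ = screen_outliers(df, ScreeningConfig(stride_sd_k=k2, allow_short=True))
        assert len(r2) >= len(r1)


class TestSummaries:
    def test_mean_and_cv(self):
        df = _cycles_frame([9.0, 10.0, 11.0])
        s = fg.summarize_subject(df, grip_strength=0.3, subject_id="a")
        assert s.means["stride_time_hc"] == pytest.approx(10.0)
        assert s.cvs["stride_time_hc"] == pytest.approx(10.0)  # sample SD = 1

    def test_negative_mean_gives_positive_cv(self):
        df = _cycles_frame(np.ones(3))
        df["pitch_at_to"] = [-9.0, -10.0, -11.0]
        s = fg.summarize_subject(df, 0.3)
        assert s.means["pitch_at_to"] == pytest.approx(-10.0)
        assert s.cvs["pitch_at_to"] == pytest.approx(10.0)

    def test_constant_parameter_has_zero_cv(self):
        df = _cycles_frame(np.ones(5))
        s = fg.summarize_subject(df, 0.3)
        assert s.cvs["gait_speed"] == pytest.approx(0.0)

    def test_zero_mean_cv_flagged_nan(self):
        df = _cycles_frame(np.ones(4))
        df["pitch_at_hc"] = [-1.0, 1.0, -1.0, 1.0]
        s = fg.summarize_subject(df, 0.3)
        assert np.isnan(s.cvs["pitch_at_hc"])

    def test_jitter_cv_recovered(self):
        # generator jitter CV 5% should appear as ~5% stride-time CV
        spec = fg.GaitSpec(n_cycles=50, cycle_jitter_cv=0.05, seed=11)
        tc = fg.simulate_foot_motion(spec).cycle_parameters()
        cv = 100 * tc["stride_time_hc"].std(ddof=1) / tc["stride_time_hc"].mean()
        assert cv == pytest.approx(5.0, abs=1.5)
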