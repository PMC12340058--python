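"""Synthetic foot-IMU gait generator with exact ground truth.

The generator builds a sagittal-plane foot trajectory: a quiet-standing
prefix, then a sequence of strides in which the foot is strictly stationary
during every stance phase and advances by a minimum-jerk displacement with a
smooth vertical clearance bump during every swing.  The foot pitch angle is a
monotone cubic (PCHIP) profile through the gait-event knots:

* 0 deg at every foot flat (FF),
* the plantarflexion trough ``pitch_min_deg`` exactly at toe-off (TO),
* the dorsiflexion peak ``pitch_hc_deg`` exactly at heel contact (HC).

Because the pitch extrema sit exactly on the events, the mediolateral
angular velocity (the pitch rate) crosses zero at TO (negative to positive)
and at HC (positive to negative) — the signal structure the zero-crossing
event detector assumes — and exceeds +70 deg/s in mid swing for any
physiological parameter choice.  All event times are snapped to the sample
grid so detection can be exact to the sample.

Ground truth (event times, per-cycle parameter values, true trajectory and
pitch) is carried alongside, which makes every downstream stage testable
against known answers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.spatial.transform import Rotation

from .errors import ConfigError
from .io import GRAVITY, CohortTable, ImuRecording, SubjectRecord

__all__ = [
    "GaitSpec",
    "NoiseSpec",
    "FootMotion",
    "GroundTruth",
    "simulate_foot_motion",
    "trajectory_to_imu",
    "simulate_cohort",
    "true_subject_parameters",
    "DEFAULT_COHORT_EFFECTS",
]


@dataclass(frozen=True)
class GaitSpec:
    """Parameters of one subject's synthetic gait.

    Defaults follow the spatiotemporal profile of community-dwelling older
    women (stride time ~1.23 s, ~71% stance, plantarflexion trough near
    -49 deg, dorsiflexion peak near +18.5 deg).
    """

    n_cycles: int = 60
    stride_time_s: float = 1.23
    stance_fraction: float = 0.713
    stride_length_m: float = 1.0
    pitch_hc_deg: float = 18.5
    pitch_min_deg: float = -48.8
    step_height_m: float = 0.12
    fs: float = 100.0
    standing_s: float = 30.0
    cycle_jitter_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.stance_fraction < 0.9):
            raise ConfigError(f"stance_fraction must be in (0.5, 0.9), got {self.stance_fraction}")
        if self.stride_time_s <= 0 or self.stride_length_m <= 0:
            raise ConfigError("stride_time_s and stride_length_m must be positive")
        if not (self.pitch_min_deg < 0 < self.pitch_hc_deg):
            raise ConfigError("need pitch_min_deg < 0 < pitch_hc_deg")
        if self.step_height_m < 0:
            raise ConfigError("step_height_m must be >= 0")
        if not (0 <= self.cycle_jitter_cv < 1):
            raise ConfigError("cycle_jitter_cv must be in [0, 1)")
        if self.standing_s < 30.0:
            raise ConfigError("standing prefix must span at least 30 s")


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor imperfection model: white noise plus a constant gyro bias."""

    acc_noise_sd: float = 0.05
    gyr_noise_sd: float = 0.5
    gyr_bias: tuple[float, float, float] = (0.5, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.acc_noise_sd < 0 or self.gyr_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")

    @classmethod
    def none(cls, seed: int = 0) -> "NoiseSpec":
        return cls(acc_noise_sd=0.0, gyr_noise_sd=0.0, gyr_bias=(0.0, 0.0, 0.0), seed=seed)


@dataclass
class FootMotion:
    """True world-frame foot motion sampled at ``fs``: the oracle trajectory."""

    t: np.ndarray
    pos: np.ndarray          # (n, 3) GCS metres, Z up
    vel: np.ndarray          # (n, 3) m/s
    lin_acc: np.ndarray      # (n, 3) m/s^2, gravity-free
    pitch_deg: np.ndarray    # sagittal pitch, dorsiflexion positive
    pitch_rate_dps: np.ndarray
    fs: float
    spec: GaitSpec


@dataclass
class GroundTruth:
    """Exact gait events and stride geometry of a synthetic recording.

    Events satisfy HC < FF < TO within each stance.  ``ff_times`` has one
    more entry than ``hc_times``/``to_times`` (the standing prefix ends in a
    foot-flat state and the recording ends in one).
    """

    hc_times: np.ndarray
    to_times: np.ndarray
    ff_times: np.ndarray
    stride_lengths_m: np.ndarray   # advance of swing j, j = 0..n_swings-1
    motion: FootMotion

    @property
    def n_cycles(self) -> int:
        return len(self.hc_times) - 2

    def cycle_parameters(self, height_m: float = 1.57) -> pd.DataFrame:
        """Per-cycle true gait parameters, computed from the true traces.

        Cycle ``k`` spans heel contacts ``k`` to ``k+1``; its stride length
        is taken between the foot flats bracketing the swing inside that
        window, and its TO-referenced stride time between the toe-offs of
        this cycle and the next — the same pairing the measurement pipeline
        uses, so rows align one-to-one with pipeline output.
        """
        m = self.motion
        fs = m.fs
        rows = []
        for k in range(self.n_cycles):
            hc0, hc1 = self.hc_times[k], self.hc_times[k + 1]
            to_in, to_next = self.to_times[k + 1], self.to_times[k + 2]
            stride_hc = hc1 - hc0
            stance = to_in - hc0
            swing = hc1 - to_in
            cadence = 120.0 / stride_hc
            length = float(self.stride_lengths_m[k + 1])
            i0, i1 = int(round(hc0 * fs)), int(round(hc1 * fs))
            iff = int(round(self.ff_times[k + 1] * fs))
            window = m.pitch_deg[i0:i1] - m.pitch_deg[iff]
            imin, imax = int(np.argmin(window)), int(np.argmax(window))
            ito = int(round(to_in * fs))
            isw0, isw1 = ito, i1
            speed = float(np.mean(np.linalg.norm(m.vel[isw0:isw1], axis=1)))
            rows.append(
                {
                    "gait_speed": length / (to_next - to_in),
                    "stride_length_norm": length / height_m,
                    "cadence": cadence,
                    "stride_time_hc": stride_hc,
                    "stance_time": stance,
                    "swing_time": swing,
                    "stance_pct": 100.0 * stance / stride_hc,
                    "pitch_at_to": float(m.pitch_deg[ito] - m.pitch_deg[iff]),
                    "pitch_at_hc": float(m.pitch_deg[i0] - m.pitch_deg[iff]),
                    "pitch_min": float(window[imin]),
                    "pitch_max": float(window[imax]),
                    "pitch_range": float(window[imax] - window[imin]),
                    "pitch_min_time": imin / fs,
                    "pitch_max_time": imax / fs,
                    "pitch_min_timing": 100.0 * (imin / fs) / stride_hc,
                    "pitch_max_timing": 100.0 * (imax / fs) / stride_hc,
                    "walk_ratio": (length * 1000.0 / 2.0) / cadence,
                    "swing_foot_speed": speed,
                    "stride_length_m": length,
                    "stride_time_to": to_next - to_in,
                }
            )
        return pd.DataFrame(rows)


def _lognormal_jitter(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative jitter with unit mean and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_foot_motion(spec: GaitSpec, tail_s: float = 2.0) -> GroundTruth:
    """Generate the true foot motion for one recording.

    Returns a :class:`GroundTruth` whose ``motion`` attribute holds the full
    sampled trajectory.  ``spec.n_cycles`` complete heel-contact-to-heel-
    contact cycles are available after the lead-in and before the tail.
    """
    fs = spec.fs
    rng = np.random.default_rng(spec.seed)
    m = spec.n_cycles + 2  # number of swings; gives n_cycles complete cycles
    stride_times = spec.stride_time_s * _lognormal_jitter(rng, spec.cycle_jitter_cv, m + 1)
    lengths = spec.stride_length_m * _lognormal_jitter(rng, spec.cycle_jitter_cv, m)

    # half-stance and swing durations in whole samples, so every event sits
    # exactly on the sample grid and FF is the exact midpoint of HC and TO
    half_stance = np.maximum(np.round(0.5 * spec.stance_fraction * stride_times * fs), 1).astype(int)
    swing_n = np.maximum(
        np.round((1.0 - spec.stance_fraction) * stride_times * fs), 2
    ).astype(int)

    ff_idx = np.empty(m + 1, dtype=int)
    to_idx = np.empty(m, dtype=int)
    hc_idx = np.empty(m, dtype=int)
    ff_idx[0] = int(round(spec.standing_s * fs))
    to_idx[0] = ff_idx[0] + half_stance[0]
    for j in range(m):
        hc_idx[j] = to_idx[j] + swing_n[j]
        ff_idx[j + 1] = hc_idx[j] + half_stance[j + 1]
        if j + 1 < m:
            to_idx[j + 1] = hc_idx[j] + 2 * half_stance[j + 1]

    n = ff_idx[m] + int(round(tail_s * fs)) + 1
    t = np.arange(n) / fs

    # pitch profile: PCHIP through (FF, 0), (TO, pitch_min), (HC, pitch_hc).
    # Auxiliary knots at +/- delta around each extremum keep the profile
    # locally symmetric there, so zero-phase filtering does not displace the
    # pitch-rate zero crossings that define the events.
    rng_pitch = spec.pitch_hc_deg - spec.pitch_min_deg
    knots_t = [0.0, ff_idx[0] / fs]
    knots_v = [0.0, 0.0]
    for j in range(m):
        d = int(min(swing_n[j] // 4, half_stance[j] // 2, half_stance[j + 1] // 2,
                    round(0.08 * fs)))
        dv = 0.05 * rng_pitch
        if d >= 2:
            knots_t += [(to_idx[j] - d) / fs, to_idx[j] / fs, (to_idx[j] + d) / fs]
            knots_v += [spec.pitch_min_deg + dv, spec.pitch_min_deg, spec.pitch_min_deg + dv]
            knots_t += [(hc_idx[j] - d) / fs, hc_idx[j] / fs, (hc_idx[j] + d) / fs]
            knots_v += [spec.pitch_hc_deg - dv, spec.pitch_hc_deg, spec.pitch_hc_deg - dv]
        else:
            knots_t += [to_idx[j] / fs, hc_idx[j] / fs]
            knots_v += [spec.pitch_min_deg, spec.pitch_hc_deg]
        knots_t.append(ff_idx[j + 1] / fs)
        knots_v.append(0.0)
    knots_t.append(t[-1])
    knots_v.append(0.0)
    pitch_spline = PchipInterpolator(np.asarray(knots_t), np.asarray(knots_v))
    pitch = pitch_spline(t)
    pitch_rate = pitch_spline.derivative()(t)

    swing_peaks = [float(np.max(pitch_rate[to_idx[j]:hc_idx[j] + 1])) for j in range(m)]
    if min(swing_peaks) < 70.0:
        warnings.warn(
            "mid-swing pitch rate stays below 70 deg/s; zero-crossing event "
            "detection may miss cycles with these gait parameters",
            stacklevel=2,
        )

    # positions: stationary everywhere except during swings
    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    acc = np.zeros((n, 3))
    cum_len = np.concatenate([[0.0], np.cumsum(lengths)])
    y_base = np.zeros(n)
    for j in range(m):
        y_base[hc_idx[j]:] = cum_len[j + 1]
        sl = slice(to_idx[j], hc_idx[j])
        s = (np.arange(to_idx[j], hc_idx[j]) - to_idx[j]) / swing_n[j]
        w_s = swing_n[j] / fs
        L = lengths[j]
        h = spec.step_height_m
        p = s**3 * (10.0 - 15.0 * s + 6.0 * s**2)            # minimum jerk
        dp = 30.0 * s**2 * (1.0 - 2.0 * s + s**2)
        ddp = 60.0 * s * (1.0 - 3.0 * s + 2.0 * s**2)
        b = 0.5 * (1.0 - np.cos(2.0 * np.pi * s))            # Hann clearance
        db = np.pi * np.sin(2.0 * np.pi * s)
        ddb = 2.0 * np.pi**2 * np.cos(2.0 * np.pi * s)
        pos[sl, 1] = cum_len[j] + L * p
        pos[sl, 2] = h * b
        vel[sl, 1] = L / w_s * dp
        vel[sl, 2] = h / w_s * db
        acc[sl, 1] = L / w_s**2 * ddp
        acc[sl, 2] = h / w_s**2 * ddb
    stance_mask = vel[:, 1] == 0.0
    pos[stance_mask, 1] = y_base[stance_mask]

    motion = FootMotion(
        t=t, pos=pos, vel=vel, lin_acc=acc,
        pitch_deg=pitch, pitch_rate_dps=pitch_rate, fs=fs, spec=spec,
    )
    return GroundTruth(
        hc_times=hc_idx / fs,
        to_times=to_idx / fs,
        ff_times=ff_idx / fs,
        stride_lengths_m=lengths,
        motion=motion,
    )


def trajectory_to_imu(truth: GroundTruth | FootMotion, noise: NoiseSpec = NoiseSpec.none(),
                      subject_id: str = "synthetic", foot_side: str = "right") -> ImuRecording:
    """Project the true motion into sensor readings.

    The accelerometer reports specific force (linear acceleration minus
    gravity) in the sensor frame; the gyroscope reports body angular
    velocity in deg/s plus a constant bias and white noise.
    """
    motion = truth.motion if isinstance(truth, GroundTruth) else truth
    rng = np.random.default_rng(noise.seed)
    rot = Rotation.from_euler("x", motion.pitch_deg[:, None], degrees=True)
    g_vec = np.array([0.0, 0.0, -GRAVITY])
    specific_force = rot.apply(motion.lin_acc - g_vec, inverse=True)
    gyr = np.zeros_like(specific_force)
    gyr[:, 0] = motion.pitch_rate_dps
    acc = specific_force
    if noise.acc_noise_sd > 0:
        acc = acc + rng.normal(0.0, noise.acc_noise_sd, acc.shape)
    gyr = gyr + np.asarray(noise.gyr_bias, dtype=float)
    if noise.gyr_noise_sd > 0:
        gyr = gyr + rng.normal(0.0, noise.gyr_noise_sd, gyr.shape)
    return ImuRecording(
        subject_id=subject_id,
        t=motion.t.copy(),
        acc=acc,
        gyr=gyr,
        fs=motion.fs,
        standing_interval=(0.0, motion.spec.standing_s),
        foot_side=foot_side,
    )


# ---------------------------------------------------------------------------
# cohorts with controlled grip-strength associations

#: default (rank correlation with grip strength, between-subject SD) per
#: GaitSpec field, emulating the direction and rough size of the
#: strength-gait associations seen in older women: stronger grip goes with
#: longer/faster strides, shorter stance, larger dorsiflexion at landing,
#: and less cycle-to-cycle variability.
DEFAULT_COHORT_EFFECTS: dict[str, tuple[float, float]] = {
    "stride_length_m": (0.41, 0.20),
    "stride_time_s": (-0.45, 0.15),
    "stance_fraction": (-0.57, 0.031),
    "pitch_hc_deg": (0.32, 6.0),
    "pitch_min_deg": (-0.28, 8.0),
    "cycle_jitter_cv": (-0.30, 0.02),
}

_SPEC_BOUNDS = {
    "stride_length_m": (0.35, 1.8),
    "stride_time_s": (0.7, 2.4),
    "stance_fraction": (0.55, 0.85),
    "pitch_hc_deg": (4.0, 45.0),
    "pitch_min_deg": (-75.0, -15.0),
    "cycle_jitter_cv": (0.005, 0.25),
    "step_height_m": (0.03, 0.30),
}

#: cohort grip-strength marginal, N/kg (lognormal mean and SD)
GRIP_MEAN, GRIP_SD = 0.28, 0.10


def simulate_cohort(
    n_subjects: int,
    target_rho: dict[str, float] | None = None,
    spread: dict[str, float] | None = None,
    seed: int = 0,
    base_spec: GaitSpec | None = None,
) -> tuple[CohortTable, list[GaitSpec]]:
    """Draw a cohort whose gait parameters co-vary with grip strength.

    A Gaussian copula ties a latent strength factor to each targeted
    GaitSpec field: the latent correlation is ``2 sin(pi * rho / 6)`` so the
    population Spearman correlation between grip strength and the field
    equals ``target_rho`` exactly (before boundary clipping, which is kept
    in the far tails).  Fields not named keep the base-spec value.
    """
    if target_rho is None:
        target_rho = {k: v[0] for k, v in DEFAULT_COHORT_EFFECTS.items()}
    if spread is None:
        spread = {k: DEFAULT_COHORT_EFFECTS.get(k, (0.0, 0.0))[1] for k in target_rho}
    base = base_spec or GaitSpec()
    for name, rho in target_rho.items():
        if name not in _SPEC_BOUNDS:
            raise ConfigError(f"unknown gait parameter {name!r}")
        if not abs(rho) < 1:
            raise ConfigError(f"target_rho[{name!r}] must satisfy |rho| < 1")
        if spread.get(name, 0.0) < 0:
            raise ConfigError(f"spread[{name!r}] must be >= 0")

    rng = np.random.default_rng(seed)
    g_latent = rng.normal(size=n_subjects)
    sigma2 = np.log1p((GRIP_SD / GRIP_MEAN) ** 2)
    grip = np.exp(np.log(GRIP_MEAN) - 0.5 * sigma2 + np.sqrt(sigma2) * g_latent)

    fields = {}
    for name, rho in target_rho.items():
        r_lat = 2.0 * np.sin(np.pi * rho / 6.0)
        z = r_lat * g_latent + np.sqrt(1.0 - r_lat**2) * rng.normal(size=n_subjects)
        lo, hi = _SPEC_BOUNDS[name]
        fields[name] = np.clip(getattr(base, name) + spread[name] * z, lo, hi)

    height = np.clip(rng.normal(1.57, 0.10, n_subjects), 1.35, 1.85)
    bmi = np.clip(rng.normal(24.7, 3.0, n_subjects), 17.0, 29.5)
    mass = bmi * height**2
    age = rng.integers(70, 96, n_subjects)

    records, specs = [], []
    for i in range(n_subjects):
        records.append(
            SubjectRecord(
                subject_id=f"S{i:04d}",
                sex="F",
                age_years=int(age[i]),
                height_m=float(height[i]),
                body_mass_kg=float(mass[i]),
                gds=1,
                grip_strength=float(grip[i]),
            )
        )
        overrides = {name: float(vals[i]) for name, vals in fields.items()}
        specs.append(replace(base, seed=int(rng.integers(0, 2**31 - 1)), **overrides))
    return CohortTable(records), specs


def _mean_swing_speed(spec: GaitSpec, n_quad: int = 200) -> float:
    """Mean 3-D foot speed over the swing implied by the spec's profiles."""
    w = (1.0 - spec.stance_fraction) * spec.stride_time_s
    s = (np.arange(n_quad) + 0.5) / n_quad
    vy = spec.stride_length_m / w * 30.0 * s**2 * (1.0 - s) ** 2
    vz = spec.step_height_m / w * np.pi * np.sin(2.0 * np.pi * s)
    return float(np.mean(np.hypot(vy, vz)))


def true_subject_parameters(specs: list[GaitSpec], heights_m) -> pd.DataFrame:
    """Nominal (jitter-free) per-subject gait-parameter values implied by specs.

    These are the population-level quantities the per-subject means estimate;
    they let cohort-scale statistics be exercised without simulating signals.
    """
    heights = np.asarray(heights_m, dtype=float)
    rows = []
    for spec, h in zip(specs, heights):
        T, L, sf = spec.stride_time_s, spec.stride_length_m, spec.stance_fraction
        cadence = 120.0 / T
        rows.append(
            {
                "gait_speed": L / T,
                "stride_length_norm": L / h,
                "cadence": cadence,
                "stride_time_hc": T,
                "stance_time": sf * T,
                "swing_time": (1 - sf) * T,
                "stance_pct": 100.0 * sf,
                "pitch_at_to": spec.pitch_min_deg,
                "pitch_at_hc": spec.pitch_hc_deg,
                "pitch_min": spec.pitch_min_deg,
                "pitch_max": spec.pitch_hc_deg,
                "pitch_range": spec.pitch_hc_deg - spec.pitch_min_deg,
                "pitch_min_time": sf * T,
                "pitch_max_time": 0.0,
                "pitch_min_timing": 100.0 * sf,
                "pitch_max_timing": 0.0,
                "walk_ratio": (L * 1000.0 / 2.0) / cadence,
                "swing_foot_speed": _mean_swing_speed(spec),
            }
        )
    return pd.DataFrame(rows)
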