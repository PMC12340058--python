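"""Orientation estimation and per-stride zero-velocity-updated dead reckoning.

Orientation is tracked with a minimal error-state filter: the quaternion is
propagated by the gyroscope (midpoint rule) and nudged toward the
accelerometer's gravity direction whenever the measured specific-force
magnitude is close to 1 g (the accelerometer is only a reliable inclinometer
when the foot is not accelerating).  The global coordinate system (GCS) has
Z up, fixed by the mean accelerometer direction over the standing prefix.

Each stride — foot flat to next ipsilateral foot flat — is reconstructed by
double integration of the gravity-free acceleration with three corrections:

1. ZUPT: a linear-in-time velocity ramp is removed so both endpoint
   velocities are exactly zero;
2. height de-drift: a linear ramp on Z so both endpoints return to Z = 0
   (level-ground assumption);
3. heading: a rotation about GCS Z aligns the endpoint-to-endpoint
   displacement with +Y, giving every stride a common forward axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import cos, sin, sqrt

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .errors import DataError, ValidationError
from .io import GRAVITY, ImuRecording

__all__ = [
    "OrientationConfig",
    "GravityModel",
    "StrideTrajectory",
    "estimate_gravity",
    "estimate_orientation",
    "integrate_stride",
    "foot_pitch",
]


@dataclass(frozen=True)
class OrientationConfig:
    """Gains of the gyro/accelerometer fusion.

    ``accel_trust_gain`` is the per-sample fraction of the tilt error
    corrected from the accelerometer; it is applied only when the measured
    acceleration norm is within ``acc_gate`` (fractional) of 1 g.
    """

    accel_trust_gain: float = 0.02
    acc_gate: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.accel_trust_gain < 1):
            raise ValueError("accel_trust_gain must be in [0, 1)")


@dataclass
class GravityModel:
    g_vec: np.ndarray      # gravity acceleration in GCS, points along -Z
    magnitude: float


@dataclass
class StrideTrajectory:
    """GCS kinematics of one foot-flat-to-foot-flat segment."""

    segment: tuple[int, int]   # inclusive sample range [i0, i1]
    t: np.ndarray
    pos: np.ndarray            # (n, 3) m; starts at origin, ends on +Y
    vel: np.ndarray            # (n, 3) m/s; exactly zero at both endpoints
    pitch: np.ndarray          # deg, re-zeroed to the segment start (foot flat)

    @property
    def stride_length_m(self) -> float:
        return float(np.linalg.norm(self.pos[-1] - self.pos[0]))


def _quiet_standing_slice(recording: ImuRecording, window_s: float = 15.0) -> slice:
    sl = recording.standing_slice()
    n = int(round(window_s * recording.fs))
    if sl.stop - sl.start < n:
        raise ValidationError(
            f"standing interval of {recording.subject_id} shorter than {window_s} s"
        )
    return slice(sl.start, sl.start + n)


def estimate_gravity(recording: ImuRecording, window_s: float = 15.0) -> GravityModel:
    """Gravity magnitude from the first 15 s of quiet standing.

    The GCS Z axis is *defined* by the standing accelerometer direction, so
    in the GCS gravity is exactly ``(0, 0, -magnitude)``.
    """
    sl = _quiet_standing_slice(recording, window_s)
    gyr_rms = float(np.sqrt(np.mean(recording.gyr[sl] ** 2)))
    if gyr_rms > 5.0:
        raise DataError(
            f"{recording.subject_id}: standing gyro RMS {gyr_rms:.1f} deg/s > 5 — not quiescent"
        )
    magnitude = float(np.linalg.norm(recording.acc[sl].mean(axis=0)))
    if not (9.5 <= magnitude <= 10.1):
        warnings.warn(
            f"estimated gravity magnitude {magnitude:.3f} m/s^2 outside [9.5, 10.1]",
            stacklevel=2,
        )
    return GravityModel(g_vec=np.array([0.0, 0.0, -magnitude]), magnitude=magnitude)


def _initial_quaternion(acc_mean: np.ndarray) -> tuple[float, float, float, float]:
    """Shortest rotation taking the sensor's gravity direction to GCS +Z."""
    a = acc_mean / np.linalg.norm(acc_mean)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(a, z)
    s = np.linalg.norm(axis)
    c = float(np.dot(a, z))
    if s < 1e-12:
        if c > 0:
            return (1.0, 0.0, 0.0, 0.0)
        return (0.0, 1.0, 0.0, 0.0)  # upside down: 180 deg about x
    angle = np.arctan2(s, c)
    axis = axis / s
    hw = cos(angle / 2.0)
    hs = sin(angle / 2.0)
    return (hw, hs * axis[0], hs * axis[1], hs * axis[2])


def estimate_orientation(
    recording: ImuRecording,
    cfg: OrientationConfig = OrientationConfig(),
    acc: np.ndarray | None = None,
    gyr: np.ndarray | None = None,
) -> Rotation:
    """Per-sample sensor-to-GCS rotation.

    ``acc``/``gyr`` may override the recording's channels (e.g. to fuse the
    low-pass-filtered signals); units stay m/s^2 and deg/s.
    """
    acc = recording.acc if acc is None else np.asarray(acc, dtype=float)
    gyr = recording.gyr if gyr is None else np.asarray(gyr, dtype=float)
    t = recording.t
    n = len(t)

    sl = _quiet_standing_slice(recording)
    q = _initial_quaternion(acc[sl].mean(axis=0))

    # precompute propagation increments (midpoint angular rate, body frame)
    w = np.radians(gyr)
    dt = np.diff(t)[:, None]
    rotvec = 0.5 * (w[:-1] + w[1:]) * dt
    half = 0.5 * np.linalg.norm(rotvec, axis=1)
    axis = np.divide(rotvec, 2 * half[:, None] + 1e-300)
    dq = np.empty((n - 1, 4))
    dq[:, 0] = np.cos(half)
    dq[:, 1:] = np.sin(half)[:, None] * axis

    # accelerometer gate and unit directions
    norm = np.linalg.norm(acc, axis=1)
    gate = np.abs(norm - GRAVITY) <= cfg.acc_gate * GRAVITY
    with np.errstate(invalid="ignore"):
        a_unit = acc / (norm[:, None] + 1e-300)

    gain = cfg.accel_trust_gain
    quats = np.empty((n, 4))
    qw, qx, qy, qz = q
    for k in range(n):
        if gain > 0 and gate[k]:
            # predicted gravity direction in the sensor frame: third row of R(q)
            bx = 2.0 * (qx * qz - qw * qy)
            by = 2.0 * (qy * qz + qw * qx)
            bz = 1.0 - 2.0 * (qx * qx + qy * qy)
            ax, ay, az = a_unit[k]
            cx = gain * (ay * bz - az * by)
            cy = gain * (az * bx - ax * bz)
            cz = gain * (ax * by - ay * bx)
            ang = sqrt(cx * cx + cy * cy + cz * cz)
            if ang > 1e-15:
                cw = cos(ang / 2.0)
                s = sin(ang / 2.0) / ang
                ex, ey, ez = cx * s, cy * s, cz * s
                qw, qx, qy, qz = (
                    qw * cw - qx * ex - qy * ey - qz * ez,
                    qw * ex + qx * cw + qy * ez - qz * ey,
                    qw * ey - qx * ez + qy * cw + qz * ex,
                    qw * ez + qx * ey - qy * ex + qz * cw,
                )
        quats[k] = (qw, qx, qy, qz)
        if k < n - 1:
            dw, dx, dy, dz = dq[k]
            qw, qx, qy, qz = (
                qw * dw - qx * dx - qy * dy - qz * dz,
                qw * dx + qx * dw + qy * dz - qz * dy,
                qw * dy - qx * dz + qy * dw + qz * dx,
                qw * dz + qx * dy - qy * dx + qz * dw,
            )
            nq = sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
            qw, qx, qy, qz = qw / nq, qx / nq, qy / nq, qz / nq
    return Rotation.from_quat(quats, scalar_first=True)


def foot_pitch(rotations: Rotation) -> np.ndarray:
    """Sagittal foot pitch in degrees, dorsiflexion positive.

    The pitch is the elevation of the foot's long (anterior, sensor-y) axis
    above the GCS ground plane: 0 when the foot is flat, positive when the
    toes point up.
    """
    e_y = np.atleast_2d(rotations.apply(np.array([0.0, 1.0, 0.0])))
    return np.degrees(np.arcsin(np.clip(e_y[:, 2], -1.0, 1.0)))


def integrate_stride(
    t: np.ndarray,
    acc: np.ndarray,
    rotations: Rotation,
    gravity: GravityModel,
    segment: tuple[int, int],
    pitch: np.ndarray | None = None,
) -> StrideTrajectory:
    """Dead-reckon one foot-flat-to-foot-flat segment (inclusive indices)."""
    i0, i1 = segment
    if i1 - i0 < 4:
        raise DataError(f"segment [{i0}, {i1}] shorter than 4 samples")
    ts = t[i0:i1 + 1]
    lin = rotations[i0:i1 + 1].apply(acc[i0:i1 + 1]) + gravity.g_vec

    vel = cumulative_trapezoid(lin, ts, initial=0.0, axis=0)
    tau = ((ts - ts[0]) / (ts[-1] - ts[0]))[:, None]
    vel = vel - tau * vel[-1]          # ZUPT: endpoints exactly zero

    pos = cumulative_trapezoid(vel, ts, initial=0.0, axis=0)
    pos[:, 2] -= tau[:, 0] * pos[-1, 2]  # level-ground Z de-drift

    d = pos[-1] - pos[0]
    if np.hypot(d[0], d[1]) > 1e-12:
        alpha = np.arctan2(d[0], d[1])
        ca, sa = np.cos(alpha), np.sin(alpha)
        rot2 = np.array([[ca, -sa], [sa, ca]])
        pos[:, :2] = pos[:, :2] @ rot2.T
        vel[:, :2] = vel[:, :2] @ rot2.T

    if pitch is None:
        pitch_seg = foot_pitch(rotations[i0:i1 + 1])
    else:
        pitch_seg = np.asarray(pitch[i0:i1 + 1], dtype=float)
    pitch_seg = pitch_seg - pitch_seg[0]   # foot flat defines 0 deg

    return StrideTrajectory(segment=(i0, i1), t=ts, pos=pos, vel=vel, pitch=pitch_seg)
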