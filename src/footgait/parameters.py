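"""Per-cycle gait parameters, outlier screening, and per-subject summaries.

Eighteen parameters are computed per gait cycle (heel contact to the next
ipsilateral heel contact).  Two distinct stride times are kept: heel-contact
referenced (used for cadence, stance percentage and the timing
normalisations) and toe-off referenced (used for gait speed), because the
two definitions differ cycle by cycle.  Pitch quantities are evaluated on
the cycle's own [HC_k, HC_{k+1}) window after re-zeroing the pitch at the
cycle's foot flat.

Screening drops cycles whose heel-contact stride time falls outside the
subject's mean +/- 2 SD band (computed once over all cycles) or whose pitch
extremes leave the plausibility box (max > +50 deg or min < -80 deg); the
first 50 surviving cycles, in temporal order, summarise the subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .events import GaitEventSet
from .trajectory import StrideTrajectory

__all__ = [
    "PARAMETER_NAMES",
    "ScreeningConfig",
    "SubjectSummary",
    "compute_cycle_parameters",
    "screen_outliers",
    "summarize_subject",
]

#: the 18 reported parameters, in output order
PARAMETER_NAMES = [
    "gait_speed",          # m/s, stride length / stride time (TO -> TO)
    "stride_length_norm",  # stride length / body height, m/HT
    "cadence",             # steps/min, 120 / stride time (HC -> HC)
    "stride_time_hc",      # s, HC -> next HC
    "stance_time",         # s, HC -> TO
    "swing_time",          # s, TO -> next HC
    "stance_pct",          # %, stance / stride (HC) * 100
    "pitch_at_to",         # deg
    "pitch_at_hc",         # deg
    "pitch_min",           # deg
    "pitch_max",           # deg
    "pitch_range",         # deg
    "pitch_min_time",      # s from HC
    "pitch_max_time",      # s from HC
    "pitch_min_timing",    # % of stride (HC)
    "pitch_max_timing",    # % of stride (HC)
    "walk_ratio",          # mm / (steps/min), step length / cadence
    "swing_foot_speed",    # m/s, mean 3-D foot speed over the swing
]


@dataclass(frozen=True)
class ScreeningConfig:
    stride_sd_k: float = 2.0
    pitch_max_limit: float = 50.0
    pitch_min_limit: float = -80.0
    n_cycles_required: int = 50
    allow_short: bool = False

    def __post_init__(self) -> None:
        if self.stride_sd_k <= 0:
            raise ValueError("stride_sd_k must be positive")
        if self.pitch_min_limit >= self.pitch_max_limit:
            raise ValueError("pitch limits must be ordered")


@dataclass
class SubjectSummary:
    """Per-subject mean and coefficient of variation of each parameter."""

    subject_id: str
    means: pd.Series
    cvs: pd.Series          # %, sample SD / |mean| * 100; NaN when mean == 0
    n_cycles_used: int
    grip_strength: float

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id}
        row.update({f"mean_{k}": v for k, v in self.means.items()})
        row.update({f"cv_{k}": v for k, v in self.cvs.items()})
        row["n_cycles_used"] = self.n_cycles_used
        row["grip_strength"] = self.grip_strength
        return row


def compute_cycle_parameters(
    strides: list[StrideTrajectory],
    events: GaitEventSet,
    pitch: np.ndarray,
    height_m: float,
) -> pd.DataFrame:
    """One parameter record per complete gait cycle.

    ``strides`` are the foot-flat segments in temporal order (stride ``k``
    spans ``ff_idx[k]`` to ``ff_idx[k+1]``); ``pitch`` is the full-recording
    pitch series in degrees (un-zeroed).
    """
    if height_m <= 0:
        raise DataError("height_m must be positive")
    fs = events.fs
    hc, to, ff = events.hc_idx, events.to_idx, events.ff_idx
    n_cycles = min(events.n_cycles, len(strides))
    rows = []
    for k in range(n_cycles):
        i0, i1 = int(hc[k]), int(hc[k + 1])
        ito, ito_next = int(to[k + 1]), int(to[k + 2])
        if not (i0 < ito < i1):
            continue  # no toe-off inside this cycle: drop
        stride_hc = (i1 - i0) / fs
        stance = (ito - i0) / fs
        swing = (i1 - ito) / fs
        cadence = 120.0 / stride_hc
        stride = strides[k]
        if stride is None:
            continue  # stride segment was dropped during reconstruction
        length = stride.stride_length_m

        window = pitch[i0:i1] - pitch[int(ff[k])]
        imin, imax = int(np.argmin(window)), int(np.argmax(window))
        seg0 = stride.segment[0]
        swing_speed = float(np.mean(np.linalg.norm(stride.vel[ito - seg0:i1 - seg0], axis=1)))

        rows.append(
            {
                "cycle_index": k,
                "gait_speed": length / ((ito_next - ito) / fs),
                "stride_length_norm": length / height_m,
                "cadence": cadence,
                "stride_time_hc": stride_hc,
                "stance_time": stance,
                "swing_time": swing,
                "stance_pct": 100.0 * stance / stride_hc,
                "pitch_at_to": float(window[ito - i0]),
                "pitch_at_hc": float(window[0]),
                "pitch_min": float(window[imin]),
                "pitch_max": float(window[imax]),
                "pitch_range": float(window[imax] - window[imin]),
                "pitch_min_time": imin / fs,
                "pitch_max_time": imax / fs,
                "pitch_min_timing": 100.0 * (imin / fs) / stride_hc,
                "pitch_max_timing": 100.0 * (imax / fs) / stride_hc,
                "walk_ratio": (length * 1000.0 / 2.0) / cadence,
                "swing_foot_speed": swing_speed,
                "stride_length_m": length,
                "stride_time_to": (ito_next - ito) / fs,
            }
        )
    return pd.DataFrame(rows)


def screen_outliers(
    cycles: pd.DataFrame, cfg: ScreeningConfig = ScreeningConfig()
) -> tuple[pd.DataFrame, dict]:
    """Apply the outlier rules and keep the first ``n_cycles_required`` survivors.

    The stride-time band (mean +/- k SD) is computed once over *all* cycles,
    outliers included; the pitch box is applied to the remainder.  Returns
    the retained cycles and a per-rule report.
    """
    if len(cycles) < 2:
        raise DataError("need at least 2 cycles to screen")
    st = cycles["stride_time_hc"]
    mean, sd = st.mean(), st.std(ddof=1)
    in_band = (st >= mean - cfg.stride_sd_k * sd) & (st <= mean + cfg.stride_sd_k * sd)
    n_stride_out = int((~in_band).sum())

    rest = cycles[in_band]
    pitch_ok = (rest["pitch_max"] <= cfg.pitch_max_limit) & (
        rest["pitch_min"] >= cfg.pitch_min_limit
    )
    n_pitch_out = int((~pitch_ok).sum())
    survivors = rest[pitch_ok]

    report = {
        "n_input": len(cycles),
        "stride_time_outliers": n_stride_out,
        "pitch_bound_outliers": n_pitch_out,
        "n_survivors": len(survivors),
    }
    if len(survivors) < cfg.n_cycles_required:
        msg = (
            f"only {len(survivors)} cycles survive screening; "
            f"{cfg.n_cycles_required} required"
        )
        if not cfg.allow_short:
            raise DataError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
        retained = survivors
    else:
        retained = survivors.iloc[: cfg.n_cycles_required]
    report["n_retained"] = len(retained)
    return retained.reset_index(drop=True), report


def summarize_subject(
    retained: pd.DataFrame, grip_strength: float, subject_id: str = ""
) -> SubjectSummary:
    """Arithmetic mean and CV (sample SD / |mean| * 100) of each parameter."""
    if len(retained) < 2:
        raise DataError("need at least 2 retained cycles to summarise")
    means = retained[PARAMETER_NAMES].mean()
    sds = retained[PARAMETER_NAMES].std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = 100.0 * sds / means.abs()
    cvs[means == 0] = np.nan  # CV undefined at zero mean
    return SubjectSummary(
        subject_id=subject_id,
        means=means,
        cvs=cvs,
        n_cycles_used=len(retained),
        grip_strength=grip_strength,
    )
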