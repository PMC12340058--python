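"""End-to-end orchestration: recording -> events -> strides -> parameters ->
subject summaries -> grip-strength correlation tables.

All stage constants live in :class:`PipelineConfig`; the defaults are the
protocol constants (10 Hz 4th-order zero-phase filter, 70 deg/s peak
threshold, mean +/- 2 SD stride-time screening, +50/-80 deg pitch box,
50 cycles per subject, 15 s gravity window, alpha = 0.05).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import DataError, FootgaitError
from .events import EventConfig, FilterConfig, detect_events, lowpass_zero_phase
from .io import CohortTable, ImuRecording, SubjectRecord, TxtDialect
from .parameters import (
    ScreeningConfig,
    SubjectSummary,
    compute_cycle_parameters,
    screen_outliers,
    summarize_subject,
)
from .stats import PowerSpec, build_results_table, results_to_frame
from .trajectory import (
    OrientationConfig,
    estimate_gravity,
    estimate_orientation,
    foot_pitch,
    integrate_stride,
)

__all__ = ["PipelineConfig", "analyze_recording", "process_subject", "run_cohort"]

logger = logging.getLogger("footgait")


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    events: EventConfig = field(default_factory=EventConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    orientation: OrientationConfig = field(default_factory=OrientationConfig)
    power: PowerSpec = field(default_factory=PowerSpec)
    dialect: TxtDialect = field(default_factory=TxtDialect)
    gravity_window_s: float = 15.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dialect"]["columns"] = list(d["dialect"]["columns"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for name, sub in [
            ("filter", FilterConfig),
            ("events", EventConfig),
            ("screening", ScreeningConfig),
            ("orientation", OrientationConfig),
            ("power", PowerSpec),
        ]:
            if name in d:
                kwargs[name] = sub(**d.pop(name))
        if "dialect" in d:
            dd = dict(d.pop("dialect"))
            if "columns" in dd:
                dd["columns"] = tuple(dd["columns"])
            kwargs["dialect"] = TxtDialect(**dd)
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def analyze_recording(
    recording: ImuRecording,
    height_m: float,
    config: PipelineConfig | None = None,
):
    """Run one recording through event detection and stride reconstruction.

    Returns ``(cycles, extras)``: the per-cycle parameter table and a dict
    with the intermediate products (filtered signals, events, gravity,
    orientation, pitch, stride trajectories).
    """
    config = config or PipelineConfig()
    fs = recording.fs
    acc_f = lowpass_zero_phase(recording.acc, fs, config.filter)
    gyr_f = lowpass_zero_phase(recording.gyr, fs, config.filter)

    events = detect_events(gyr_f[:, 0], fs, config.events)
    gravity = estimate_gravity(recording, config.gravity_window_s)
    rotations = estimate_orientation(recording, config.orientation, acc=acc_f, gyr=gyr_f)
    pitch = foot_pitch(rotations)

    strides = []
    for k in range(len(events.ff_idx) - 1):
        seg = (int(events.ff_idx[k]), int(events.ff_idx[k + 1]))
        try:
            strides.append(
                integrate_stride(recording.t, acc_f, rotations, gravity, seg, pitch)
            )
        except DataError as exc:
            logger.warning("%s: stride %d dropped: %s", recording.subject_id, k, exc)
            strides.append(None)

    cycles = compute_cycle_parameters(strides, events, pitch, height_m)
    extras = {
        "acc_filtered": acc_f,
        "gyr_filtered": gyr_f,
        "events": events,
        "gravity": gravity,
        "rotations": rotations,
        "pitch": pitch,
        "strides": strides,
    }
    return cycles, extras


def process_subject(
    recording: ImuRecording,
    subject: SubjectRecord,
    config: PipelineConfig | None = None,
) -> tuple[SubjectSummary, dict]:
    """Full single-subject path: recording to screened parameter summary."""
    config = config or PipelineConfig()
    cycles, _ = analyze_recording(recording, subject.height_m, config)
    retained, report = screen_outliers(cycles, config.screening)
    summary = summarize_subject(retained, subject.grip_strength, subject.subject_id)
    logger.info(
        "%s: %d cycles in, %d stride-time and %d pitch outliers, %d used",
        subject.subject_id,
        report["n_input"],
        report["stride_time_outliers"],
        report["pitch_bound_outliers"],
        report["n_retained"],
    )
    return summary, report


def run_cohort(
    recordings: dict[str, ImuRecording],
    cohort: CohortTable,
    config: PipelineConfig | None = None,
) -> dict:
    """Process every subject and correlate gait statistics with grip strength.

    Returns a dict with the per-subject summary table, the mean- and
    CV-statistic correlation tables, and a list of subjects that failed
    hard preconditions (with the reason).
    """
    config = config or PipelineConfig()
    rows, failures = [], []
    for subject in cohort:
        rec = recordings.get(subject.subject_id)
        if rec is None:
            failures.append((subject.subject_id, "no recording"))
            continue
        try:
            summary, _ = process_subject(rec, subject, config)
        except FootgaitError as exc:
            logger.warning("%s failed: %s", subject.subject_id, exc)
            failures.append((subject.subject_id, str(exc)))
            continue
        rows.append(summary.to_row())
    if not rows:
        raise DataError("no subject completed the pipeline")
    summaries = pd.DataFrame(rows)
    mean_results = build_results_table(summaries, "mean")
    cv_results = build_results_table(summaries, "cv")
    return {
        "summaries": summaries,
        "mean_results": mean_results,
        "cv_results": cv_results,
        "mean_table": results_to_frame(mean_results),
        "cv_table": results_to_frame(cv_results),
        "failures": failures,
    }
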