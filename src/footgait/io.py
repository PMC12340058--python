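"""Reading and writing foot-IMU recordings and subject/cohort tables.

Recordings are delimited-text files with one sample per row (time, 3-axis
acceleration, 3-axis angular velocity).  A :class:`TxtDialect` maps file
columns onto the canonical channel order and declares the units on disk;
everything downstream of :func:`read_imu_txt` works in canonical units
(seconds, m/s^2, deg/s) with the foot-sensor axis convention
x = medial/lateral, y = anterior/posterior, z = superior/inferior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError, ValidationError

__all__ = [
    "GRAVITY",
    "TxtDialect",
    "ImuRecording",
    "SubjectRecord",
    "CohortTable",
    "read_imu_txt",
    "write_imu_txt",
    "read_cohort_csv",
    "write_cohort_csv",
    "select_cohort",
]

#: standard gravity, m/s^2
GRAVITY = 9.80665

#: canonical axis meaning, in storage order
AXIS_CONVENTION = {"x": "medial/lateral", "y": "anterior/posterior", "z": "superior/inferior"}

_ACC_SCALE = {"m/s^2": 1.0, "m/s2": 1.0, "g": GRAVITY}
_GYR_SCALE = {"deg/s": 1.0, "rad/s": math.degrees(1.0)}
_TIME_SCALE = {"s": 1.0, "ms": 1e-3}


@dataclass(frozen=True)
class TxtDialect:
    """Column mapping and unit declaration for delimited-text IMU files.

    The default matches the canonical dump written by :func:`write_imu_txt`:
    columns ``t, ax, ay, az, gx, gy, gz`` in SI units.
    """

    columns: tuple[str, ...] = ("t", "ax", "ay", "az", "gx", "gy", "gz")
    sep: str = ","
    acc_unit: str = "m/s^2"
    gyr_unit: str = "deg/s"
    time_unit: str = "s"
    header: bool = True

    def __post_init__(self) -> None:
        required = {"t", "ax", "ay", "az", "gx", "gy", "gz"}
        missing = required - set(self.columns)
        if missing:
            raise ConfigError(f"dialect is missing columns: {sorted(missing)}")
        if self.acc_unit not in _ACC_SCALE:
            raise ConfigError(f"unknown acceleration unit {self.acc_unit!r}")
        if self.gyr_unit not in _GYR_SCALE:
            raise ConfigError(f"unknown angular-velocity unit {self.gyr_unit!r}")
        if self.time_unit not in _TIME_SCALE:
            raise ConfigError(f"unknown time unit {self.time_unit!r}")


@dataclass
class ImuRecording:
    """A calibrated foot-IMU recording in canonical units.

    Parameters
    ----------
    t : (n,) array, seconds, strictly increasing
    acc : (n, 3) array, m/s^2, sensor frame
    gyr : (n, 3) array, deg/s, sensor frame
    standing_interval : optional (t0, t1) in seconds flagging quiet standing
        (the protocol records >= 30 s of standing before walking starts).
    """

    subject_id: str
    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    fs: float | None = None
    standing_interval: tuple[float, float] | None = None
    foot_side: str = "unknown"
    axis_convention: dict = field(default_factory=lambda: dict(AXIS_CONVENTION))

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        n = self.t.shape[0]
        if n < 2:
            raise DataError("recording needs at least two samples to estimate fs")
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise DataError(
                f"acc/gyr must be (n, 3) with one sample per timestamp; got "
                f"{self.acc.shape} and {self.gyr.shape} for n={n}"
            )
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise DataError("timestamps must be strictly increasing")
        if self.fs is None:
            self.fs = 1.0 / float(np.median(dt))
        if np.max(dt) > 3.0 / self.fs:
            raise DataError(
                f"gap of {np.max(dt):.4f} s exceeds 3 sample intervals at fs={self.fs:.1f} Hz"
            )
        if self.foot_side not in ("left", "right", "unknown"):
            raise ValidationError(f"foot_side must be left|right|unknown, got {self.foot_side!r}")
        if self.standing_interval is not None:
            t0, t1 = self.standing_interval
            if not (self.t[0] <= t0 < t1 <= self.t[-1]):
                raise ValidationError("standing_interval must lie within the recording")
            if t1 - t0 < 15.0:
                raise ValidationError("standing_interval must span at least 15 s")

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    def standing_slice(self) -> slice:
        """Sample slice covering the annotated standing interval."""
        if self.standing_interval is None:
            raise ValidationError(f"recording {self.subject_id} has no standing_interval")
        t0, t1 = self.standing_interval
        i0 = int(np.searchsorted(self.t, t0, side="left"))
        i1 = int(np.searchsorted(self.t, t1, side="right"))
        return slice(i0, i1)


def read_imu_txt(path, dialect: TxtDialect = TxtDialect(), subject_id: str = "",
                 standing_interval: tuple[float, float] | None = None) -> ImuRecording:
    """Read a delimited-text IMU recording and convert to canonical units."""
    df = pd.read_csv(path, sep=dialect.sep, header=0 if dialect.header else None)
    if dialect.header:
        missing = [c for c in dialect.columns if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        df = df[list(dialect.columns)]
    else:
        if df.shape[1] < len(dialect.columns):
            raise FormatError(
                f"{path}: expected {len(dialect.columns)} columns, found {df.shape[1]}"
            )
        df = df.iloc[:, : len(dialect.columns)]
        df.columns = list(dialect.columns)
    if df.shape[0] < 2:
        raise DataError(f"{path}: need at least two rows to estimate the sampling rate")
    t = df["t"].to_numpy(dtype=float) * _TIME_SCALE[dialect.time_unit]
    acc = df[["ax", "ay", "az"]].to_numpy(dtype=float) * _ACC_SCALE[dialect.acc_unit]
    gyr = df[["gx", "gy", "gz"]].to_numpy(dtype=float) * _GYR_SCALE[dialect.gyr_unit]
    return ImuRecording(
        subject_id=subject_id or str(path),
        t=t,
        acc=acc,
        gyr=gyr,
        standing_interval=standing_interval,
    )


def write_imu_txt(recording: ImuRecording, path) -> None:
    """Write the canonical CSV dump (t, ax..az in m/s^2, gx..gz in deg/s)."""
    df = pd.DataFrame(
        {
            "t": recording.t,
            "ax": recording.acc[:, 0],
            "ay": recording.acc[:, 1],
            "az": recording.acc[:, 2],
            "gx": recording.gyr[:, 0],
            "gy": recording.gyr[:, 1],
            "gz": recording.gyr[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# cohort tables


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's metadata row.

    ``grip_strength`` is the maximum hand-grip force normalized to body mass
    (N/kg), the sarcopenia-screening convention.  ``gds`` is the Global
    Deterioration Scale (1 = no cognitive decline).
    """

    subject_id: str
    sex: str
    age_years: int
    height_m: float
    body_mass_kg: float
    gds: int
    grip_strength: float
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"{self.subject_id}: sex must be F or M, got {self.sex!r}")
        if self.height_m <= 0 or self.body_mass_kg <= 0:
            raise ValidationError(f"{self.subject_id}: height and body mass must be positive")
        if self.gds < 1:
            raise ValidationError(f"{self.subject_id}: GDS must be >= 1")
        if self.grip_strength < 0:
            raise ValidationError(f"{self.subject_id}: grip strength must be >= 0")
        computed = self.body_mass_kg / self.height_m**2
        if self.bmi is None:
            object.__setattr__(self, "bmi", computed)
        elif abs(self.bmi - computed) > 0.5:
            raise ValidationError(
                f"{self.subject_id}: BMI {self.bmi:.2f} inconsistent with "
                f"mass/height^2 = {computed:.2f}"
            )


_COHORT_COLUMNS = [
    "subject_id", "sex", "age_years", "height_m", "body_mass_kg", "bmi", "gds", "grip_strength",
]


@dataclass
class CohortTable:
    """Ordered collection of :class:`SubjectRecord` with unique ids."""

    records: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> SubjectRecord:
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "sex": r.sex,
                    "age_years": r.age_years,
                    "height_m": r.height_m,
                    "body_mass_kg": r.body_mass_kg,
                    "bmi": r.bmi,
                    "gds": r.gds,
                    "grip_strength": r.grip_strength,
                }
                for r in self.records
            ],
            columns=_COHORT_COLUMNS,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortTable":
        missing = [c for c in _COHORT_COLUMNS if c not in df.columns and c != "bmi"]
        if missing:
            raise FormatError(f"cohort table missing columns {missing}")
        records = []
        for row in df.itertuples(index=False):
            bmi = getattr(row, "bmi", None)
            if bmi is not None and (isinstance(bmi, float) and math.isnan(bmi)):
                bmi = None
            records.append(
                SubjectRecord(
                    subject_id=str(row.subject_id),
                    sex=str(row.sex),
                    age_years=int(row.age_years),
                    height_m=float(row.height_m),
                    body_mass_kg=float(row.body_mass_kg),
                    gds=int(row.gds),
                    grip_strength=float(row.grip_strength),
                    bmi=None if bmi is None else float(bmi),
                )
            )
        return cls(records)


def read_cohort_csv(path) -> CohortTable:
    return CohortTable.from_frame(pd.read_csv(path))


def write_cohort_csv(cohort: CohortTable, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def select_cohort(cohort: CohortTable) -> tuple[CohortTable, list[tuple[str, str]]]:
    """Apply the eligibility rules: female sex, GDS <= 1, BMI <= 30 kg/m^2.

    Returns the retained cohort and an exclusion log of
    ``(subject_id, rule_name)`` pairs, one entry per excluded subject (the
    first failed rule, checked in the order sex, gds, bmi).
    """
    kept: list[SubjectRecord] = []
    exclusions: list[tuple[str, str]] = []
    for r in cohort:
        if r.sex != "F":
            exclusions.append((r.subject_id, "sex"))
        elif r.gds > 1:
            exclusions.append((r.subject_id, "gds"))
        elif r.bmi > 30.0:
            exclusions.append((r.subject_id, "bmi"))
        else:
            kept.append(r)
    return CohortTable(kept), exclusions
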