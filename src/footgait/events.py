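"""Gait-event detection from mediolateral angular velocity.

The pitch-rate trace of a foot-worn gyroscope shows one large positive peak
per stride in mid swing.  Toe-off is the negative-to-positive zero crossing
immediately before that peak, heel contact the positive-to-negative crossing
immediately after it, and foot flat the midpoint of a heel contact and the
following toe-off.  Signals are low-pass filtered (4th-order Butterworth,
10 Hz cutoff, applied forward and backward for zero phase lag) before
detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DataError, NoGaitError

__all__ = ["FilterConfig", "EventConfig", "GaitEventSet", "lowpass_zero_phase", "detect_events"]


@dataclass(frozen=True)
class FilterConfig:
    """Zero-phase low-pass filter: 4th-order coefficients run forward and
    backward, i.e. an effective 8th-order magnitude with -6 dB at cutoff."""

    order: int = 4
    cutoff_hz: float = 10.0


@dataclass(frozen=True)
class EventConfig:
    peak_threshold: float = 70.0        # deg/s, minimum mid-swing peak height
    min_peak_separation_s: float = 0.4  # suppresses double peaks within one swing

    def __post_init__(self) -> None:
        if self.peak_threshold <= 0:
            raise ValueError("peak_threshold must be positive")


@dataclass
class GaitEventSet:
    """Sample indices of heel contacts, toe-offs and foot flats.

    ``hc_idx[k] < ff_idx[k] < to_idx[k+1]`` for every stance: foot flat k is
    the midpoint of heel contact k and the next toe-off.  ``to_idx[0]``
    precedes ``hc_idx[0]`` (the first detected swing).
    """

    hc_idx: np.ndarray
    to_idx: np.ndarray
    ff_idx: np.ndarray
    fs: float

    @property
    def n_cycles(self) -> int:
        """Number of complete heel-contact-to-heel-contact parameter cycles.

        A complete cycle needs its bounding heel contacts, the toe-off of the
        following cycle (for the TO-referenced stride time) and the foot flat
        that closes its stride segment.
        """
        return max(len(self.hc_idx) - 2, 0)

    def times(self, which: str) -> np.ndarray:
        return getattr(self, which + "_idx") / self.fs


def lowpass_zero_phase(x: np.ndarray, fs: float, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Forward-backward Butterworth low-pass along the first axis."""
    x = np.asarray(x, dtype=float)
    if cfg.cutoff_hz >= fs / 2:
        raise DataError(f"cutoff {cfg.cutoff_hz} Hz must be below Nyquist ({fs / 2} Hz)")
    b, a = sps.butter(cfg.order, cfg.cutoff_hz, btype="low", fs=fs)
    padlen = 3 * max(len(a), len(b))
    if x.shape[0] <= 3 * padlen:
        raise DataError(f"series of length {x.shape[0]} too short to filter (need > {3 * padlen})")
    return sps.filtfilt(b, a, x, axis=0)


def _zero_crossings(x: np.ndarray, rising: bool) -> np.ndarray:
    """Sub-sample zero-crossing positions (float indices) by linear interpolation."""
    a, b = x[:-1], x[1:]
    mask = (a < 0) & (b >= 0) if rising else (a > 0) & (b <= 0)
    idx = np.flatnonzero(mask)
    frac = a[idx] / (a[idx] - b[idx])
    return idx + frac


def detect_events(gyr_x_filtered: np.ndarray, fs: float,
                  cfg: EventConfig = EventConfig()) -> GaitEventSet:
    """Detect gait events on the filtered mediolateral angular velocity.

    If the trace's dominant swing peaks are negative (mirrored sensor
    mounting), the signal is sign-flipped before detection.
    """
    x = np.asarray(gyr_x_filtered, dtype=float)
    if abs(x.min()) > abs(x.max()):
        x = -x  # polarity check: dorsiflexion-positive convention

    distance = max(int(round(cfg.min_peak_separation_s * fs)), 1)
    peaks, _ = sps.find_peaks(x, height=cfg.peak_threshold, distance=distance)
    if len(peaks) == 0:
        raise NoGaitError(
            f"no local maximum >= {cfg.peak_threshold} deg/s found: no gait detected"
        )

    ups = _zero_crossings(x, rising=True)
    downs = _zero_crossings(x, rising=False)

    to_list, hc_list = [], []
    for p in peaks:
        i_up = np.searchsorted(ups, p) - 1
        i_dn = np.searchsorted(downs, p)
        if i_up < 0 or i_dn >= len(downs):
            continue  # recording edge: flanking crossing missing, drop peak
        to_list.append(int(round(ups[i_up])))
        hc_list.append(int(round(downs[i_dn])))

    if not to_list:
        raise NoGaitError("all qualifying peaks lacked flanking zero crossings")

    to_idx = np.asarray(to_list)
    hc_idx = np.asarray(hc_list)
    # enforce alternation: each swing's TO must follow the previous swing's HC
    keep = np.ones(len(to_idx), dtype=bool)
    for k in range(1, len(to_idx)):
        prev = np.flatnonzero(keep[:k])
        if len(prev) and to_idx[k] <= hc_idx[prev[-1]]:
            keep[k] = False
    if not keep.all():
        warnings.warn(
            f"dropped {int((~keep).sum())} cycle(s) with non-alternating zero crossings",
            stacklevel=2,
        )
        to_idx, hc_idx = to_idx[keep], hc_idx[keep]

    # foot flat k = midpoint of stance [HC_k, TO_{k+1}]
    ff_idx = np.round((hc_idx[:-1] + to_idx[1:]) / 2.0).astype(int)
    return GaitEventSet(hc_idx=hc_idx, to_idx=to_idx, ff_idx=ff_idx, fs=fs)
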