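"""Raw-stream conditioning: zero-phase low-pass filtering, gait-event detection
from per-belt vertical force, and stride segmentation.

Conventions: kinematics are filtered at 6 Hz, ground-reaction forces at 20 Hz,
both with a fourth-order Butterworth applied forward-backward (zero phase; the
stated order is the per-pass design order, so the effective attenuation order
doubles).  Gait events are threshold crossings of the filtered vertical force
(default 20 N) with sub-sample timing by linear interpolation; load bouts
shorter than 100 ms are discarded as noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "EventTable",
    "StrideTable",
    "lowpass_zerophase",
    "detect_gait_events",
    "segment_strides",
]

KINEMATIC_CUTOFF_HZ = 6.0
FORCE_CUTOFF_HZ = 20.0
FORCE_THRESHOLD_N = 20.0
MIN_BOUT_S = 0.100


@dataclass
class EventTable:
    """Foot-strike / foot-off times (s) per leg; within a leg the events
    alternate strike, off, strike, off, ... and are strictly increasing."""

    fast_strikes: np.ndarray
    fast_offs: np.ndarray
    slow_strikes: np.ndarray
    slow_offs: np.ndarray

    def for_leg(self, leg: str) -> tuple[np.ndarray, np.ndarray]:
        if leg == "fast":
            return self.fast_strikes, self.fast_offs
        if leg == "slow":
            return self.slow_strikes, self.slow_offs
        raise ValueError(f"unknown leg {leg!r}")


@dataclass
class Stride:
    """One reference-leg stride: consecutive ipsilateral strikes with the
    enclosed ipsilateral foot-off and contralateral strike/off."""

    start: float
    end: float
    ipsi_off: float
    contra_strike: float
    contra_off: float
    valid: bool = True

    @property
    def duration(self) -> float:
        return self.end - self.start


StrideTable = list


def lowpass_zerophase(x: np.ndarray, rate: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward ``filtfilt``).

    ``order`` is the design order of each pass; at the cutoff the two-pass
    amplitude gain is 0.5 (twice -3 dB).  Raises if ``cutoff`` reaches the
    Nyquist frequency.
    """
    nyq = rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz at rate {rate} Hz")
    b, a = butter(order, cutoff / nyq, btype="low")
    x = np.asarray(x, dtype=float)
    return filtfilt(b, a, x, axis=0)


def _crossings(t, fz, threshold, rising):
    f0, f1 = fz[:-1], fz[1:]
    if rising:
        idx = np.nonzero((f0 < threshold) & (f1 >= threshold))[0]
    else:
        idx = np.nonzero((f0 >= threshold) & (f1 < threshold))[0]
    # linear interpolation between the bracketing samples
    frac = (threshold - f0[idx]) / (f1[idx] - f0[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def detect_gait_events_leg(t: np.ndarray, fz: np.ndarray,
                           threshold: float = FORCE_THRESHOLD_N) -> tuple[np.ndarray, np.ndarray]:
    """Strike (upward crossing) and foot-off (downward crossing) times for one
    belt's vertical force.  Bouts shorter than 100 ms are discarded."""
    t = np.asarray(t, float)
    fz = np.asarray(fz, float)
    strikes = _crossings(t, fz, threshold, rising=True)
    offs = _crossings(t, fz, threshold, rising=False)
    if strikes.size == 0 and offs.size == 0:
        raise ValueError("no gait events: vertical force never crosses the threshold")
    # drop a leading off (already loaded at start) and trailing strike
    if offs.size and (strikes.size == 0 or offs[0] < strikes[0]):
        offs = offs[1:]
    n = min(strikes.size, offs.size)
    strikes, offs = strikes[:n], offs[:n]
    keep = (offs - strikes) >= MIN_BOUT_S
    return strikes[keep], offs[keep]


def detect_gait_events(t: np.ndarray, fz_fast: np.ndarray, fz_slow: np.ndarray,
                       threshold: float = FORCE_THRESHOLD_N) -> EventTable:
    """Events for both legs from the two belts' (filtered) vertical forces."""
    fs, fo = detect_gait_events_leg(t, fz_fast, threshold)
    ss, so = detect_gait_events_leg(t, fz_slow, threshold)
    return EventTable(fast_strikes=fs, fast_offs=fo, slow_strikes=ss, slow_offs=so)


def segment_strides(events: EventTable, reference_leg: str = "fast") -> StrideTable:
    """Partition the trial into reference-leg strides.

    A stride spans consecutive ipsilateral strikes; the ipsilateral foot-off
    and the contralateral strike and foot-off must fall inside it, otherwise
    the stride is flagged invalid.  Boundary strides without a closing strike
    are dropped.
    """
    strikes, offs = events.for_leg(reference_leg)
    c_strikes, c_offs = events.for_leg("slow" if reference_leg == "fast" else "fast")
    if strikes.size < 2:
        raise ValueError("need at least two reference-leg strikes to form a stride")
    strides: StrideTable = []
    for k in range(strikes.size - 1):
        s, e = strikes[k], strikes[k + 1]

        def inside(arr):
            sel = arr[(arr > s) & (arr < e)]
            return sel[0] if sel.size else np.nan

        st = Stride(start=s, end=e, ipsi_off=inside(offs),
                    contra_strike=inside(c_strikes), contra_off=inside(c_offs))
        st.valid = not np.isnan([st.ipsi_off, st.contra_strike, st.contra_off]).any()
        strides.append(st)
    return strides
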