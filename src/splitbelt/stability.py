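"""Mediolateral margin of stability (ML MoS).

Pipeline: combine the two belts' plates into a single equivalent plate
(load-weighted CoP); obtain the ML CoM by double-integrating ML GRF / mass and
complementary-filtering against the CoP (the CoP carries the low-frequency
CoM motion, the force integral the high-frequency sway); extrapolate the CoM
by its velocity over the pendulum eigenfrequency omega0 = sqrt(g / l); and
evaluate the margin to the stance foot's lateral boundary at contralateral
foot-off.

Axis convention: lab x = anterior, y = left-lateral, z = up.  Plates report
the moment of the ground-reaction force about their own origin, so the
per-plate ML CoP is Mx / Fz plus the plate's ML offset.  MoS is signed so that
an extrapolated CoM medial to the stance boundary is positive, and reported in
cm (positions are metres internally).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, detrend, filtfilt

from .preprocess import EventTable

__all__ = ["combined_cop_ml", "com_ml_absolute", "xcom", "mos_per_stride"]

G = 9.81
DRIFT_CUTOFF_HZ = 0.4  # complementary-filter crossover
UNLOADED_MAX_GAP_S = 0.050


def combined_cop_ml(fz_per_plate: np.ndarray, mx_per_plate: np.ndarray,
                    plate_offsets_ml: tuple[float, ...], rate: float,
                    min_load: float = 50.0) -> np.ndarray:
    """Load-weighted ML centre of pressure of the combined plates.

    ``fz_per_plate`` and ``mx_per_plate`` are (n_samples, n_plates).  Samples
    where a plate carries less than ``min_load`` N ignore that plate; if all
    plates are unloaded for longer than 50 ms the trial is rejected (a person
    walking must load at least one belt), shorter gaps are interpolated.
    """
    fz = np.atleast_2d(np.asarray(fz_per_plate, float))
    mx = np.atleast_2d(np.asarray(mx_per_plate, float))
    if fz.ndim != 2 or fz.shape != mx.shape:
        raise ValueError("fz and mx must have identical (n_samples, n_plates) shapes")
    loaded = fz > min_load
    cop_plate = np.zeros_like(fz)
    np.divide(mx, fz, out=cop_plate, where=loaded)
    cop_plate += np.asarray(plate_offsets_ml)[None, :]
    wsum = np.where(loaded, fz, 0.0).sum(axis=1)
    num = (np.where(loaded, fz, 0.0) * cop_plate).sum(axis=1)
    any_loaded = wsum > 0
    if not any_loaded.any():
        raise ValueError("both plates unloaded for the whole record")
    gap = _longest_false_run(any_loaded) / rate
    if gap > UNLOADED_MAX_GAP_S:
        raise ValueError(
            f"both plates unloaded for {gap * 1e3:.0f} ms (> {UNLOADED_MAX_GAP_S * 1e3:.0f} ms)"
        )
    cop = np.full(fz.shape[0], np.nan)
    cop[any_loaded] = num[any_loaded] / wsum[any_loaded]
    if (~any_loaded).any():
        t = np.arange(fz.shape[0])
        cop = np.interp(t, t[any_loaded], cop[any_loaded])
    return cop


def _longest_false_run(mask: np.ndarray) -> int:
    worst = run = 0
    for ok in mask:
        run = 0 if ok else run + 1
        worst = max(worst, run)
    return worst


def com_ml_absolute(grf_ml: np.ndarray, mass: float, cop_ml: np.ndarray,
                    rate: float, cutoff: float = DRIFT_CUTOFF_HZ) -> tuple[np.ndarray, np.ndarray]:
    """ML CoM absolute position and velocity from force and CoP.

    The ML acceleration (F/m) is twice integrated (trapezoid) with linear
    detrending after each integration to control drift; the absolute position
    is the CoP plus the high-passed difference between the integrated position
    and the CoP, i.e. a complementary filter with crossover at ``cutoff``:
    below it the CoP defines the CoM, above it the force integral does.
    Velocity is the first difference of the absolute position.
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    grf_ml = np.asarray(grf_ml, float)
    cop_ml = np.asarray(cop_ml, float)
    if grf_ml.shape != cop_ml.shape:
        raise ValueError("force and CoP streams must be co-sampled")
    dt = 1.0 / rate
    a = grf_ml / mass
    v = cumulative_trapezoid(a - a.mean(), dx=dt, initial=0.0)
    v = detrend(v, type="linear")
    p = cumulative_trapezoid(v, dx=dt, initial=0.0)
    p = detrend(p, type="linear")
    b, coeff = butter(2, cutoff / (rate / 2.0), btype="high")
    com = cop_ml + filtfilt(b, coeff, p - cop_ml)
    vcom = np.gradient(com, dt)
    return com, vcom


def xcom(com: np.ndarray, vcom: np.ndarray, leg_length: float) -> np.ndarray:
    """Extrapolated centre of mass: com + vcom / omega0, omega0 = sqrt(g/l)."""
    if not leg_length > 0:
        raise ValueError(f"leg_length must be positive, got {leg_length}")
    omega0 = np.sqrt(G / leg_length)
    return np.asarray(com) + np.asarray(vcom) / omega0


def mos_per_stride(t: np.ndarray, xcom_ml: np.ndarray,
                   bos_fast_ml: np.ndarray, bos_slow_ml: np.ndarray,
                   events: EventTable,
                   fast_side: str = "left") -> pd.DataFrame:
    """Fast- and slow-leg ML MoS per stride, in cm.

    Fast-leg MoS is evaluated at slow-leg foot-off (the stance leg is the fast
    leg), slow-leg MoS at fast-leg foot-off.  The base of support is the
    stance leg's lateral-malleolus ML position at that instant, and the sign
    is chosen so that an xCoM medial to the boundary is positive:
    left-side stance uses (BoS - xCoM), right-side (xCoM - BoS).
    """
    if fast_side not in ("left", "right"):
        raise ValueError("fast_side must be 'left' or 'right'")
    sgn_fast = 1.0 if fast_side == "left" else -1.0

    def at(query, stream):
        if np.any(query < t[0]) or np.any(query > t[-1]):
            raise ValueError("event time outside stream range")
        return np.interp(query, t, stream)

    rows = []
    n = min(events.slow_offs.size, events.fast_offs.size)
    for k in range(n):
        so, fo = events.slow_offs[k], events.fast_offs[k]
        mos_fast = sgn_fast * (at(so, bos_fast_ml) - at(so, xcom_ml))
        mos_slow = -sgn_fast * (at(fo, bos_slow_ml) - at(fo, xcom_ml))
        rows.append({"stride": k, "t_fast": so, "t_slow": fo,
                     "mos_fast": 100.0 * mos_fast, "mos_slow": 100.0 * mos_slow})
    return pd.DataFrame(rows)
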