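"""Metabolic and mechanical energetics.

Metabolic side: breath-wise gross energy expenditure from gas exchange
(Brockway linear combination, E_gross = 16.58*VO2 + 4.51*VCO2 J min^-1 with
gas volumes in ml min^-1), gross -> net (standing baseline subtracted) -> mass
-normalized rates, removal of the onset transient at the start of exercise,
and relative effort as a percentage of VO2 peak.

Mechanical side: point-mass model of leg work on a treadmill.  Per-stride CoM
velocity comes from integrating (F - m g z)/m with integration constants
forcing zero per-stride mean velocity (belt frame is stationary in the lab).
Instantaneous leg power is the dot product of CoM velocity with that leg's GRF
(work on the body) plus the dot product of the belt velocity with the force on
the belt, the negative of the GRF (work on the treadmill).  Positive and
negative work are rectified time integrals over the stride, divided by stride
duration to give rates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, trapezoid

__all__ = [
    "brockway_rate",
    "net_relative_rate",
    "remove_onset_transient",
    "percent_vo2peak",
    "com_velocity_3d",
    "leg_power_and_work",
    "breath_table",
]

G = 9.81
BROCKWAY_O2 = 16.58  # J per ml O2
BROCKWAY_CO2 = 4.51  # J per ml CO2


def brockway_rate(vo2_ml_min, vco2_ml_min):
    """Gross energy expenditure (J min^-1) and gross metabolic rate (W)."""
    vo2 = np.asarray(vo2_ml_min, float)
    vco2 = np.asarray(vco2_ml_min, float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas exchange volumes must be non-negative")
    e_gross = BROCKWAY_O2 * vo2 + BROCKWAY_CO2 * vco2
    return e_gross, e_gross / 60.0


def net_relative_rate(w_gross: np.ndarray, standing_w_gross: np.ndarray,
                      mass: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Net and mass-relative net metabolic rate.

    The standing baseline is the mean gross rate over the standing record
    (>= 2 min of breaths recommended; shorter windows are used with a warning).
    Returns (w_net, w_net_per_kg, baseline).
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    standing = np.asarray(standing_w_gross, float)
    baseline = float(standing.mean())
    w_net = np.asarray(w_gross, float) - baseline
    return w_net, w_net / mass, baseline


def remove_onset_transient(t: np.ndarray, w_net: np.ndarray,
                           window_s: float = 30.0,
                           search_s: float = 180.0) -> tuple[np.ndarray, np.ndarray]:
    """Drop breaths during the initial on-transient rise of metabolic rate.

    The transient end is the maximum of a 30-s moving average restricted to
    the first 3 min of the series; all earlier breaths are removed and the
    remainder keeps its original timestamps.  When the smoothed series
    plateaus, several windows tie for the maximum within noise; the tie is
    resolved to the latest such time (the end of the rise), using one standard
    error of the window mean as the tie band.  A series shorter than the
    search span, or one with no rise at all (peak at the first breath), is
    returned with a warning / unchanged respectively.
    """
    t = np.asarray(t, float)
    w = np.asarray(w_net, float)
    if t[-1] - t[0] < search_s:
        warnings.warn("series shorter than the transient search span; "
                      "searching the available record")
    # trailing average: the transient is over once the average of the
    # preceding 30 s of breaths stops rising
    counts = np.array([((t >= ti - window_s) & (t <= ti)).sum() for ti in t])
    smoothed = np.array([
        w[(t >= ti - window_s) & (t <= ti)].mean() for ti in t
    ])
    in_search = np.nonzero(t <= t[0] + search_s)[0]
    # robust breath-to-breath noise scale -> SE of the window mean
    dw = np.diff(w)
    sigma = np.median(np.abs(dw)) / (np.sqrt(2.0) * 0.6745) if dw.size else 0.0
    tie_band = sigma / np.sqrt(max(counts[in_search].max(), 1))
    peak_val = smoothed[in_search].max()
    tied = in_search[smoothed[in_search] >= peak_val - tie_band]
    peak_idx = int(tied[-1])
    if np.allclose(w, w[0]):
        warnings.warn("constant metabolic series; nothing to remove")
        return t, w
    keep = t >= t[peak_idx]
    return t[keep], w[keep]


def percent_vo2peak(mean_walking_vo2: float, vo2peak: float) -> float:
    """Relative effort, percent of VO2 peak (inputs in ml kg^-1 min^-1)."""
    if vo2peak <= 0:
        raise ValueError("vo2peak must be positive")
    return 100.0 * mean_walking_vo2 / vo2peak


def breath_table(breaths: pd.DataFrame, standing: pd.DataFrame,
                 mass: float) -> pd.DataFrame:
    """Per-breath energetics table from raw gas exchange.

    Input frames need columns t, vo2_ml_min, vco2_ml_min.  Output adds
    e_gross (J min^-1), w_gross (W), w_net (W) and w_net_per_kg (W kg^-1).
    """
    e_gross, w_gross = brockway_rate(breaths["vo2_ml_min"], breaths["vco2_ml_min"])
    _, w_stand = brockway_rate(standing["vo2_ml_min"], standing["vco2_ml_min"])
    w_net, w_net_kg, baseline = net_relative_rate(w_gross, w_stand, mass)
    out = breaths.copy()
    out["e_gross"] = e_gross
    out["w_gross"] = w_gross
    out["w_net"] = w_net
    out["w_net_per_kg"] = w_net_kg
    out.attrs["standing_baseline_w"] = baseline
    return out


def _stride_slice(t: np.ndarray, start: float, end: float) -> np.ndarray:
    return (t >= start) & (t < end)


def com_velocity_3d(t: np.ndarray, grf_total: np.ndarray, mass: float,
                    strides) -> np.ndarray:
    """CoM velocity (lab frame) per sample, integrated stride by stride.

    ``grf_total`` is (n, 3) total ground-reaction force (x anterior, y left,
    z up).  Acceleration (F - m g z)/m is trapezoid-integrated within each
    stride, and the integration constant per stride and axis is set so the
    per-stride mean velocity is zero (steady treadmill walking does not
    translate in the lab).  Samples outside any stride hold zero.
    """
    grf = np.asarray(grf_total, float)
    if grf.ndim != 2 or grf.shape[1] != 3:
        raise ValueError("grf_total must be (n, 3)")
    if not np.isfinite(grf).all():
        raise ValueError("force dropout (non-finite samples) in stride data")
    a = grf / mass
    a[:, 2] -= G
    v = np.zeros_like(a)
    for st in strides:
        m = _stride_slice(t, st.start, st.end)
        if not m.any():
            continue
        seg = cumulative_trapezoid(a[m], x=t[m], axis=0, initial=0.0)
        v[m] = seg - seg.mean(axis=0)
    return v


def leg_power_and_work(t: np.ndarray, grf_fast: np.ndarray, grf_slow: np.ndarray,
                       v_com: np.ndarray, belt_speeds: tuple[float, float],
                       strides) -> pd.DataFrame:
    """Per-stride rectified work rates of each leg (W).

    P_leg(t) = v_com . GRF_leg + v_belt . (-GRF_leg), with the belt surface
    moving posteriorly: v_belt = (-speed, 0, 0).  Per stride, W+ and W- are
    the rectified trapezoid integrals of P divided by stride duration, and
    the net rate is the sum of all four signed rates.
    """
    v_fast = np.array([-belt_speeds[0], 0.0, 0.0])
    v_slow = np.array([-belt_speeds[1], 0.0, 0.0])
    for g in (grf_fast, grf_slow):
        if np.asarray(g).shape != np.asarray(v_com).shape:
            raise ValueError("mismatched stream shapes")
    p_fast = (v_com * grf_fast).sum(axis=1) + (-grf_fast) @ v_fast
    p_slow = (v_com * grf_slow).sum(axis=1) + (-grf_slow) @ v_slow
    rows = []
    for k, st in enumerate(strides):
        m = _stride_slice(t, st.start, st.end)
        if m.sum() < 2:
            continue
        tt = t[m]
        rec = {"stride": k, "t": st.start, "duration": st.duration}
        for leg, p in (("fast", p_fast[m]), ("slow", p_slow[m])):
            rec[f"w_pos_{leg}"] = trapezoid(np.maximum(p, 0.0), tt) / st.duration
            rec[f"w_neg_{leg}"] = trapezoid(np.minimum(p, 0.0), tt) / st.duration
        rec["w_net"] = (rec["w_pos_fast"] + rec["w_neg_fast"]
                        + rec["w_pos_slow"] + rec["w_neg_slow"])
        rows.append(rec)
    return pd.DataFrame(rows)
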