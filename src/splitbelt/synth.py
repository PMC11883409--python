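"""Synthetic split-belt cohorts at two fidelity tiers.

Tier 1 (measure level): per-stride series of step-length asymmetry (SLA), step
lengths, mediolateral margins of stability (MoS) and mechanical work rates, and
per-breath net metabolic rate, all drawn from the dual-rate exponential
adaptation model with a per-subject random plateau shared across measures.

Tier 2 (signal level): full raw trials — ankle/ASIS marker trajectories,
per-belt 3-D ground-reaction forces and moments, and a breath table — built by
inverse construction so that the processing pipeline's outputs (step lengths,
MoS, work rates) have known ground truth.

Determinism: identical (config, truth, seed) produces identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    AdaptationParams,
    CohortConfig,
    DEFAULT_TRUTH,
    SubjectParams,
    dual_rate_curve,
)

__all__ = [
    "Cohort",
    "GaitTrial",
    "generate_subjects",
    "generate_measure_series",
    "generate_cohort",
    "generate_signal_trial",
    "generate_standing_breaths",
    "generate_fitness_dataset",
]

G = 9.81  # m s^-2

#: Brockway-style inversion used when synthesizing gas volumes from a target
#: energy rate (respiratory exchange ratio assumed in synthesis).
SYNTH_RER = 0.85


@dataclass
class Cohort:
    """Measure-level synthetic cohort: long table + provenance."""

    data: pd.DataFrame  # columns: subject, measure, t, value
    subjects: list[SubjectParams]
    truth: dict[str, AdaptationParams]
    config: CohortConfig

    def series(self, measure: str) -> pd.DataFrame:
        """Long table (subject, t, value) for one measure."""
        out = self.data[self.data["measure"] == measure]
        return out[["subject", "t", "value"]].reset_index(drop=True)


@dataclass
class GaitTrial:
    """Raw synchronized streams for one walking bout plus ground truth."""

    markers: pd.DataFrame  # 100 Hz: t, ankle_L_x/y/z, ankle_R_x/y/z, asis_L_y, asis_R_y
    forces: pd.DataFrame  # 1000 Hz: t, {fast,slow} x Fx/Fy/Fz/Mx/My/Mz
    breaths: pd.DataFrame  # t, vo2_ml_min, vco2_ml_min
    subject: SubjectParams
    condition: str = "adaptation"
    truth: dict = field(default_factory=dict)

    marker_rate: float = 100.0
    force_rate: float = 1000.0
    #: plate mediolateral origin offsets in the lab frame (fast, slow), m
    plate_offsets_ml: tuple[float, float] = (0.25, -0.25)


# ---------------------------------------------------------------------------
# subjects


def generate_subjects(config: CohortConfig) -> list[SubjectParams]:
    """Draw a cohort of subjects (anthropometrics, fitness, random plateau)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    subjects = []
    for i in range(config.n_subjects):
        gender = "woman" if i % 2 == 0 else "man"
        height = float(np.clip(rng.normal(1.72, 0.08), 1.5, 2.0))
        mass = float(np.clip(rng.normal(72.0, 10.0), 45.0, 110.0))
        vo2peak = float(np.clip(rng.normal(40.0, 6.0), 25.0, 60.0))
        subjects.append(
            SubjectParams(
                id=f"S{i + 1:02d}",
                mass=mass,
                height=height,
                leg_length=round(0.53 * height, 4),
                vo2peak=vo2peak,
                gender=gender,
                plateau_offset=float(rng.standard_normal()),
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# tier 1: measure-level series


def _measure_times(measure: str, config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Sampling instants: stride cadence for biomechanics, breath cadence for
    metabolic (breath intervals jittered +-20% around the nominal period)."""
    if measure == "metabolic_rate":
        n = int(np.ceil(config.duration / (0.8 * config.breath_period))) + 2
        gaps = config.breath_period * rng.uniform(0.8, 1.2, size=n)
        t = np.cumsum(gaps) - gaps[0]
        return t[t <= config.duration]
    return np.arange(0.0, config.duration, config.stride_period)


def generate_measure_series(
    params: AdaptationParams,
    subject: SubjectParams,
    config: CohortConfig,
    measure: str,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """One subject's noisy adaptation series for one measure.

    The subject's plateau offset (a standard-normal draw) is scaled by the
    cohort's per-measure plateau SD.  The metabolic series is delayed by
    ``config.metabolic_lag`` and multiplied by a mono-exponential onset
    transient (time constant ``config.metabolic_onset_tau``), emulating the
    rise of oxygen uptake at exercise onset.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if noise_sd is None:
        noise_sd = config.noise_for(measure)
    t = _measure_times(measure, config, rng)
    p = params.with_plateau_offset(subject.plateau_offset * config.plateau_sd_for(measure))
    if measure == "metabolic_rate":
        # prepended onset transient: a mono-exponential rise toward the
        # start-of-adaptation rate during the lag, then the (shifted) decay
        y = dual_rate_curve(np.maximum(t - config.metabolic_lag, 0.0), p)
        lag, tau = config.metabolic_lag, config.metabolic_onset_tau
        if lag > 0 and tau > 0:
            pre = t < lag
            rise = np.expm1(-t[pre] / tau) / np.expm1(-lag / tau)
            y[pre] = dual_rate_curve(0.0, p) * rise
    else:
        y = dual_rate_curve(t, p)
    y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return pd.DataFrame({"t": t, "value": y})


def _derived_slow_step_curve(
    truth: dict[str, AdaptationParams], subject_offsets: dict[str, float], t: np.ndarray
) -> np.ndarray:
    """Slow-leg step-length curve derived from the fast-leg and SLA curves so
    that the three series satisfy the SLA definition exactly before noise:
    L_slow = L_fast * (1 - SLA) / (1 + SLA)."""
    lf = dual_rate_curve(t, truth["step_length_fast"].with_plateau_offset(
        subject_offsets["step_length_fast"]))
    y = dual_rate_curve(t, truth["sla"].with_plateau_offset(subject_offsets["sla"]))
    return lf * (1.0 - y) / (1.0 + y)


#: Cross-measure coupling of SLA to the stability and work measures, active
#: when the coupled measures are generated together.  MoS couplings act on the
#: noiseless deviation of each MoS curve from its plateau (stability shapes
#: SLA only while stability itself is still adapting); the work coupling acts
#: on the full deviation including stride noise (stride-level mechanical
#: coupling that persists throughout adaptation).  Units: SLA per cm for the
#: MoS terms, SLA per W kg^-1 for the work term.
DEFAULT_COUPLINGS: dict[str, float] = {
    "mos_fast": 0.02,
    "mos_slow": -0.02,
    "work_net": -0.05,
}


def generate_cohort(
    config: CohortConfig,
    truth: dict[str, AdaptationParams] | None = None,
    measures: list[str] | None = None,
    subjects: list[SubjectParams] | None = None,
    couplings: dict[str, float] | None = None,
) -> Cohort:
    """Measure-level cohort.

    Each subject's plateau offsets come from a single standard-normal draw
    scaled by the per-measure plateau SD, shared across the kinematic and
    energetic measures; the MoS measures use an independent draw (frontal-
    plane placement plateaus are not tied to a subject's asymmetry plateau).
    The slow-leg step-length series is derived from the fast-leg and SLA
    curves (see :func:`_derived_slow_step_curve`) so that recomputing SLA from
    the generated step-length pair reproduces the generated SLA series up to
    noise.  When SLA is generated together with the MoS / net-work measures,
    the couplings (default :data:`DEFAULT_COUPLINGS`) are added to the SLA
    series.
    """
    if truth is None:
        truth = dict(DEFAULT_TRUTH)
    if measures is None:
        measures = list(truth)
    if subjects is None:
        subjects = generate_subjects(config)
    if couplings is None:
        couplings = dict(DEFAULT_COUPLINGS)

    t_stride = np.arange(0.0, config.duration, config.stride_period)
    frames = []
    for i, subj in enumerate(subjects):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13, i]))
        mos_z = float(np.random.default_rng(
            np.random.SeedSequence([config.seed, 17, i])).standard_normal())
        offsets = {
            m: (mos_z if m.startswith("mos") else subj.plateau_offset)
            * config.plateau_sd_for(m)
            for m in truth
        }
        series: dict[str, pd.DataFrame] = {}
        for measure in measures:
            if measure == "step_length_slow" and {"sla", "step_length_fast"} <= set(measures):
                y = _derived_slow_step_curve(truth, offsets, t_stride)
                y = y + rng.normal(0.0, config.noise_for(measure), size=t_stride.shape)
                series[measure] = pd.DataFrame({"t": t_stride, "value": y})
            else:
                series[measure] = generate_measure_series(
                    truth[measure], subj, config, measure, rng=rng
                )
        if "sla" in series:
            extra = np.zeros(len(series["sla"]))
            for m in ("mos_fast", "mos_slow"):
                if m in series and m in couplings:
                    dev = dual_rate_curve(t_stride, truth[m]) - truth[m].c
                    extra += couplings[m] * dev
            if "work_net" in series and "work_net" in couplings:
                p = truth["work_net"].with_plateau_offset(offsets["work_net"])
                dev = series["work_net"]["value"].to_numpy() - p.c
                extra += couplings["work_net"] * dev
            series["sla"]["value"] += extra
        for measure, df in series.items():
            frames.append(df.assign(subject=subj.id, measure=measure))
    data = pd.concat(frames, ignore_index=True)[["subject", "measure", "t", "value"]]
    return Cohort(data=data, subjects=subjects, truth=truth, config=config)


# ---------------------------------------------------------------------------
# tier 2: signal-level trial


def _quintic_segment(t: np.ndarray, t0: float, t1: float, x0: float, x1: float,
                     v0: float, v1: float) -> np.ndarray:
    """Quintic Hermite interpolant with zero end accelerations (C2 junctions
    against constant-velocity stance segments)."""
    h = t1 - t0
    u = (t - t0) / h
    # boundary conditions: x(0)=x0, x(1)=x1, x'(0)=v0*h, x'(1)=v1*h, x''=0 at ends
    b0, b1 = x0, v0 * h
    d = x1 - x0
    c3 = 10 * d - 6 * b1 - 4 * v1 * h
    c4 = -15 * d + 8 * b1 + 7 * v1 * h
    c5 = 6 * d - 3 * b1 - 3 * v1 * h
    return b0 + b1 * u + c3 * u**3 + c4 * u**4 + c5 * u**5


# high-order Hermite: x, x' prescribed and derivatives 2-4 zero at both ends,
# so swing segments join the constant-velocity stance lines with C4 continuity
# and the marker spectrum stays well below the kinematic filter cutoff
_NONIC_M_INV = np.linalg.inv(np.array([
    [1.0, 1.0, 1.0, 1.0, 1.0],
    [5.0, 6.0, 7.0, 8.0, 9.0],
    [20.0, 30.0, 42.0, 56.0, 72.0],
    [60.0, 120.0, 210.0, 336.0, 504.0],
    [120.0, 360.0, 840.0, 1680.0, 3024.0],
]))


def _septic_segment(t: np.ndarray, t0: float, t1: float, x0: float, x1: float,
                    v0: float, v1: float) -> np.ndarray:
    h = t1 - t0
    u = (t - t0) / h
    d = x1 - x0 - v0 * h
    w = (v1 - v0) * h
    c = _NONIC_M_INV @ np.array([d, w, 0.0, 0.0, 0.0])
    return x0 + v0 * h * u + sum(ck * u ** (5 + k) for k, ck in enumerate(c))


def _leg_trajectory(t: np.ndarray, strikes: np.ndarray, strike_x: np.ndarray,
                    v_belt: float, margin: float, land: float) -> np.ndarray:
    """Ankle AP trajectory.

    From each strike the marker rides the belt line for ``margin`` seconds
    (covering the instants at which step lengths sample it), transitions with a
    C3 septic segment, and rejoins the next stance line ``land`` seconds before
    the next strike, so no sampled instant is within the kinematic filter's
    reach of the transition.
    """
    x = np.full_like(t, strike_x[0])
    x[t < strikes[0]] = strike_x[0] - v_belt * (t[t < strikes[0]] - strikes[0])
    for k in range(len(strikes)):
        s = strikes[k]
        if k + 1 < len(strikes):
            s_next = strikes[k + 1]
            a, b = s + margin, s_next - land
            m = (t >= s) & (t < a)
            x[m] = strike_x[k] - v_belt * (t[m] - s)
            m = (t >= a) & (t < b)
            x[m] = _septic_segment(
                t[m], a, b,
                strike_x[k] - v_belt * margin,
                strike_x[k + 1] + v_belt * land,
                -v_belt, -v_belt)
            m = (t >= b) & (t < s_next)
            x[m] = strike_x[k + 1] - v_belt * (t[m] - s_next)
        else:
            m = t >= s
            x[m] = strike_x[k] - v_belt * np.minimum(t[m] - s, margin)
    return x


def _hold_with_blend(t: np.ndarray, knot_t: np.ndarray, knot_v: np.ndarray,
                     blend: float) -> np.ndarray:
    """Piecewise-constant schedule with smooth quintic blends of width ``blend``
    starting at each knot time."""
    v = np.full_like(t, knot_v[0])
    for k in range(1, len(knot_t)):
        a, b = knot_t[k], knot_t[k] + blend
        v[t >= b] = knot_v[k]
        m = (t >= a) & (t < b)
        if m.any():
            v[m] = _quintic_segment(t[m], a, b, knot_v[k - 1], knot_v[k], 0.0, 0.0)
    return v


def generate_signal_trial(
    subject: SubjectParams,
    config: CohortConfig,
    truth: dict[str, AdaptationParams] | None = None,
    sway_amplitude: float = 0.02,
    stance_fraction: float = 0.65,
    noise: bool = False,
) -> GaitTrial:
    """Construct a raw adaptation trial whose processed outputs are known.

    The gait is periodic with stride period ``config.stride_period``: the fast
    leg strikes at ``t0 + k*T``, the slow leg half a stride later; stance
    vertical force is a half-sine bump whose peak is set so the mean total
    vertical force over an integer number of strides equals body weight.
    Anterior-posterior ankle trajectories follow the belt during stance and a
    C2-smooth swing such that the step length at every ipsilateral strike
    equals the scheduled (noiseless) adaptation-curve value.  Mediolateral
    force is the second derivative of a prescribed CoM sway
    ``y(t) = A*sin(2*pi*t/T)``; plate moments encode a prescribed CoP trace;
    stance-foot ML positions are placed so the margin of stability at
    contralateral foot-off equals the scheduled MoS curve.  Per-leg AP shear
    forces carry the scheduled net mechanical work rate through the belt term
    of the point-mass power model.
    """
    if truth is None:
        truth = dict(DEFAULT_TRUTH)
    T = config.stride_period
    v_fast, v_slow = config.belt_speeds
    dur = config.duration
    stance = stance_fraction * T
    if stance <= 0.15 or T - stance <= 0.1:
        raise ValueError("stride_period too short for stance+swing construction")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))

    t0 = 0.4  # first fast-leg strike; slow leg is mid-stance at t=0
    n_strides = int(np.floor((dur - t0) / T)) + 1  # final stance clipped by record end
    fast_strikes = t0 + T * np.arange(n_strides)
    slow_strikes = fast_strikes + T / 2.0
    fast_offs = fast_strikes + stance
    slow_offs = slow_strikes + stance

    offsets = {m: subject.plateau_offset * config.plateau_sd_for(m) for m in truth}

    # scheduled step lengths (noiseless curves at the ipsilateral strike times)
    L_fast = dual_rate_curve(
        fast_strikes, truth["step_length_fast"].with_plateau_offset(offsets["step_length_fast"])
    )
    L_slow = _derived_slow_step_curve(truth, offsets, slow_strikes)

    # ankle strike positions solved stride by stride from the contralateral
    # stance-foot position plus the scheduled step length
    x_fast_strike = np.empty(n_strides)
    x_slow_strike = np.empty(n_strides)
    x_slow_prev = 0.0  # slow ankle AP at its virtual strike t0 - T/2
    for k in range(n_strides):
        x_slow_at_fs = x_slow_prev - v_slow * (T / 2.0)
        x_fast_strike[k] = x_slow_at_fs + L_fast[k]
        x_fast_at_ss = x_fast_strike[k] - v_fast * (T / 2.0)
        x_slow_strike[k] = x_fast_at_ss + L_slow[k]
        x_slow_prev = x_slow_strike[k]

    tm = np.arange(0.0, dur, 1.0 / 100.0)
    tf = np.arange(0.0, dur, 1.0 / 1000.0)

    # Marker trajectories track the belt line from each strike until after the
    # contralateral strike samples them (T/2 later), then transition smoothly
    # to the next strike position over the remainder of the stride (the marker
    # may leave the belt line in late stance, as a rising heel does); the wide
    # transition keeps the 6 Hz-filtered positions on schedule.
    margin = T / 2.0 + 0.10 * T
    land = 0.08 * T
    x_fast_m = _leg_trajectory(tm, fast_strikes, x_fast_strike, v_fast, margin, land)
    # slow leg: prepend the virtual stride so it is in stance from t=0
    ss = np.concatenate(([t0 - T / 2.0], slow_strikes))
    so = np.concatenate(([t0 - T / 2.0 + stance], slow_offs))
    sx = np.concatenate(([0.0], x_slow_strike))
    x_slow_m = _leg_trajectory(tm, ss, sx, v_slow, margin, land)

    # Vertical force: half-sine stance bumps.  The bump leads the scheduled
    # strike by the time the rising half-sine needs to reach the event
    # threshold, so threshold-crossing detection lands on the scheduled event
    # times; the peak is set so mean total force over integer strides equals
    # body weight.
    mg = subject.mass * G
    thr = 20.0  # construction counterpart of the default event threshold (N)
    f_peak, lead = mg * np.pi * T / (4.0 * stance), 0.0
    for _ in range(4):
        lead = (stance + 2 * lead) / np.pi * np.arcsin(thr / f_peak)
        f_peak = mg * np.pi * T / (4.0 * (stance + 2 * lead))

    def bumps(tvec, strikes):
        fz = np.zeros_like(tvec)
        width = stance + 2 * lead
        for s in strikes:
            b0 = s - lead
            m = (tvec >= b0) & (tvec < b0 + width)
            fz[m] = f_peak * np.sin(np.pi * (tvec[m] - b0) / width)
        return fz

    fz_fast = bumps(tf, fast_strikes)
    fz_slow = bumps(tf, ss)

    # prescribed ML CoM sway and the ML force that produces it
    omega = 2.0 * np.pi / T
    sway = sway_amplitude * np.sin(omega * tf)
    f_ml_total = subject.mass * (-sway_amplitude * omega**2 * np.sin(omega * tf))
    # split ML force across plates by instantaneous vertical-load share
    fz_tot = fz_fast + fz_slow
    share_fast = np.divide(fz_fast, fz_tot, out=np.full_like(fz_tot, 0.5), where=fz_tot > 0)
    fy_fast = f_ml_total * share_fast
    fy_slow = f_ml_total * (1.0 - share_fast)

    # margin-of-stability schedule -> stance-foot ML placement
    omega0 = np.sqrt(G / subject.leg_length)
    sway_v = sway_amplitude * omega * np.cos(omega * tm)
    xcom_m = sway_amplitude * np.sin(omega * tm) + sway_v / omega0

    # Both legs follow a common stability schedule in the signal tier: the
    # CoP-anchored CoM estimator cannot observe an opposite common-mode drift
    # of the two foot placements (the low-frequency CoM is the load-weighted
    # placement midline), so per-leg distinct MoS dynamics are a measure-tier
    # feature only.
    mos_truth = truth["mos_fast"].with_plateau_offset(offsets["mos_fast"])
    mos_fast_cm = dual_rate_curve(slow_offs, mos_truth)
    mos_slow_cm = dual_rate_curve(fast_offs, mos_truth)
    xcom_at_so = np.interp(slow_offs, tm, xcom_m)
    xcom_at_fo = np.interp(fast_offs, tm, xcom_m)
    # fast leg on the left (lab +y): MoS = BoS - xcom; slow leg right: MoS = xcom - BoS
    y_fast_knots = mos_fast_cm / 100.0 + xcom_at_so
    y_slow_knots = xcom_at_fo - mos_slow_cm / 100.0
    # each placement takes effect during the leg's swing preceding the stance
    # in which its MoS event falls: blend at foot-off k toward knot k
    y_fast_m = _hold_with_blend(tm, fast_offs, y_fast_knots, blend=T - stance)
    y_slow_m = _hold_with_blend(tm, so[:n_strides], y_slow_knots, blend=T - stance)

    # prescribed per-plate CoP: under the stance foot (AP follows ankle, ML the
    # placement schedule); moments encode it about each plate origin
    y_fast_f = np.interp(tf, tm, y_fast_m)
    y_slow_f = np.interp(tf, tm, y_slow_m)
    x_fast_f = np.interp(tf, tm, x_fast_m)
    x_slow_f = np.interp(tf, tm, x_slow_m)
    off_fast, off_slow = 0.25, -0.25

    # AP shear: half-sine per stance scaled per stride to carry the scheduled
    # net work rate through the treadmill (belt) power term
    w_net = dual_rate_curve(
        fast_strikes, truth["work_net"].with_plateau_offset(offsets["work_net"])
    )  # W kg^-1 schedule, per stride
    # fast-leg AP impulse carrying the scheduled net rate: the belt power terms
    # sum to impulse*(v_fast - v_slow) per stride
    impulse = w_net * subject.mass * T / (v_fast - v_slow)  # N s
    fx_fast = np.zeros_like(tf)
    fx_slow = np.zeros_like(tf)
    for k in range(n_strides):
        amp = impulse[k] * np.pi / (2.0 * stance)
        m = (tf >= fast_strikes[k]) & (tf < fast_offs[k])
        fx_fast[m] = amp * np.sin(np.pi * (tf[m] - fast_strikes[k]) / stance)
        m = (tf >= ss[k]) & (tf < so[k])
        fx_slow[m] = -amp * np.sin(np.pi * (tf[m] - ss[k]) / (so[k] - ss[k]))

    def moments(fz, fx, fy, cop_x, cop_y, off_y):
        mx = (cop_y - off_y) * fz
        my = -cop_x * fz
        mz = np.zeros_like(fz)
        return mx, my, mz

    mx_f, my_f, mz_f = moments(fz_fast, fx_fast, fy_fast, x_fast_f, y_fast_f, off_fast)
    mx_s, my_s, mz_s = moments(fz_slow, fx_slow, fy_slow, x_slow_f, y_slow_f, off_slow)

    if noise:
        for arr, sd in ((fz_fast, 2.0), (fz_slow, 2.0), (fx_fast, 0.5), (fx_slow, 0.5)):
            arr += rng.normal(0.0, sd, size=arr.shape)

    forces = pd.DataFrame({
        "t": tf,
        "fast_Fx": fx_fast, "fast_Fy": fy_fast, "fast_Fz": fz_fast,
        "fast_Mx": mx_f, "fast_My": my_f, "fast_Mz": mz_f,
        "slow_Fx": fx_slow, "slow_Fy": fy_slow, "slow_Fz": fz_slow,
        "slow_Mx": mx_s, "slow_My": my_s, "slow_Mz": mz_s,
    })

    markers = pd.DataFrame({
        "t": tm,
        "ankle_L_x": x_fast_m, "ankle_L_y": y_fast_m, "ankle_L_z": np.full_like(tm, 0.08),
        "ankle_R_x": x_slow_m, "ankle_R_y": y_slow_m, "ankle_R_z": np.full_like(tm, 0.08),
        "asis_L_y": 0.12 + sway_amplitude * np.sin(omega * tm),
        "asis_R_y": -0.12 + sway_amplitude * np.sin(omega * tm),
    })

    breaths = _breaths_from_metabolic(subject, config, truth, rng)

    truth_out = {
        "fast_strikes": fast_strikes, "fast_offs": fast_offs,
        "slow_strikes": slow_strikes, "slow_offs": slow_offs,
        "step_length_fast": L_fast, "step_length_slow": L_slow,
        "mos_fast_cm": mos_fast_cm, "mos_slow_cm": mos_slow_cm,
        "work_net_w_per_kg": w_net,
        "sway_amplitude": sway_amplitude,
        "com_ml": sway, "standing_w_per_kg": STANDING_W_PER_KG,
    }
    return GaitTrial(markers=markers, forces=forces, breaths=breaths,
                     subject=subject, condition="adaptation", truth=truth_out)


STANDING_W_PER_KG = 1.3  # gross standing metabolic rate, W kg^-1


def _gas_from_gross_watts(w_gross: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invert the Brockway energy equation at the synthesis RER."""
    e_j_min = w_gross * 60.0
    vo2 = e_j_min / (16.58 + 4.51 * SYNTH_RER)
    return vo2, SYNTH_RER * vo2


def _breaths_from_metabolic(subject, config, truth, rng) -> pd.DataFrame:
    series = generate_measure_series(
        truth["metabolic_rate"], subject, config, "metabolic_rate", rng=rng,
        noise_sd=0.0,
    )
    w_gross = (series["value"].to_numpy() + STANDING_W_PER_KG) * subject.mass
    vo2, vco2 = _gas_from_gross_watts(np.maximum(w_gross, 0.0))
    return pd.DataFrame({"t": series["t"].to_numpy(),
                         "vo2_ml_min": vo2, "vco2_ml_min": vco2})


def generate_standing_breaths(subject: SubjectParams, duration: float = 240.0,
                              breath_period: float = 4.0, seed: int = 0) -> pd.DataFrame:
    """Quiet-standing breath table at the standing gross rate."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 47]))
    t = np.arange(0.0, duration, breath_period)
    w = STANDING_W_PER_KG * subject.mass * (1.0 + rng.normal(0, 0.02, size=t.shape))
    vo2, vco2 = _gas_from_gross_watts(w)
    return pd.DataFrame({"t": t, "vo2_ml_min": vo2, "vco2_ml_min": vco2})


# ---------------------------------------------------------------------------
# aerobic-fitness dataset


def generate_fitness_dataset(
    n: int,
    quad_coeffs: tuple[float, float] = (-0.018, 0.001),
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Table (vo2peak, vo2peak_centered, delta_sla, gender) with
    delta_sla = tilt*x + convexity*x^2 + eps on the gender-centered scale."""
    if n < 3:
        raise ValueError("need n >= 3 subjects")
    tilt, convexity = quad_coeffs
    rng = np.random.default_rng(np.random.SeedSequence([seed, 53]))
    gender = np.where(np.arange(n) % 2 == 0, "woman", "man")
    vo2 = np.clip(rng.normal(40.0, 6.0, size=n), 22.0, 60.0)
    df = pd.DataFrame({"subject": [f"S{i+1:02d}" for i in range(n)],
                       "vo2peak": vo2, "gender": gender})
    df["vo2peak_centered"] = df["vo2peak"] - df.groupby("gender")["vo2peak"].transform("mean")
    x = df["vo2peak_centered"].to_numpy()
    df["delta_sla"] = tilt * x + convexity * x**2 + rng.normal(0.0, noise_sd, size=n)
    return df
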