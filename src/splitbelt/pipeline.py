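"""End-to-end orchestration: simulate -> preprocess -> metrics -> fits ->
epochs -> regressions -> reports.

`process_trial` turns one raw signal-level trial into per-stride metrics
(step lengths, SLA, ML MoS, work rates) and a per-breath energetics table.
`run_pipeline` runs the full analysis on a synthetic cohort: dual- vs
single-rate mixed fits per measure (AIC-selected), epoch interaction models,
and the aerobic-fitness sub-analysis, writing tables and JSON reports.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import energetics, preprocess, spatiotemporal, stability
from .adaptation_fit import fit_and_select
from .io import RunConfig, write_report, write_table
from .model import CohortConfig
from .phases import (build_epochs, fitness_regression, interaction_lmm,
                     metabolic_lag_regression)
from .synth import GaitTrial, generate_cohort, generate_standing_breaths

log = logging.getLogger("splitbelt")

__all__ = ["process_trial", "run_pipeline", "fitness_records"]


def process_trial(trial: GaitTrial, config: RunConfig | None = None) -> dict:
    """Process one raw trial into stride metrics and breath energetics.

    Returns dict with 'strides' (per-stride step lengths, SLA, MoS in cm,
    work rates in W), 'breaths' (per-breath energetics) and intermediate
    streams ('cop_ml', 'com_ml', 'xcom_ml') for debugging.
    """
    if config is None:
        config = RunConfig()
    tm = trial.markers["t"].to_numpy()
    tf = trial.forces["t"].to_numpy()

    km = {c: preprocess.lowpass_zerophase(trial.markers[c].to_numpy(),
                                          trial.marker_rate, config.kinematic_cutoff)
          for c in trial.markers.columns if c != "t"}
    ff = {c: preprocess.lowpass_zerophase(trial.forces[c].to_numpy(),
                                          trial.force_rate, config.force_cutoff)
          for c in trial.forces.columns if c != "t"}

    events = preprocess.detect_gait_events(tf, ff["fast_Fz"], ff["slow_Fz"],
                                           config.force_threshold)
    strides = preprocess.segment_strides(events, reference_leg="fast")
    valid = [s for s in strides if s.valid]

    # spatiotemporal: fast leg is the left leg in the synthetic lab frame
    steps = spatiotemporal.step_lengths(tm, km["ankle_L_x"], km["ankle_R_x"], events)
    sla_df = spatiotemporal.sla_series(steps)

    # stability
    cop = stability.combined_cop_ml(
        np.column_stack([ff["fast_Fz"], ff["slow_Fz"]]),
        np.column_stack([ff["fast_Mx"], ff["slow_Mx"]]),
        trial.plate_offsets_ml, trial.force_rate)
    f_ml = ff["fast_Fy"] + ff["slow_Fy"]
    com, vcom = stability.com_ml_absolute(f_ml, trial.subject.mass, cop,
                                          trial.force_rate, config.drift_cutoff)
    xc = stability.xcom(com, vcom, trial.subject.leg_length)
    bos_fast = np.interp(tf, tm, km["ankle_L_y"])
    bos_slow = np.interp(tf, tm, km["ankle_R_y"])
    mos = stability.mos_per_stride(tf, xc, bos_fast, bos_slow, events, fast_side="left")

    # mechanical work
    grf_fast = np.column_stack([ff["fast_Fx"], ff["fast_Fy"], ff["fast_Fz"]])
    grf_slow = np.column_stack([ff["slow_Fx"], ff["slow_Fy"], ff["slow_Fz"]])
    v_com3 = energetics.com_velocity_3d(tf, grf_fast + grf_slow,
                                        trial.subject.mass, valid)
    work = energetics.leg_power_and_work(tf, grf_fast, grf_slow, v_com3,
                                         config.belt_speeds, valid)

    # merge per-stride tables on the stride's fast-strike time
    stride_df = pd.DataFrame({
        "t": [s.start for s in valid],
        "duration": [s.duration for s in valid],
    })
    stride_df = pd.merge_asof(stride_df, sla_df, on="t", direction="backward",
                              tolerance=config.stride_period / 2)
    mos_t = mos.rename(columns={"t_fast": "t"})[["t", "mos_fast", "mos_slow"]]
    stride_df = pd.merge_asof(stride_df, mos_t, on="t", direction="forward",
                              tolerance=config.stride_period)
    stride_df = stride_df.merge(work.drop(columns=["duration", "stride"]), on="t",
                                how="left")

    standing = generate_standing_breaths(trial.subject, seed=config.seed)
    breaths = energetics.breath_table(trial.breaths, standing, trial.subject.mass)

    return {"strides": stride_df, "breaths": breaths,
            "cop_ml": cop, "com_ml": com, "xcom_ml": xc, "events": events}


def _trim_metabolic(series: pd.DataFrame) -> pd.DataFrame:
    """Apply the onset-transient removal rule per subject."""
    import warnings

    from .energetics import remove_onset_transient

    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for subj, grp in series.groupby("subject"):
            t, w = remove_onset_transient(grp["t"].to_numpy(), grp["value"].to_numpy())
            frames.append(pd.DataFrame({"subject": subj, "t": t, "value": w}))
    return pd.concat(frames, ignore_index=True)


def _cohort_stride_metrics(cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide per-stride and per-breath tables from a measure-level cohort."""
    wide = cohort.data[cohort.data["measure"] != "metabolic_rate"].pivot_table(
        index=["subject", "t"], columns="measure", values="value").reset_index()
    wide = wide.rename(columns={"work_net": "w_net"})
    met = cohort.data[cohort.data["measure"] == "metabolic_rate"]
    met = met.rename(columns={"value": "w_net_metabolic"})[
        ["subject", "t", "w_net_metabolic"]]
    return wide, met


def fitness_records(stride_metrics: pd.DataFrame, breath_metrics: pd.DataFrame,
                    subjects, r_f: float, lag: float = 180.0) -> pd.DataFrame:
    """Per-subject adaptation changes for the aerobic-fitness analysis:
    late mean (last 2 min) minus initial mean ([0, r_f]; metabolic windows
    shifted by the lag)."""
    rows = []
    dur = stride_metrics["t"].max()
    for subj in subjects:
        s = stride_metrics[stride_metrics["subject"] == subj.id]
        m = breath_metrics[breath_metrics["subject"] == subj.id]
        sla_init = s.loc[s["t"] <= r_f, "sla"].mean()
        sla_late = s.loc[s["t"] >= dur - 120.0, "sla"].mean()
        met_init = m.loc[(m["t"] >= lag) & (m["t"] <= lag + r_f),
                         "w_net_metabolic"].mean()
        met_late = m.loc[m["t"] >= dur - 120.0, "w_net_metabolic"].mean()
        rows.append({"subject": subj.id, "vo2peak": subj.vo2peak,
                     "gender": subj.gender,
                     "delta_sla": sla_late - sla_init,
                     "delta_metabolic": met_late - met_init})
    df = pd.DataFrame(rows)
    df["vo2peak_centered"] = (df["vo2peak"]
                              - df.groupby("gender")["vo2peak"].transform("mean"))
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Full analysis on a synthetic cohort; returns and writes the report bundle."""
    out = Path(config.out_dir)
    cohort_cfg = CohortConfig(
        n_subjects=config.n_subjects, duration=config.duration, seed=config.seed,
        stride_period=config.stride_period, breath_period=config.breath_period,
        belt_speeds=config.belt_speeds,
    )
    log.info("simulating cohort: n=%d, duration=%.0f s, seed=%d",
             config.n_subjects, config.duration, config.seed)
    cohort = generate_cohort(cohort_cfg, measures=list(config.measures))
    stride_metrics, breath_metrics = _cohort_stride_metrics(cohort)

    fits = {}
    for measure in config.measures:
        log.info("fitting adaptation models: %s", measure)
        series = cohort.series(measure)
        if measure == "metabolic_rate":
            series = _trim_metabolic(series)
        selected, single, dual = fit_and_select(series)
        fits[measure] = {
            "selected": "dual" if selected.n_components == 2 else "single",
            "delta_aic": dual.aic - single.aic,
            "single": _fit_summary(single),
            "dual": _fit_summary(dual),
        }

    r_f = fits["sla"]["dual"]["r_f"] if "sla" in fits else 23.0
    report: dict = {"config": dataclasses.asdict(config), "fits": fits,
                    "sla_r_f": r_f}

    if {"sla", "mos_fast", "mos_slow", "work_net"} <= set(config.measures):
        epochs = build_epochs(stride_metrics, breath_metrics, r_f=r_f,
                              lag=config.metabolic_lag, bin_s=config.epoch_bin)
        regressions = {
            p: interaction_lmm(epochs, predictor=p)
            for p in ("mos_fast", "mos_slow", "w_net")
        }
        if "metabolic_rate" in config.measures:
            regressions["metabolic"] = metabolic_lag_regression(epochs)
        report["epoch_regressions"] = {k: dataclasses.asdict(v)
                                       for k, v in regressions.items()}
        recs = fitness_records(stride_metrics, breath_metrics, cohort.subjects,
                               r_f=r_f, lag=config.metabolic_lag)
        fitness = {o: fitness_regression(recs, outcome=o)
                   for o in ("delta_sla", "delta_metabolic")}
        report["fitness"] = {
            k: {kk: vv for kk, vv in dataclasses.asdict(v).items() if kk != "table"}
            for k, v in fitness.items()}
        epochs_out = epochs.copy()
        for c in ("sla", "mos_fast", "mos_slow", "w_net", "w_net_metabolic"):
            if c not in epochs_out.columns:
                epochs_out[c] = np.nan
        write_table(epochs_out, out / "epochs.csv", "epochs")
        write_table(recs.assign(), out / "fitness.csv", "fitness")

    write_table(cohort.data, out / "measures.csv", "measures")
    # curve data on a 1-s grid for each fitted measure (adaptation-curve export)
    grid = np.arange(0.0, config.duration, 1.0)
    curves = {}
    for measure in config.measures:
        which = fits[measure]["selected"]
        p = fits[measure][which]
        from .model import AdaptationParams
        ap = AdaptationParams(
            c=p["c"], a_f=p["a_f"], r_f=p["r_f"],
            a_s=p.get("a_s", 0.0) or 0.0, r_s=p.get("r_s") or np.inf,
            n_components=2 if which == "dual" else 1)
        curves[measure] = ap.curve(grid).tolist()
    write_report({"t": grid.tolist(), "curves": curves}, out / "curves.json")
    write_report(report, out / "report.json")
    log.info("report written to %s", out / "report.json")
    return report


def _fit_summary(fit) -> dict:
    p = fit.params
    d = {"c": p.c, "a_f": p.a_f, "r_f": p.r_f, "sigma_b": fit.sigma_b,
         "sigma": fit.sigma, "loglik": fit.loglik, "aic": fit.aic,
         "converged": fit.converged, "boundary": fit.boundary,
         "se": fit.se}
    if p.n_components == 2:
        d["a_s"] = p.a_s
        d["r_s"] = p.r_s
    return d
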