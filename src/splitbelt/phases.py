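"""Initial/later adaptation epochs and the regressions across them.

The initial epoch spans the first r_f seconds of adaptation (r_f taken from
the SLA dual-rate fit), the later epoch minutes 15-17 for biomechanics.
Metabolic data lag gait mechanics, so their windows are shifted by a 3-min
lag: initial [lag, lag + r_f], later minutes 18-20.  Within each window every
measure is averaged over 3-s bins (5-s available via the bin argument); a
partial trailing bin is kept when it covers at least half the bin width.

Epoch x predictor interactions on SLA are tested with linear mixed models
(random intercept per subject, exact ML); per-epoch simple slopes are reported
with Wald tests on Satterthwaite-style degrees of freedom plus a
likelihood-ratio test of the interaction.  The aerobic-fitness sub-analysis
regresses the change in SLA (and in net metabolic rate) on gender-centered
VO2 peak with OLS, comparing linear against quadratic shapes by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import fit_linear_mixed

__all__ = [
    "build_epochs",
    "interaction_lmm",
    "metabolic_lag_regression",
    "fitness_regression",
    "InteractionResult",
    "FitnessResult",
]

LATER_BIOMECH_WINDOW = (900.0, 1020.0)  # minutes 15-17
LATER_METABOLIC_WINDOW = (1080.0, 1200.0)  # minutes 18-20
DEFAULT_LAG_S = 180.0
DEFAULT_BIN_S = 3.0


def _bin_window(df: pd.DataFrame, cols, start: float, stop: float,
                bin_s: float, origin: float) -> pd.DataFrame:
    """Per-subject bin means over [start, stop); bin times are reported
    relative to ``origin`` (so lagged metabolic bins align with biomechanics).
    Partial trailing bins are kept if they cover >= half a bin."""
    sel = df[(df["t"] >= start) & (df["t"] < stop)]
    if sel.empty:
        return pd.DataFrame(columns=["subject", "bin", "bin_mid", *cols])
    n_full, rem = divmod(stop - start, bin_s)
    n_bins = int(n_full) + (1 if rem >= bin_s / 2.0 - 1e-9 and rem > 1e-9 else 0)
    idx = np.floor((sel["t"] - start) / bin_s).astype(int)
    sel = sel.assign(bin=idx)
    sel = sel[sel["bin"] < n_bins]
    out = sel.groupby(["subject", "bin"], as_index=False)[list(cols)].mean()
    edges = start + out["bin"] * bin_s
    width = np.minimum(edges + bin_s, stop) - edges
    out["bin_mid"] = edges + width / 2.0 - origin
    return out


def build_epochs(stride_metrics: pd.DataFrame, breath_metrics: pd.DataFrame,
                 r_f: float, lag: float = DEFAULT_LAG_S,
                 bin_s: float = DEFAULT_BIN_S) -> pd.DataFrame:
    """Binned initial/later epoch dataset.

    ``stride_metrics``: long table (subject, t, sla, mos_fast, mos_slow,
    w_net); ``breath_metrics``: (subject, t, w_net_metabolic).  The metabolic
    windows are shifted by ``lag`` and their bin times mapped back onto the
    biomechanics clock, so with lag=0 the two sets of bin times coincide.
    """
    if r_f >= stride_metrics["t"].max():
        raise ValueError("r_f exceeds the trial duration")
    bio_cols = [c for c in ("sla", "mos_fast", "mos_slow", "w_net")
                if c in stride_metrics.columns]
    frames = []
    windows = {
        "initial": ((0.0, r_f), (lag, lag + r_f)),
        "later": (LATER_BIOMECH_WINDOW, LATER_METABOLIC_WINDOW),
    }
    for epoch, (bio_w, met_w) in windows.items():
        bio = _bin_window(stride_metrics, bio_cols, *bio_w, bin_s, origin=bio_w[0])
        met = _bin_window(breath_metrics, ["w_net_metabolic"], *met_w, bin_s,
                          origin=met_w[0]).drop(columns=["bin_mid"])
        merged = bio.merge(met, on=["subject", "bin"], how="left")
        merged.insert(1, "epoch", epoch)
        merged["bin_mid"] += bio_w[0]
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)


@dataclass
class InteractionResult:
    """Epoch x predictor mixed-model summary."""

    predictor: str
    outcome: str
    coef: dict[str, float]
    se: dict[str, float]
    interaction_F: float
    interaction_df: tuple[float, float]
    interaction_p: float
    interaction_p_lrt: float
    slope_initial: float
    slope_initial_p: float
    slope_later: float
    slope_later_p: float
    sigma_b: float
    sigma: float
    loglik: float
    n_obs: int = 0


def _wald_p(est: float, var: float, df: float) -> float:
    if var <= 0:
        return np.nan
    return float(2.0 * stats.t.sf(abs(est) / np.sqrt(var), df))


def interaction_lmm(dataset: pd.DataFrame, predictor: str,
                    outcome: str = "sla") -> InteractionResult:
    """outcome ~ predictor * epoch with a per-subject random intercept (ML).

    Reports the interaction Wald F (Satterthwaite-style denominator df) and
    likelihood-ratio test, plus simple slopes within each epoch.
    """
    df = dataset.dropna(subset=[predictor, outcome]).copy()
    if df["epoch"].nunique() < 2:
        raise ValueError("both epochs are required for an interaction model")
    later = (df["epoch"] == "later").astype(float).to_numpy()
    x = df[predictor].to_numpy(float)
    y = df[outcome].to_numpy(float)
    X = np.column_stack([np.ones_like(x), x, later, x * later])
    names = ["intercept", predictor, "later", f"{predictor}:later"]
    fit = fit_linear_mixed(X, y, df["subject"].to_numpy(), names=names)

    # interaction test: Wald with Satterthwaite df, and LRT against the
    # no-interaction model
    L = np.array([0.0, 0.0, 0.0, 1.0])
    v = fit.contrast_variance(L)
    ddf = fit.satterthwaite_df(L)
    F = fit.beta[3] ** 2 / v if v > 0 else np.nan
    p_wald = float(stats.f.sf(F, 1, ddf)) if np.isfinite(F) else np.nan
    fit0 = fit_linear_mixed(X[:, :3], y, df["subject"].to_numpy())
    lrt = 2.0 * (fit.loglik - fit0.loglik)
    p_lrt = float(stats.chi2.sf(max(lrt, 0.0), 1))

    L_init = np.array([0.0, 1.0, 0.0, 0.0])
    L_later = np.array([0.0, 1.0, 0.0, 1.0])
    slope_i = float(fit.beta @ L_init)
    slope_l = float(fit.beta @ L_later)
    p_i = _wald_p(slope_i, fit.contrast_variance(L_init), fit.satterthwaite_df(L_init))
    p_l = _wald_p(slope_l, fit.contrast_variance(L_later), fit.satterthwaite_df(L_later))

    return InteractionResult(
        predictor=predictor, outcome=outcome,
        coef=dict(zip(names, map(float, fit.beta))),
        se=dict(zip(names, map(float, fit.se()))),
        interaction_F=float(F), interaction_df=(1.0, float(ddf)),
        interaction_p=p_wald, interaction_p_lrt=p_lrt,
        slope_initial=slope_i, slope_initial_p=p_i,
        slope_later=slope_l, slope_later_p=p_l,
        sigma_b=float(np.sqrt(fit.sigma_b2)), sigma=float(np.sqrt(fit.sigma2)),
        loglik=float(fit.loglik), n_obs=len(y),
    )


def metabolic_lag_regression(dataset: pd.DataFrame) -> InteractionResult:
    """Epoch x SLA interaction on the (lagged) net metabolic rate."""
    return interaction_lmm(dataset, predictor="sla", outcome="w_net_metabolic")


@dataclass
class FitnessResult:
    """Aerobic-fitness OLS sub-analysis for one adaptation outcome."""

    outcome: str
    model: str  # "linear" | "quadratic"
    gender_covariate: bool
    coef: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    aic_table: dict[str, float]
    vertex_centered: float | None = None
    vertex_raw: float | None = None
    table: pd.DataFrame | None = field(default=None, repr=False)


def fitness_regression(records: pd.DataFrame, outcome: str = "delta_sla",
                       aic_gender_threshold: float = -2.0) -> FitnessResult:
    """Linear-vs-quadratic OLS of an adaptation change on gender-centered
    VO2 peak.

    VO2 peak is centered within gender; the gender covariate is retained only
    if it improves AIC by more than ``aic_gender_threshold``; linear vs
    quadratic is likewise decided by AIC.  If the selected model is quadratic
    with positive convexity, the vertex (minimum-adaptation fitness level) is
    reported on the centered and raw scales.
    """
    import statsmodels.api as sm

    df = records.dropna(subset=[outcome, "vo2peak", "gender"]).copy()
    if len(df) < 4:
        raise ValueError("need at least 4 subjects")
    if df["vo2peak"].nunique() < 2:
        raise ValueError("degenerate design: all vo2peak values equal")
    if "vo2peak_centered" not in df.columns:
        df["vo2peak_centered"] = (
            df["vo2peak"] - df.groupby("gender")["vo2peak"].transform("mean"))
    x = df["vo2peak_centered"].to_numpy()
    y = df[outcome].to_numpy(float)
    man = (df["gender"] == "man").astype(float).to_numpy()

    def fit(quadratic: bool, gender: bool):
        cols = [np.ones_like(x), x]
        names = ["intercept", "tilt"]
        if quadratic:
            cols.append(x**2)
            names.append("convexity")
        if gender:
            cols.append(man)
            names.append("gender_man")
        res = sm.OLS(y, np.column_stack(cols)).fit()
        return res, names

    fits = {(q, g): fit(q, g) for q in (False, True) for g in (False, True)}
    aics = {k: v[0].aic for k, v in fits.items()}
    keep_gender = {
        q: aics[(q, True)] - aics[(q, False)] < aic_gender_threshold
        for q in (False, True)
    }
    cand = {q: (q, keep_gender[q]) for q in (False, True)}
    quadratic = aics[cand[True]] < aics[cand[False]]
    key = cand[quadratic]
    res, names = fits[key]
    coef = dict(zip(names, map(float, res.params)))
    pvals = dict(zip(names, map(float, res.pvalues)))

    vertex_c = vertex_raw = None
    if quadratic and coef.get("convexity", 0.0) > 0:
        vertex_c = -coef["tilt"] / (2.0 * coef["convexity"])
        vertex_raw = vertex_c + float(df["vo2peak"].mean())
    return FitnessResult(
        outcome=outcome,
        model="quadratic" if quadratic else "linear",
        gender_covariate=key[1],
        coef=coef, pvalues=pvals,
        r_squared=float(res.rsquared),
        aic_table={f"{'quad' if q else 'lin'}{'+gender' if g else ''}": float(a)
                   for (q, g), a in aics.items()},
        vertex_centered=vertex_c, vertex_raw=vertex_raw, table=df,
    )
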