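"""Dual-rate exponential mixed-effects adaptation fits.

Fits y(t) = c + a_f exp(-t/r_f) [+ a_s exp(-t/r_s)] to a cohort of per-subject
series by exact marginal maximum likelihood, with a Gaussian random plateau
per subject (see :mod:`splitbelt.mixedlm`).  Time constants are optimized on
the log scale, and the dual-rate model is parameterized by log r_f and
log(r_s - r_f) so the ordering r_f < r_s holds by construction (no label
switching).  Single- vs dual-rate selection is by AIC, ties going to the model
with fewer parameters.

Also provides the simulation-based minimum-sample-size heuristic: simulate
cohorts of increasing size from known parameters and find the smallest N at
which the spread of the time-constant estimation errors from sizes N..N_max
falls to half the spread seen below N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .mixedlm import GroupedData, full_negloglik, numeric_hessian, profile_loglik
from .model import AdaptationParams, dual_rate_curve

__all__ = [
    "ExpFitResult",
    "fit_exponential_mixed",
    "fit_and_select",
    "compare_models",
    "predict_curve",
    "stable_sample_size",
    "sample_size_simulation",
]


@dataclass
class ExpFitResult:
    """Mixed-effects exponential fit: estimates, SEs, likelihood, diagnostics."""

    params: AdaptationParams
    se: dict[str, float]
    sigma_b: float  # random-plateau SD
    sigma: float  # residual SD
    loglik: float
    n_components: int
    k_params: int
    converged: bool
    boundary: bool  # second component collapsed (dual fit of single-rate data)
    n_obs: int = 0
    n_subjects: int = 0
    message: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.loglik


def _design(t: np.ndarray, r_f: float, r_s: float | None) -> np.ndarray:
    cols = [np.ones_like(t), np.exp(-t / r_f)]
    if r_s is not None:
        cols.append(np.exp(-t / r_s))
    return np.column_stack(cols)


def _theta_to_rates(theta, dual: bool):
    if dual:
        r_f = np.exp(theta[0])
        return r_f, r_f + np.exp(theta[1]), np.exp(theta[-1])
    return np.exp(theta[0]), None, np.exp(theta[-1])


def _neg_profile(theta, data: GroupedData, dual: bool) -> float:
    r_f, r_s, lam = _theta_to_rates(theta, dual)
    if not np.isfinite(r_f) or (dual and not np.isfinite(r_s)):
        return 1e12
    try:
        ll, *_ = profile_loglik(data, _design(data.t, r_f, r_s), lam)
    except np.linalg.LinAlgError:
        return 1e12
    return -ll if np.isfinite(ll) else 1e12


def _grid_starts(data: GroupedData, dual: bool) -> list[np.ndarray]:
    """Deterministic starts: log-spaced 8x8 time-constant grid ranked by OLS
    residual sum of squares, then a moment estimate of lam."""
    span = data.t.max() - data.t.min()
    rs = np.geomspace(max(2.0, span / 400.0), span / 2.0, 8)
    best, best_ss = None, np.inf
    if dual:
        cand = [(rf, rsl) for rf in rs for rsl in rs if rsl > 1.5 * rf]
    else:
        cand = [(r, None) for r in rs]
    for rf, rsl in cand:
        X = _design(data.t, rf, rsl)
        beta, res, *_ = np.linalg.lstsq(X, data.y, rcond=None)
        r = data.y - X @ beta
        ss = float(r @ r)
        if ss < best_ss:
            best, best_ss = (rf, rsl), ss
    rf, rsl = best
    X = _design(data.t, rf, rsl)
    beta, *_ = np.linalg.lstsq(X, data.y, rcond=None)
    resid = data.y - X @ beta
    gm = np.array([resid[sl].mean() for sl in data.group_slices()])
    s2 = float(resid.var())
    lam0 = max(float(gm.var()) / max(s2, 1e-12), 1e-4)
    if dual:
        start = np.array([np.log(rf), np.log(rsl - rf), np.log(lam0)])
    else:
        start = np.array([np.log(rf), np.log(lam0)])
    return [start]


def fit_exponential_mixed(series: pd.DataFrame, n_components: int = 2,
                          extra_starts: list | None = None) -> ExpFitResult:
    """Fit the single- or dual-rate mixed model to a cohort.

    ``series`` is a long table with columns subject, t, value (one row per
    stride or breath).  Returns the exact marginal-ML fit; non-convergence is
    reported in the result, never silently.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    data = GroupedData(series["t"].to_numpy(), series["value"].to_numpy(),
                       series["subject"].to_numpy())
    dual = n_components == 2
    starts = _grid_starts(data, dual)
    if extra_starts:
        starts += [np.asarray(s, float) for s in extra_starts]

    best = None
    for x0 in starts:
        res = minimize(_neg_profile, x0, args=(data, dual), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000,
                                "maxfev": 4000})
        if best is None or res.fun < best.fun:
            best = res
    r_f, r_s, lam = _theta_to_rates(best.x, dual)
    X = _design(data.t, r_f, r_s)
    ll, beta, sigma2, sigma_b2 = profile_loglik(data, X, lam)
    # boundary: no between-subject variance improves the likelihood
    ll0, beta0, sigma2_0, _ = profile_loglik(data, X, 0.0)
    if ll0 >= ll:
        lam, ll, beta, sigma2, sigma_b2 = 0.0, ll0, beta0, sigma2_0, 0.0

    if dual:
        params = AdaptationParams(c=beta[0], a_f=beta[1], r_f=r_f,
                                  a_s=beta[2], r_s=r_s, n_components=2)
        boundary = (r_s - r_f) < 0.05 * r_f or abs(beta[2]) < 0.02 * max(
            abs(beta[1]), np.sqrt(sigma2))
    else:
        params = AdaptationParams(c=beta[0], a_f=beta[1], r_f=r_f, n_components=1)
        boundary = False
    k = (5 if not dual else 7) if lam > 0 else (4 if not dual else 6)
    se = _standard_errors(data, beta, r_f, r_s, lam, sigma2, dual)
    return ExpFitResult(
        params=params, se=se, sigma_b=float(np.sqrt(sigma_b2)),
        sigma=float(np.sqrt(sigma2)), loglik=float(ll), n_components=n_components,
        k_params=k, converged=bool(best.success), boundary=bool(boundary),
        n_obs=data.n, n_subjects=data.n_groups, message=best.message,
    )


def _standard_errors(data, beta, r_f, r_s, lam, sigma2, dual) -> dict[str, float]:
    """Delta-method SEs from the numeric Hessian of the full log-likelihood,
    with time constants and variance parameters on the log scale."""
    use_lam = lam > 1e-8
    if dual:
        phi = [beta[0], beta[1], beta[2], np.log(r_f), np.log(r_s - r_f)]
    else:
        phi = [beta[0], beta[1], np.log(r_f)]
    if use_lam:
        phi.append(np.log(lam))
    phi.append(np.log(sigma2))
    phi = np.array(phi)
    nb = 3 if dual else 2

    def nll(p):
        b = p[:nb]
        rf = np.exp(p[nb])
        rs = rf + np.exp(p[nb + 1]) if dual else None
        la = np.exp(p[-2]) if use_lam else 0.0
        s2 = np.exp(p[-1])
        return full_negloglik(data, _design(data.t, rf, rs), b, la, s2)

    try:
        H = numeric_hessian(nll, phi)
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return {}
    se = {}
    names = (["c", "a_f", "a_s"] if dual else ["c", "a_f"])
    for i, nm in enumerate(names):
        se[nm] = float(np.sqrt(max(cov[i, i], 0.0)))
    i_rf = nb
    se["r_f"] = float(r_f * np.sqrt(max(cov[i_rf, i_rf], 0.0)))
    if dual:
        # r_s = exp(u) + exp(w): gradient (r_f, r_s - r_f)
        g = np.zeros(phi.size)
        g[i_rf], g[i_rf + 1] = r_f, r_s - r_f
        se["r_s"] = float(np.sqrt(max(g @ cov @ g, 0.0)))
    return se


def fit_and_select(series: pd.DataFrame) -> tuple[ExpFitResult, ExpFitResult, ExpFitResult]:
    """Fit both the single- and dual-rate models and select by AIC.

    The dual fit is additionally started from the single-rate solution (second
    component seeded at a nearby time constant), which guarantees its
    log-likelihood is at least the single model's.  Returns
    (selected, single_fit, dual_fit).
    """
    single = fit_exponential_mixed(series, n_components=1)
    lam1 = max((single.sigma_b / single.sigma) ** 2, 1e-4)
    embed = [np.log(single.params.r_f), np.log(0.8 * single.params.r_f), np.log(lam1)]
    dual = fit_exponential_mixed(series, n_components=2, extra_starts=[embed])
    selected, _ = compare_models(single, dual)
    return selected, single, dual


def compare_models(fit1: ExpFitResult, fit2: ExpFitResult) -> tuple[ExpFitResult, float]:
    """AIC model selection: returns (winner, delta_aic = AIC2 - AIC1).

    Lower AIC wins; within numerical tie (1e-9) the model with fewer
    parameters is preferred.
    """
    d = fit2.aic - fit1.aic
    if abs(d) < 1e-9:
        return (fit1 if fit1.k_params <= fit2.k_params else fit2), d
    return (fit1 if d > 0 else fit2), d


def predict_curve(params: AdaptationParams, t) -> np.ndarray:
    """Evaluate the fitted adaptation curve on a time grid."""
    return dual_rate_curve(np.asarray(t, float), params)


# ---------------------------------------------------------------------------
# sample-size heuristic


@dataclass
class SampleSizeResult:
    n_selected: int
    criterion_met: bool
    table: pd.DataFrame = field(repr=False)


def stable_sample_size(n_values, diffs_per_n) -> tuple[int, bool]:
    """Smallest N whose tail spread halves relative to the head.

    ``diffs_per_n`` holds, per candidate size N, the estimation errors
    (estimate - truth); the rule selects the smallest N such that the SD of
    all errors from sizes N..N_max is <= half the SD of all errors from sizes
    below N.  If never met, returns (N_max, False).
    """
    n_values = list(n_values)
    pools = [np.atleast_1d(np.asarray(d, float)) for d in diffs_per_n]
    for i in range(1, len(n_values)):
        before = np.concatenate(pools[:i])
        after = np.concatenate(pools[i:])
        if before.size < 2 or after.size < 2:
            continue
        if after.std(ddof=1) <= 0.5 * before.std(ddof=1):
            return n_values[i], True
    return n_values[-1], False


def sample_size_simulation(truth: AdaptationParams, measure: str,
                           n_range, reps: int, seed: int,
                           duration: float = 1200.0,
                           config_kwargs: dict | None = None) -> SampleSizeResult:
    """Simulate cohorts across sample sizes, refit, and apply the stability
    rule to the fast and slow time-constant errors."""
    from .model import CohortConfig
    from .synth import generate_cohort

    n_range = sorted(n_range)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows, diffs_per_n = [], []
    for j, n in enumerate(n_range):
        diffs = []
        for rep in range(reps):
            cfg = CohortConfig(n_subjects=n, duration=duration,
                               seed=seed + 1000 * j + rep,
                               **(config_kwargs or {}))
            cohort = generate_cohort(cfg, truth={measure: truth}, measures=[measure])
            fit = fit_exponential_mixed(cohort.series(measure),
                                        n_components=truth.n_components)
            diffs.append(fit.params.r_f - truth.r_f)
            if truth.n_components == 2:
                diffs.append(fit.params.r_s - truth.r_s)
        diffs_per_n.append(np.array(diffs))
        rows.append({"n": n, "sd_diff": float(np.std(diffs, ddof=1)) if len(diffs) > 1
                     else 0.0})
    n_sel, met = stable_sample_size(n_range, diffs_per_n)
    return SampleSizeResult(n_selected=n_sel, criterion_met=met,
                            table=pd.DataFrame(rows))
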