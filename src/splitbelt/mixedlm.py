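"""Gaussian random-intercept mixed models by exact marginal maximum likelihood.

Both the nonlinear adaptation fits and the linear epoch-interaction models in
this package share one random-effects structure: a subject-level random
intercept (the "random plateau") with i.i.d. Gaussian residuals,

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sb^2),  e_ij ~ N(0, s^2).

Because the random effect enters linearly, the marginal covariance per subject
is compound-symmetric, V_i = s^2 (I + lam J) with lam = sb^2 / s^2, and the
marginal likelihood is available in closed form: no Laplace or quadrature
approximation is needed.  Given lam (and, for the nonlinear model, the time
constants defining the design matrix), beta is profiled by GLS and s^2 by its
closed-form ML estimate, leaving a 1-3 dimensional smooth optimization.

Standard errors come from the numerically differentiated Hessian of the full
(unprofiled) log-likelihood.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GroupedData",
    "profile_loglik",
    "gls_beta",
    "full_negloglik",
    "numeric_hessian",
    "fit_linear_mixed",
]


class GroupedData:
    """y values grouped by subject with per-group index bounds (sorted once)."""

    def __init__(self, t: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.t = np.asarray(t, float)[order]
        self.y = np.asarray(y, float)[order]
        g = np.asarray(groups)[order]
        _, starts, counts = np.unique(g, return_index=True, return_counts=True)
        self.starts = starts
        self.counts = counts
        self.n = self.y.size
        self.n_groups = starts.size
        self.group_labels = g[starts]

    def group_slices(self):
        for s, c in zip(self.starts, self.counts):
            yield slice(s, s + c)


def _cs_weights(counts: np.ndarray, lam: float) -> np.ndarray:
    """Per-group shrinkage weight w_i = lam / (1 + n_i lam) for the
    compound-symmetry inverse V^-1 = I - w J (up to the s^2 scale)."""
    return lam / (1.0 + counts * lam)


def gls_beta(data: GroupedData, X: np.ndarray, lam: float):
    """GLS estimate of beta under compound symmetry, plus the ML residual
    quadratic form and the (unscaled) normal-equations matrix."""
    w = _cs_weights(data.counts, lam)
    XtX = X.T @ X
    Xty = X.T @ data.y
    for sl, wi in zip(data.group_slices(), w):
        sx = X[sl].sum(axis=0)
        sy = data.y[sl].sum()
        XtX -= wi * np.outer(sx, sx)
        Xty -= wi * sx * sy
    beta = np.linalg.solve(XtX, Xty)
    r = data.y - X @ beta
    qform = float(r @ r)
    for sl, wi in zip(data.group_slices(), w):
        qform -= wi * r[sl].sum() ** 2
    return beta, qform, XtX


def profile_loglik(data: GroupedData, X: np.ndarray, lam: float):
    """Profile log-likelihood over (beta, s^2) for fixed lam and design X.

    Returns (loglik, beta, sigma2, sigma_b2).
    """
    beta, qform, _ = gls_beta(data, X, lam)
    sigma2 = max(qform / data.n, 1e-300)  # guard: exactly noiseless data
    logdet = float(np.log1p(data.counts * lam).sum())
    ll = -0.5 * (data.n * np.log(2.0 * np.pi * sigma2) + logdet + data.n)
    return ll, beta, sigma2, lam * sigma2


def full_negloglik(data: GroupedData, X: np.ndarray, beta: np.ndarray,
                   lam: float, sigma2: float) -> float:
    """Exact negative marginal log-likelihood at an arbitrary parameter point."""
    r = data.y - X @ beta
    w = _cs_weights(data.counts, lam)
    qform = float(r @ r)
    for sl, wi in zip(data.group_slices(), w):
        qform -= wi * r[sl].sum() ** 2
    logdet = float(np.log1p(data.counts * lam).sum())
    return 0.5 * (data.n * np.log(2.0 * np.pi * sigma2) + logdet + qform / sigma2)


def numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    x = np.asarray(x, float)
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * f(x) + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[[i, j]] += [h[i], -h[j]]
                xmp[[i, j]] += [-h[i], h[j]]
                xmm[[i, j]] += [-h[i], -h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


class LinearMixedResult:
    """Linear random-intercept model fit (exact ML)."""

    def __init__(self, beta, cov_beta, sigma2, sigma_b2, loglik, k_params,
                 names, data, X):
        self.beta = beta
        self.cov_beta = cov_beta
        self.sigma2 = sigma2
        self.sigma_b2 = sigma_b2
        self.loglik = loglik
        self.k_params = k_params
        self.names = list(names)
        self._data = data
        self._X = X

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.loglik

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def contrast_variance(self, L: np.ndarray, lam: float | None = None,
                          sigma2: float | None = None) -> float:
        """Var(L'beta) at given (or fitted) variance parameters."""
        lam = self.sigma_b2 / self.sigma2 if lam is None else lam
        sigma2 = self.sigma2 if sigma2 is None else sigma2
        _, _, XtVX = gls_beta(self._data, self._X, lam)
        cov = sigma2 * np.linalg.inv(XtVX)
        return float(L @ cov @ L)

    def satterthwaite_df(self, L: np.ndarray) -> float:
        """Satterthwaite-style denominator degrees of freedom for L'beta.

        df = 2 v^2 / Var(v), with v = Var(L'beta) as a function of the
        variance parameters (log lam, log s^2), their uncertainty taken from
        the numeric Hessian of the marginal likelihood.
        """
        lam = max(self.sigma_b2 / self.sigma2, 1e-10)
        theta = np.log([lam, self.sigma2])

        def nll_theta(th):
            la, s2 = np.exp(th)
            beta, _, _ = gls_beta(self._data, self._X, la)
            return full_negloglik(self._data, self._X, beta, la, s2)

        H = numeric_hessian(nll_theta, theta)
        try:
            C = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return float(self._data.n - self._X.shape[1])

        def v_of(th):
            la, s2 = np.exp(th)
            return self.contrast_variance(L, lam=la, sigma2=s2)

        h = 1e-4 * np.maximum(np.abs(theta), 1.0)
        g = np.array([
            (v_of(theta + dx) - v_of(theta - dx)) / (2 * hi)
            for dx, hi in ((np.eye(2)[i] * h[i], h[i]) for i in range(2))
        ])
        var_v = float(g @ C @ g)
        v = v_of(theta)
        if var_v <= 0:
            return float(self._data.n - self._X.shape[1])
        df = 2.0 * v**2 / var_v
        return float(np.clip(df, 1.0, self._data.n - self._X.shape[1]))


def fit_linear_mixed(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                     names=None) -> LinearMixedResult:
    """Exact-ML linear random-intercept fit, optimizing the 1-D profile over
    log lam (with the boundary lam -> 0 checked explicitly, where the model
    degenerates to OLS)."""
    from scipy.optimize import minimize_scalar

    X = np.asarray(X, float)
    data = GroupedData(np.zeros(len(y)), y, groups)
    # re-sort X rows identically to data ordering
    order = np.argsort(np.asarray(groups), kind="stable")
    X = X[order]

    def neg_profile(log_lam):
        return -profile_loglik(data, X, np.exp(log_lam))[0]

    res = minimize_scalar(neg_profile, bounds=(-15.0, 20.0), method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    ll, beta, sigma2, sigma_b2 = profile_loglik(data, X, lam)
    ll0, beta0, sigma2_0, _ = profile_loglik(data, X, 0.0)
    if ll0 >= ll:  # boundary: no between-subject variance
        lam, ll, beta, sigma2, sigma_b2 = 0.0, ll0, beta0, sigma2_0, 0.0
    _, _, XtVX = gls_beta(data, X, lam)
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    k = X.shape[1] + (2 if lam > 0 else 1)
    if names is None:
        names = [f"b{i}" for i in range(X.shape[1])]
    return LinearMixedResult(beta, cov_beta, sigma2, sigma_b2, ll, k, names, data, X)
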