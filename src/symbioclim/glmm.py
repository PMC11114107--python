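"""Random-intercept logistic regression by marginal maximum likelihood.

The model for host i in location g:

    y_ig ~ Bernoulli(p_ig),   logit(p_ig) = x_ig' beta + u_g,
    u_g ~ N(0, tau^2)  independently across locations.

The random intercept is integrated out of the likelihood per group with
adaptive Gauss-Hermite quadrature centred and scaled at the conditional mode
(one node = the Laplace approximation, the default), and (beta, tau) are
maximized jointly.  Wald standard errors come from the observed information
of the fixed effects at the variance estimate.  AICc counts the
random-intercept variance as one parameter.

This is the engine behind both the coinfection log-odds models and the
candidate-set prevalence models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = ["GlmmFit", "fit_logistic_glmm", "aicc", "wald_ci"]

_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GH_CACHE:
        x, w = np.polynomial.hermite.hermgauss(n)
        _GH_CACHE[n] = (x, w)
    return _GH_CACHE[n]


@dataclass
class GlmmFit:
    """Result of one random-intercept logistic fit."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    tau2: float
    loglik: float
    n: int
    k: int
    aic: float
    aicc: float
    n_groups: int
    converged: bool
    separation_flag: bool
    ranef_modes: dict[str, float] = field(default_factory=dict, repr=False)

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in self.se],
            "tau2": self.tau2,
            "loglik": self.loglik,
            "n": self.n,
            "k": self.k,
            "aic": self.aic,
            "aicc": self.aicc,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
        }


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # log p(y | eta) = y*eta - log(1 + exp(eta)), stable via logaddexp
    return y * eta - np.logaddexp(0.0, eta)


def _group_mode(eta0: np.ndarray, y: np.ndarray, tau2: float,
                u0: float = 0.0) -> tuple[float, float]:
    """Newton mode and curvature of the per-group integrand h(u) =
    sum_i loglik(eta0_i + u) - u^2/(2 tau^2)."""
    u = u0
    for _ in range(50):
        p = special.expit(eta0 + u)
        g = (y - p).sum() - u / tau2
        h = -(p * (1 - p)).sum() - 1.0 / tau2
        step = g / h
        u_new = u - step
        if abs(u_new - u) < 1e-10:
            u = u_new
            break
        u = u_new
    p = special.expit(eta0 + u)
    curv = (p * (1 - p)).sum() + 1.0 / tau2  # -h''(u)
    return float(u), float(curv)


def _marginal_loglik(
    beta: np.ndarray,
    tau: float,
    X: np.ndarray,
    y: np.ndarray,
    group_slices: list[slice],
    n_quad: int,
    modes: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Marginal log-likelihood; also returns per-group modes for warm starts."""
    eta_fix = X @ beta
    if tau < 1e-8:
        ll = _bernoulli_loglik(eta_fix, y).sum()
        return float(ll), np.zeros(len(group_slices))
    tau2 = tau * tau
    nodes, weights = _gh_nodes(n_quad)
    total = 0.0
    out_modes = np.empty(len(group_slices))
    for gi, sl in enumerate(group_slices):
        e0, yg = eta_fix[sl], y[sl]
        u0 = modes[gi] if modes is not None else 0.0
        u_hat, curv = _group_mode(e0, yg, tau2, u0)
        out_modes[gi] = u_hat
        sigma = 1.0 / np.sqrt(curv)
        if n_quad == 1:
            # Laplace: log integral of exp(h(u)) ~ h(u_hat) + 0.5 log(2 pi sigma^2)
            h_hat = _bernoulli_loglik(e0 + u_hat, yg).sum() - u_hat**2 / (2 * tau2)
            log_int = h_hat + 0.5 * np.log(2 * np.pi) + np.log(sigma)
        else:
            u_k = u_hat + np.sqrt(2.0) * sigma * nodes
            h_k = (
                _bernoulli_loglik(e0[:, None] + u_k[None, :], yg[:, None]).sum(axis=0)
                - u_k**2 / (2 * tau2)
            )
            # log( sqrt(2) sigma sum_k w_k exp(x_k^2) exp(h_k) )
            log_terms = np.log(weights) + nodes**2 + h_k
            log_int = special.logsumexp(log_terms) + 0.5 * np.log(2.0) + np.log(sigma)
        total += log_int - 0.5 * np.log(2 * np.pi * tau2)
    return float(total), out_modes


def _start_values(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Penalized ordinary-logistic starting values (ridge keeps separation finite)."""
    beta = np.zeros(X.shape[1])
    for _ in range(25):
        p = special.expit(X @ beta)
        W = p * (1 - p)
        H = X.T @ (X * W[:, None]) + 1e-4 * np.eye(X.shape[1])
        g = X.T @ (y - p) - 1e-4 * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-9:
            break
    return np.clip(beta, -10, 10)


def fit_logistic_glmm(
    frame,
    response: str = "response",
    predictors: list[str] | None = None,
    group: str = "location_id",
    n_quad: int = 1,
    separation_bound: float = 15.0,
    tau_start: float = 0.3,
) -> GlmmFit:
    """Fit ``response ~ predictors + (1 | group)`` with a Bernoulli-logit GLMM.

    Parameters
    ----------
    frame
        DataFrame with the binary response, predictor columns, and the
        grouping column.
    predictors
        Fixed-effect covariate names (intercept always included).  The
        candidate-model analyses cap this at two.
    n_quad
        Adaptive Gauss-Hermite nodes; 1 is the Laplace approximation.
    separation_bound
        |beta| beyond this marks (quasi-)complete separation; the fit is
        still returned, flagged.
    """
    predictors = list(predictors or [])
    y = frame[response].to_numpy(dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("response must be binary 0/1")
    X = np.column_stack(
        [np.ones(len(frame))] + [frame[p].to_numpy(dtype=float) for p in predictors]
    )
    names = ["(Intercept)"] + predictors

    order = np.argsort(frame[group].to_numpy(), kind="stable")
    X, y = X[order], y[order]
    groups = frame[group].to_numpy()[order]
    uniq, starts = np.unique(groups, return_index=True)
    bounds_idx = list(starts) + [len(y)]
    group_slices = [slice(bounds_idx[i], bounds_idx[i + 1]) for i in range(len(uniq))]

    beta0 = _start_values(X, y)
    x0 = np.append(beta0, tau_start)

    def negll(theta: np.ndarray) -> float:
        beta, tau = theta[:-1], theta[-1]
        ll, _ = _marginal_loglik(beta, tau, X, y, group_slices, n_quad)
        return -ll

    bnds = [(-50.0, 50.0)] * X.shape[1] + [(0.0, 10.0)]
    res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bnds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
    # derivative-free polish: finite-difference gradients can stall the
    # quasi-Newton step short of the optimum on nearly flat likelihoods
    polish = optimize.minimize(
        negll, res.x, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
    )
    if polish.fun < res.fun:
        res = polish
    theta = np.asarray(res.x, dtype=float)
    theta[-1] = min(max(theta[-1], 0.0), 10.0)
    beta_hat, tau_hat = theta[:-1], float(theta[-1])
    ll, modes = _marginal_loglik(beta_hat, tau_hat, X, y, group_slices, n_quad)

    # Observed information of the fixed effects at (beta_hat, tau_hat)
    se = _beta_se(beta_hat, tau_hat, X, y, group_slices, n_quad)

    k = X.shape[1] + 1  # fixed effects + random-intercept variance
    n = len(y)
    separation = bool(np.abs(beta_hat).max() >= separation_bound)
    fit = GlmmFit(
        names=names,
        beta=beta_hat,
        se=se,
        tau2=tau_hat**2,
        loglik=ll,
        n=n,
        k=k,
        aic=-2.0 * ll + 2.0 * k,
        aicc=aicc(ll, k, n),
        n_groups=len(uniq),
        converged=bool(res.success),
        separation_flag=separation,
        ranef_modes={str(g): float(m) for g, m in zip(uniq, modes)},
    )
    return fit


def _beta_se(beta, tau, X, y, group_slices, n_quad) -> np.ndarray:
    p = len(beta)
    h = 1e-4 * np.maximum(1.0, np.abs(beta))

    def f(b):
        return _marginal_loglik(b, tau, X, y, group_slices, n_quad)[0]

    H = np.empty((p, p))
    f0 = f(beta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(beta + ei) - 2 * f0 + f(beta - ei)) / (h[i] ** 2)
            else:
                H[i, j] = H[j, i] = (
                    f(beta + ei + ej) - f(beta + ei - ej)
                    - f(beta - ei + ej) + f(beta - ei - ej)
                ) / (4 * h[i] * h[j])
    info = -H
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se


def wald_ci(fit: GlmmFit, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Wald confidence intervals, beta_hat +/- z * se, per coefficient.

    Under separation the interval is unbounded on the escaping side and a
    (-inf, inf) interval is reported for the offending coefficient.
    """
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = {}
    for name, b, s in zip(fit.names, fit.beta, fit.se):
        if fit.separation_flag and abs(b) >= 15.0:
            out[name] = (-np.inf, np.inf)
        else:
            out[name] = (float(b - z * s), float(b + z * s))
    return out
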