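"""AICc candidate-set model selection and residual spatial diagnostics.

For each analysis target (each of the five symbionts, overall symbiosis, and
the hayleyella-Amoebophilus coinfection) the candidate set is every model
with at most two of the six location-level predictors -- the two
predictability windows, soil temperature, C/N, mean annual precipitation and
pH -- plus the intercept-only null: 1 + 6 + C(6,2) = 22 models, each with a
location random intercept.  Models are ranked by AICc; a model is
"informative" when it beats the null by at least 2 AICc units, and the top
set is every model within 2 units of the best.

Spatial autocorrelation of the selected model is checked with Moran's I on
location-aggregated simulated (randomized-quantile) residuals, with a
permutation p-value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .glmm import GlmmFit, fit_logistic_glmm

__all__ = [
    "DEFAULT_PREDICTORS",
    "MoranResult",
    "enumerate_candidates",
    "fit_candidates",
    "rank_models",
    "simulated_quantile_residuals",
    "morans_i",
    "moran_check",
]

DEFAULT_PREDICTORS = (
    "colwell_long", "colwell_5yr", "soil_mat", "cn_ratio", "map_mm", "soil_ph",
)


def enumerate_candidates(predictors=DEFAULT_PREDICTORS) -> list[tuple[str, ...]]:
    """All predictor subsets of size 0, 1 and 2 (null model first)."""
    predictors = tuple(predictors)
    if len(set(predictors)) != len(predictors):
        raise ValueError("duplicate predictor names")
    subsets: list[tuple[str, ...]] = [()]
    subsets += [(p,) for p in predictors]
    subsets += list(itertools.combinations(predictors, 2))
    return subsets


def fit_candidates(
    frame: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    response: str = "response",
) -> dict[tuple[str, ...], GlmmFit]:
    """Fit every candidate model on the same observation set."""
    return {
        subset: fit_logistic_glmm(frame, response, list(subset))
        for subset in enumerate_candidates(predictors)
    }


def rank_models(fits: dict[tuple[str, ...], GlmmFit]) -> pd.DataFrame:
    """Rank candidate fits by AICc against the null.

    Requires all fits to share n (AICc is not comparable otherwise).  Ties
    in AICc break toward fewer parameters, then lexicographic predictor
    names.  Columns: model, k, aicc, delta_best, delta_null, informative,
    top_set.
    """
    if () not in fits:
        raise ValueError("candidate set must include the null (intercept-only) model")
    ns = {fit.n for fit in fits.values()}
    if len(ns) != 1:
        raise ValueError(f"fits computed on differing observation counts: {sorted(ns)}")
    null_aicc = fits[()].aicc
    rows = [
        {
            "model": "+".join(subset) if subset else "(null)",
            "predictors": subset,
            "k": fit.k,
            "loglik": fit.loglik,
            "aicc": fit.aicc,
        }
        for subset, fit in fits.items()
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["aicc", "k", "model"], kind="stable", ignore_index=True
    )
    best = df["aicc"].iloc[0]
    df["delta_best"] = df["aicc"] - best
    df["delta_null"] = df["aicc"] - null_aicc
    df["informative"] = (null_aicc - df["aicc"]) >= 2.0
    df["top_set"] = df["delta_best"] <= 2.0
    return df


def simulated_quantile_residuals(
    fit: GlmmFit,
    frame: pd.DataFrame,
    n_sims: int = 250,
    seed: int | np.random.Generator = 0,
    response: str = "response",
    group: str = "location_id",
) -> pd.DataFrame:
    """Randomized quantile residuals from model simulations, per host.

    Simulates ``n_sims`` response vectors from the fitted model with fresh
    random intercepts drawn from N(0, tau_hat^2), then places each observed
    response within its simulated distribution with uniform jitter on ties.
    Under a correct model the residuals are Uniform(0, 1).  Returns per-host
    residuals plus the grouping column (aggregate with
    ``df.groupby('location_id')['residual'].mean()`` for spatial checks).
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for stable quantile residuals")
    if not np.isfinite(fit.tau2):
        raise ValueError("non-finite random-intercept variance")
    rng = np.random.default_rng(seed)
    predictors = [nm for nm in fit.names if nm != "(Intercept)"]
    X = np.column_stack(
        [np.ones(len(frame))] + [frame[p].to_numpy(dtype=float) for p in predictors]
    )
    eta_fix = X @ fit.beta
    codes, _ = pd.factorize(frame[group])
    n_loc = codes.max() + 1
    tau = np.sqrt(fit.tau2)
    u = rng.normal(0.0, tau, size=(n_sims, n_loc))
    p_sim = special.expit(eta_fix[None, :] + u[:, codes])
    y_sim = (rng.random(p_sim.shape) < p_sim).astype(np.int8)

    y = frame[response].to_numpy(dtype=int)
    # for a 0/1 observable: P(sim < y) + U * P(sim == y)
    frac_below = np.where(y == 1, (y_sim == 0).mean(axis=0), 0.0)
    frac_equal = (y_sim == y[None, :]).mean(axis=0)
    resid = frac_below + rng.random(len(y)) * frac_equal
    out = frame[[group]].copy()
    out["residual"] = resid
    return out


@dataclass
class MoranResult:
    I: float
    expected: float
    p: float
    n_perm: int


def _haversine_km(lat, lon) -> np.ndarray:
    """Pairwise great-circle distances in km."""
    R = 6371.0088
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    return 2 * R * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def morans_i(
    values,
    lat,
    lon,
    permutations: int = 999,
    seed: int | np.random.Generator = 0,
    weights: np.ndarray | None = None,
    min_dist_km: float = 1.0,
) -> MoranResult:
    """Moran's I with inverse great-circle-distance weights and permutation p.

    I = (n / sum_ij w_ij) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2) with
    z = values - mean.  Weights default to 1/max(distance, 1 km), zero
    diagonal, row-standardized; the floor protects colocated entries such as
    a twice-sampled site.  The two-sided permutation p-value counts
    permuted statistics at least as far from the null expectation
    E[I] = -1/(n-1) as the observed one, with the +1 convention.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 locations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: all values equal")
    if weights is None:
        d = _haversine_km(lat, lon)
        w = 1.0 / np.maximum(d, min_dist_km)
        np.fill_diagonal(w, 0.0)
        w = w / w.sum(axis=1, keepdims=True)
    else:
        w = np.asarray(weights, dtype=float)

    def stat(v: np.ndarray) -> float:
        z = v - v.mean()
        return float(n / w.sum() * (z @ w @ z) / (z @ z))

    I_obs = stat(x)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(permutations):
        I_perm = stat(rng.permutation(x))
        if abs(I_perm - expected) >= abs(I_obs - expected) - 1e-15:
            extreme += 1
    p = (1 + extreme) / (1 + permutations)
    return MoranResult(I=I_obs, expected=expected, p=p, n_perm=permutations)


def moran_check(
    fit: GlmmFit,
    frame: pd.DataFrame,
    locations: pd.DataFrame,
    n_sims: int = 250,
    permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Moran's I on location-mean simulated residuals of a fitted model."""
    resid = simulated_quantile_residuals(fit, frame, n_sims=n_sims, seed=seed)
    loc_means = resid.groupby("location_id")["residual"].mean()
    coords = locations.set_index("location_id").loc[loc_means.index]
    return morans_i(
        loc_means.to_numpy(),
        coords["latitude"].to_numpy(),
        coords["longitude"].to_numpy(),
        permutations=permutations,
        seed=seed + 1,
    )
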