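"""Bespoke resampling procedures: niche-separation permutation test and
subsample robustness of the predictability effect.

The permutation test asks whether hosts infected with two sister symbiont
species sit in soils with different precipitation predictability: species
labels are shuffled without replacement across the infected hosts, and both
the mean and median difference in predictability are referred to their
permutation nulls.

The robustness check guards against two much-larger collections dominating a
fitted effect: a fixed number of hosts is repeatedly removed at random from
the pooled hosts of those two collections, the model is refit, and the
distribution of the predictability coefficient is compared with the
full-data estimate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import GlmmFit, fit_logistic_glmm

__all__ = [
    "PermutationResult",
    "RobustnessResult",
    "permutation_niche_test",
    "niche_test_from_hosts",
    "subsample_robustness",
]


@dataclass
class PermutationResult:
    observed_mean_diff: float
    observed_median_diff: float
    null_mean_diffs: np.ndarray
    null_median_diffs: np.ndarray
    p_mean: float
    p_median: float
    B: int
    exhaustive: bool = False

    def to_dict(self) -> dict:
        return {
            "observed_mean_diff": self.observed_mean_diff,
            "observed_median_diff": self.observed_median_diff,
            "p_mean": self.p_mean,
            "p_median": self.p_median,
            "B": self.B,
            "exhaustive": self.exhaustive,
        }


def permutation_niche_test(
    labels,
    values,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> PermutationResult:
    """Two-group permutation test on mean and median differences.

    ``labels`` holds exactly two distinct group labels; differences are
    first-group-minus-second, groups ordered by first appearance.  Two-sided
    p = (1 + #{|T*| >= |T_obs|}) / (1 + B).  With ``exhaustive=True`` every
    distinct assignment of group sizes to positions is enumerated and
    p = #{|T*| >= |T_obs|} / #assignments (the observed assignment is one of
    them, so no +1 is needed).
    """
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    uniq = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    if len(uniq) != 2:
        raise ValueError(f"need exactly two group labels, got {uniq}")
    g1 = labels == uniq[0]
    n1 = int(g1.sum())
    n = len(values)

    def diffs(mask: np.ndarray) -> tuple[float, float]:
        a, b = values[mask], values[~mask]
        return float(a.mean() - b.mean()), float(np.median(a) - np.median(b))

    obs_mean, obs_median = diffs(g1)

    if exhaustive:
        null_mean, null_median = [], []
        for idx in itertools.combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            m, md = diffs(mask)
            null_mean.append(m)
            null_median.append(md)
        null_mean = np.array(null_mean)
        null_median = np.array(null_median)
        p_mean = float((np.abs(null_mean) >= abs(obs_mean) - 1e-12).mean())
        p_median = float((np.abs(null_median) >= abs(obs_median) - 1e-12).mean())
        return PermutationResult(obs_mean, obs_median, null_mean, null_median,
                                 p_mean, p_median, B=len(null_mean), exhaustive=True)

    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    null_mean = np.empty(B)
    null_median = np.empty(B)
    for b in range(B):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n1, replace=False)] = True
        null_mean[b], null_median[b] = diffs(mask)
    p_mean = (1 + int((np.abs(null_mean) >= abs(obs_mean) - 1e-12).sum())) / (1 + B)
    p_median = (1 + int((np.abs(null_median) >= abs(obs_median) - 1e-12).sum())) / (1 + B)
    return PermutationResult(obs_mean, obs_median, null_mean, null_median,
                             float(p_mean), float(p_median), B=B)


def niche_test_from_hosts(
    hosts: pd.DataFrame,
    colwell: pd.DataFrame,
    species: tuple[str, str] = ("hayleyella", "bonniea"),
    window: str = "colwell_long",
    B: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Niche-separation test built from the host table.

    Each host infected with exactly one of the two species contributes its
    location's predictability value under that species' label; hosts
    positive for both are ambiguous and are dropped (their count is logged
    via a warning).  Differences are species[0] minus species[1].
    """
    a, b = species
    cw = colwell.set_index("location_id")[window]
    known = hosts[[a, b]].notna().all(axis=1)
    pos_a = known & (hosts[a] == 1) & (hosts[b] != 1)
    pos_b = known & (hosts[b] == 1) & (hosts[a] != 1)
    both = known & (hosts[a] == 1) & (hosts[b] == 1)
    if both.any():
        warnings.warn(f"{int(both.sum())} host(s) coinfected with both species dropped")
    sel = hosts[pos_a | pos_b]
    labels = np.where(sel[a] == 1, a, b)
    values = cw.loc[sel["location_id"]].to_numpy()
    # order groups so the difference is species[0] - species[1]
    order = np.argsort(np.where(labels == a, 0, 1), kind="stable")
    return permutation_niche_test(labels[order], values[order], B=B, seed=seed)


@dataclass
class RobustnessResult:
    full_estimate: float
    subsample_estimates: np.ndarray
    removed_per_rep: int
    R: int
    sign_agreement: float
    n_nonconverged: int

    def to_dict(self) -> dict:
        return {
            "full_estimate": self.full_estimate,
            "subsample_estimates": [float(v) for v in self.subsample_estimates],
            "removed_per_rep": self.removed_per_rep,
            "R": self.R,
            "sign_agreement": self.sign_agreement,
            "n_nonconverged": self.n_nonconverged,
        }


def subsample_robustness(
    frame: pd.DataFrame,
    predictors: list[str],
    big_locations: tuple[str, str] | None = None,
    n_remove: int = 350,
    R: int = 1_000,
    seed: int = 0,
    coef: str | None = None,
) -> RobustnessResult:
    """Refit after repeatedly down-sampling the two largest collections.

    Per replicate, ``n_remove`` hosts are removed uniformly without
    replacement from the pooled hosts of the two named (or auto-detected
    largest) locations and the model is refit; the coefficient of interest
    (default: the first predictor, the predictability term) is collected.
    Non-converged replicates are kept but counted.
    """
    coef = coef or predictors[0]
    if big_locations is None:
        sizes = frame["location_id"].value_counts()
        big_locations = tuple(sizes.index[:2])
    pool_mask = frame["location_id"].isin(big_locations).to_numpy()
    pool_idx = np.flatnonzero(pool_mask)
    if n_remove >= len(pool_idx):
        raise ValueError(
            f"n_remove={n_remove} >= pooled size {len(pool_idx)} of {big_locations}"
        )
    full_fit = fit_logistic_glmm(frame, "response", predictors)
    full_est = full_fit.coef(coef)

    rng = np.random.default_rng(seed)
    estimates = np.empty(R)
    n_noncv = 0
    for r in range(R):
        if n_remove == 0:
            sub = frame
        else:
            drop = rng.choice(pool_idx, size=n_remove, replace=False)
            sub = frame.drop(index=frame.index[drop])
        fit = fit_logistic_glmm(sub, "response", predictors)
        estimates[r] = fit.coef(coef)
        if not fit.converged:
            n_noncv += 1
    sign_agreement = float((np.sign(estimates) == np.sign(full_est)).mean())
    return RobustnessResult(
        full_estimate=full_est,
        subsample_estimates=estimates,
        removed_per_rep=n_remove,
        R=R,
        sign_agreement=sign_agreement,
        n_nonconverged=n_noncv,
    )
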