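"""Coinfection enrichment statistics.

Two complementary views of whether pairs of endosymbionts co-occur in the
same host more or less often than chance:

* across locations -- for each of the C(5,2) = 10 unordered symbiont pairs, a
  random-intercept logistic model (presence of A ~ presence of B, location as
  random effect) whose slope is the within-location coinfection log-odds;
* within locations -- for a *Paraburkholderia* pair, a Fisher exact test on
  each location's 2x2 presence table, with Benjamini-Hochberg correction
  across the locations tested.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import PARABURKHOLDERIA, SYMBIONTS
from .glmm import GlmmFit, fit_logistic_glmm, wald_ci

__all__ = [
    "CoinfectionResult",
    "FisherResult",
    "pairwise_coinfection",
    "fisher_exact_2x2",
    "bh_adjust",
    "fisher_by_location",
]


@dataclass
class CoinfectionResult:
    pair: tuple[str, str]
    log_odds: float
    se: float
    ci95: tuple[float, float]
    outlier_flag: bool  # no coinfections observed for this pair
    n: int
    fit: GlmmFit

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "log_odds": self.log_odds,
            "se": self.se,
            "ci95": list(self.ci95),
            "outlier_flag": self.outlier_flag,
            "n": self.n,
        }


@dataclass
class FisherResult:
    location_id: str
    table: np.ndarray  # rows A+/A-, cols B+/B-
    odds_ratio: float
    p: float
    p_adj: float


def pairwise_coinfection(hosts: pd.DataFrame) -> list[CoinfectionResult]:
    """Coinfection log-odds for all 10 unordered symbiont pairs.

    Hosts missing either member's status are excluded from that pair only.
    The response is the alphabetically first member (under a saturated 2x2
    logit the slope is symmetric in direction).  Pairs with zero observed
    coinfections are flagged as outliers (their estimates escape toward
    -infinity under separation).
    """
    results = []
    for a, b in itertools.combinations(sorted(SYMBIONTS), 2):
        sub = hosts[[a, b, "location_id"]].dropna(subset=[a, b])
        if (sub[a] == 1).sum() == 0 or (sub[b] == 1).sum() == 0:
            warnings.warn(f"pair ({a}, {b}) skipped: a member is absent everywhere")
            continue
        frame = pd.DataFrame(
            {
                "response": sub[a].astype(int).to_numpy(),
                "partner": sub[b].astype(int).to_numpy(),
                "location_id": sub["location_id"].to_numpy(),
            }
        )
        fit = fit_logistic_glmm(frame, "response", ["partner"])
        ci = wald_ci(fit)["partner"]
        n_coinf = int(((sub[a] == 1) & (sub[b] == 1)).sum())
        results.append(
            CoinfectionResult(
                pair=(a, b),
                log_odds=fit.coef("partner"),
                se=fit.coef_se("partner"),
                ci95=ci,
                outlier_flag=(n_coinf == 0),
                n=len(sub),
                fit=fit,
            )
        )
    return results


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test (probability-mass criterion).

    Returns (odds_ratio, p).  A zero row or column margin makes the table
    degenerate: p = 1 and the odds ratio is reported as NaN.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return float("nan"), 1.0
    odds_ratio, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds_ratio), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_by_location(hosts: pd.DataFrame, pair: tuple[str, str]) -> list[FisherResult]:
    """Per-location Fisher exact tests for a *Paraburkholderia* pair.

    Only locations where both members of the pair were observed at least once
    (among hosts with both statuses known) are eligible; BH correction is
    applied across the eligible locations' p-values.
    """
    a, b = pair
    if a not in PARABURKHOLDERIA or b not in PARABURKHOLDERIA:
        raise ValueError(f"pair must be drawn from {PARABURKHOLDERIA}")
    partial: list[tuple[str, np.ndarray, float, float]] = []
    for loc, grp in hosts.groupby("location_id", sort=True):
        sub = grp[[a, b]].dropna()
        if len(sub) == 0 or (sub[a] == 1).sum() == 0 or (sub[b] == 1).sum() == 0:
            continue
        t = np.array(
            [
                [((sub[a] == 1) & (sub[b] == 1)).sum(), ((sub[a] == 1) & (sub[b] == 0)).sum()],
                [((sub[a] == 0) & (sub[b] == 1)).sum(), ((sub[a] == 0) & (sub[b] == 0)).sum()],
            ],
            dtype=int,
        )
        odds, p = fisher_exact_2x2(t)
        partial.append((loc, t, odds, p))
    if not partial:
        warnings.warn(f"no location eligible for pair {pair}")
        return []
    adj = bh_adjust([p for _, _, _, p in partial])
    return [
        FisherResult(location_id=loc, table=t, odds_ratio=odds, p=p, p_adj=float(pa))
        for (loc, t, odds, p), pa in zip(partial, adj)
    ]
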