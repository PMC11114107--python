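"""Colwell's predictability indices for monthly precipitation.

Colwell (1974) quantifies how predictable a periodic phenomenon is by
cross-classifying observations into a state x time contingency table and
decomposing predictability (P) into constancy (C) -- the tendency to stay in
one state year-round -- and contingency (M) -- the tendency for the state to
depend on the time of year.  With column (time) marginal totals X_j, row
(state) totals Y_i, cell counts N_ij and grand total Z, the three Shannon
entropies (natural log) are

    H(X)  = -sum_j (X_j/Z)  ln(X_j/Z)
    H(Y)  = -sum_i (Y_i/Z)  ln(Y_i/Z)
    H(XY) = -sum_ij (N_ij/Z) ln(N_ij/Z)

and

    P = 1 - (H(XY) - H(X)) / ln s
    C = 1 -  H(Y) / ln s
    M = (H(X) + H(Y) - H(XY)) / ln s

where s is the number of state classes.  P = C + M identically, and all
three lie in [0, 1].  Here time categories are the 12 calendar months and
state classes are equal-width bins of ln(precipitation + offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ColwellMatrix",
    "ColwellResult",
    "transform_and_bin",
    "colwell_metrics",
    "windowed_predictability",
    "colwell_table",
]

N_MONTHS = 12


@dataclass(frozen=True)
class ColwellMatrix:
    """State x month count matrix underlying Colwell's indices.

    ``counts`` has one row per state class and 12 columns (Jan..Dec);
    ``bin_edges`` are the class boundaries on the ln(x + offset) scale
    (length s + 1; degenerate series collapse to a single occupied row).
    """

    counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ColwellResult:
    """Predictability decomposition for one series and window."""

    P: float
    C: float
    M: float
    HX: float
    HY: float
    HXY: float
    matrix: ColwellMatrix
    window: tuple[int, int]


def transform_and_bin(
    series: pd.DataFrame,
    n_states: int = 11,
    offset_mm: float = 1.0,
) -> ColwellMatrix:
    """Bin one location's monthly precipitation into a state x month table.

    Parameters
    ----------
    series
        Columns ``year``, ``month`` (1-12), ``precip_mm`` (>= 0) for a single
        location; one row per (year, month).
    n_states
        Number of state classes s (>= 2).  Class boundaries are equally
        spaced between the window's own min and max of ln(x + offset_mm);
        intervals are closed on the right and the maximum falls in the top
        class.
    offset_mm
        Additive offset before the log, so that zero-rain months are defined.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if len(series) < 24:
        raise ValueError(
            f"window too short: {len(series)} monthly observations (< 24)"
        )
    months = series["month"].to_numpy()
    if months.min() < 1 or months.max() > N_MONTHS:
        raise ValueError("months must lie in 1..12")
    if series.duplicated(["year", "month"]).any():
        raise ValueError("duplicate (year, month) observations")
    precip = series["precip_mm"].to_numpy(dtype=float)
    if (precip < 0).any():
        raise ValueError("negative precipitation")

    z = np.log(precip + offset_mm)
    lo, hi = z.min(), z.max()
    if hi - lo < 1e-12:
        # constant series: all mass in one state class
        edges = np.linspace(lo - 0.5, lo + 0.5, n_states + 1)
    else:
        edges = np.linspace(lo, hi, n_states + 1)
    # right-closed bins, max value in the top class
    state = np.clip(np.searchsorted(edges, z, side="left") - 1, 0, n_states - 1)
    if hi - lo < 1e-12:
        state = np.full_like(state, n_states // 2)

    counts = np.zeros((n_states, N_MONTHS), dtype=int)
    np.add.at(counts, (state, months - 1), 1)
    return ColwellMatrix(counts=counts, bin_edges=edges)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def colwell_metrics(
    matrix: ColwellMatrix, window: tuple[int, int] = (0, 0)
) -> ColwellResult:
    """Compute P, C, M and the underlying entropies from a count matrix.

    The denominator uses ln of the *configured* class count s (the matrix's
    row dimension), not the number of occupied classes, so a constant series
    deterministically yields C = 1.  Empty cells contribute 0 (0 ln 0 := 0).
    """
    counts = np.asarray(matrix.counts, dtype=float)
    s = counts.shape[0]
    if s < 2:
        raise ValueError("need at least 2 state classes")
    Z = counts.sum()
    if Z <= 0:
        raise ValueError("empty count matrix")
    HX = _entropy(counts.sum(axis=0) / Z)  # time (month) marginal
    HY = _entropy(counts.sum(axis=1) / Z)  # state marginal
    HXY = _entropy(counts.ravel() / Z)
    log_s = np.log(s)
    P = 1.0 - (HXY - HX) / log_s
    C = 1.0 - HY / log_s
    M = (HX + HY - HXY) / log_s
    return ColwellResult(P=P, C=C, M=M, HX=HX, HY=HY, HXY=HXY,
                         matrix=matrix, window=window)


def windowed_predictability(
    series: pd.DataFrame,
    collection_year: int,
    start_year: int = 1901,
    n_states: int = 11,
    offset_mm: float = 1.0,
    recent_years: int = 5,
) -> tuple[ColwellResult, ColwellResult]:
    """Long-term and recent predictability for one location.

    The long-term window spans ``start_year``..``collection_year`` inclusive;
    the recent window is the ``recent_years`` calendar years ending with the
    collection year (60 months by default).  Each window is binned
    independently so class boundaries adapt to the window's own range.
    """
    years_present = set(series["year"].unique())
    needed = set(range(start_year, collection_year + 1))
    missing = sorted(needed - years_present)
    if missing:
        raise ValueError(f"insufficient precipitation coverage; missing years {missing}")

    def _window(y0: int, y1: int) -> ColwellResult:
        sub = series[(series["year"] >= y0) & (series["year"] <= y1)]
        mat = transform_and_bin(sub, n_states=n_states, offset_mm=offset_mm)
        return colwell_metrics(mat, window=(y0, y1))

    long_term = _window(start_year, collection_year)
    recent = _window(collection_year - recent_years + 1, collection_year)
    return long_term, recent


def colwell_table(
    precip: pd.DataFrame,
    locations: pd.DataFrame,
    n_states: int = 11,
    offset_mm: float = 1.0,
) -> pd.DataFrame:
    """Per-location predictability table (both windows) for the full study.

    ``precip`` is long-format (location_id, year, month, precip_mm);
    ``locations`` supplies each location's collection ``year``.  Returns one
    row per location with columns ``colwell_long`` / ``colwell_5yr`` plus the
    C and M components and window bounds for each.
    """
    rows = []
    for _, loc in locations.iterrows():
        sub = precip[precip["location_id"] == loc["location_id"]]
        if sub.empty:
            raise ValueError(f"no precipitation series for {loc['location_id']!r}")
        long_term, recent = windowed_predictability(
            sub, int(loc["year"]), n_states=n_states, offset_mm=offset_mm
        )
        rows.append(
            {
                "location_id": loc["location_id"],
                "colwell_long": long_term.P,
                "colwell_long_C": long_term.C,
                "colwell_long_M": long_term.M,
                "long_start": long_term.window[0],
                "long_end": long_term.window[1],
                "colwell_5yr": recent.P,
                "colwell_5yr_C": recent.C,
                "colwell_5yr_M": recent.M,
                "recent_start": recent.window[0],
                "recent_end": recent.window[1],
            }
        )
    return pd.DataFrame(rows)
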