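"""Synthetic survey generator with known ground truth.

Emulates the statistical structure the analysis assumes -- not real
geography or climate: a set of location-collections with log-normal seasonal
monthly precipitation, location-level soil covariates, and per-host 0/1
symbiont statuses generated from a random-intercept logistic model whose
slope is on the location's long-term precipitation predictability.
Seasonal amplitude tunes Colwell's P (larger amplitude, more contingent and
hence more predictable rainfall); noise lowers it.  Coinfection structure is
pairwise: each non-focal symbiont is drawn conditionally on the focal one to
match a marginal prevalence and a target odds ratio.

Every generator is a pure function of (config, seed); per-stage RNG streams
are spawned from the config seed so each stage is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from . import colwell as cw
from .data_io import SYMBIONTS

__all__ = ["SimConfig", "SimTruth", "simulate_precip", "simulate_locations",
           "simulate_hosts", "simulate_study", "STUDY_HOST_COUNTS"]

# per-collection screened-host counts of the emulated survey design
# (22 collections, range 4..226, two of them much larger than the rest)
STUDY_HOST_COUNTS = (
    9, 14, 7, 18, 13, 10, 12, 9, 13, 24, 24,
    10, 7, 13, 6, 7, 12, 59, 7, 4, 226, 188,
)


@dataclass
class SimConfig:
    """Ground-truth parameters of a synthetic survey.

    Defaults mirror the emulated study design: 22 location-collections with
    the survey's per-collection host counts, climate from 1901 through a
    collection year ~a century later, moderate seasonality, and a focal
    symbiont whose infection logit depends on long-term predictability with
    a location random intercept.
    """

    n_locations: int = 22
    hosts_per_location: int | tuple[int, ...] = STUDY_HOST_COUNTS
    years: int = 100            # climate series length, starting 1901
    start_year: int = 1901
    seasonal_amplitude: float = 1.0   # a in exp(mu + a sin(...) + eps)
    amplitude_range: tuple[float, float] | None = None  # per-location a ~ U(lo, hi)
    noise_sd: float = 0.6             # eps SD on the ln-mm scale
    mean_log_mm: float = 4.5          # mu, ~90 mm/month
    beta0: float = -1.0               # focal infection intercept (log-odds)
    beta_pred: float = 1.0            # slope on long-term Colwell P
    tau: float = 0.5                  # location random-intercept SD
    focal: str = "hayleyella"
    marginal_p: dict = field(default_factory=lambda: {
        "agricolaris": 0.20, "bonniea": 0.05,
        "amoebophilus": 0.20, "chlamydiae": 0.30,
    })
    coinfection_log_or: dict = field(default_factory=dict)  # {(a, b): log OR}
    mat_ph_corr: float = 0.0
    n_states: int = 11
    offset_mm: float = 1.0
    seed: int = 0

    def host_counts(self) -> np.ndarray:
        if isinstance(self.hosts_per_location, int):
            counts = np.full(self.n_locations, self.hosts_per_location)
        else:
            counts = np.asarray(self.hosts_per_location)
        if len(counts) != self.n_locations:
            raise ValueError("hosts_per_location length != n_locations")
        if (counts < 1).any():
            raise ValueError("hosts_per_location must be >= 1")
        return counts

    def validate(self) -> None:
        if self.years < 5:
            raise ValueError("years must be >= 5")
        if self.noise_sd < 0 or self.tau < 0 or self.seasonal_amplitude < 0:
            raise ValueError("SDs and amplitude must be >= 0")
        if self.focal not in SYMBIONTS:
            raise ValueError(f"focal must be one of {SYMBIONTS}")
        self.host_counts()


@dataclass
class SimTruth:
    """Realized ground truth of one synthetic dataset."""

    config: SimConfig
    location_ids: list[str]
    random_intercepts: np.ndarray
    colwell_long: np.ndarray
    collection_year: int

    def to_dict(self) -> dict:
        cfg = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(self.config).items()
            if k not in ("marginal_p", "coinfection_log_or")
        }
        cfg["marginal_p"] = dict(self.config.marginal_p)
        cfg["coinfection_log_or"] = {
            "|".join(k): v for k, v in self.config.coinfection_log_or.items()
        }
        return {
            "config": cfg,
            "location_ids": self.location_ids,
            "random_intercepts": [float(u) for u in self.random_intercepts],
            "colwell_long": [float(p) for p in self.colwell_long],
            "collection_year": self.collection_year,
        }


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _location_ids(config: SimConfig) -> list[str]:
    return [f"L{i:02d}" for i in range(1, config.n_locations + 1)]


def simulate_precip(config: SimConfig) -> pd.DataFrame:
    """Monthly precipitation per location, long format.

    precip = exp(mu + a sin(2 pi m / 12 + phi_loc) + eps), eps ~ N(0, sd^2),
    with a location-specific phase.  Amplitude a controls the contingency
    (month-dependence) of the series and therefore Colwell's P.  When
    ``amplitude_range`` is set, each location gets its own amplitude drawn
    uniformly from that range -- the design for parameter-recovery studies,
    which need predictability to vary between locations.
    """
    config.validate()
    rng = _rng(config, 1)
    ids = _location_ids(config)
    phases = rng.uniform(0, 2 * np.pi, size=config.n_locations)
    if config.amplitude_range is not None:
        lo, hi = config.amplitude_range
        amplitudes = rng.uniform(lo, hi, size=config.n_locations)
    else:
        amplitudes = np.full(config.n_locations, config.seasonal_amplitude)
    years = np.arange(config.start_year, config.start_year + config.years)
    months = np.arange(1, 13)
    frames = []
    for loc, phi, a in zip(ids, phases, amplitudes):
        yy, mm = np.meshgrid(years, months, indexing="ij")
        seasonal = a * np.sin(2 * np.pi * mm / 12 + phi)
        eps = rng.normal(0.0, config.noise_sd, size=yy.shape)
        precip = np.exp(config.mean_log_mm + seasonal + eps)
        frames.append(pd.DataFrame({
            "location_id": loc,
            "year": yy.ravel(),
            "month": mm.ravel(),
            "precip_mm": precip.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_locations(config: SimConfig, precip: pd.DataFrame) -> pd.DataFrame:
    """Location table with plausible soil covariates and coordinates.

    Soil pH, mean annual soil temperature and C/N are Gaussian with
    field-realistic means/SDs; an optional MAT-pH correlation can be
    switched on.  MAP is computed from the simulated series itself.
    """
    rng = _rng(config, 2)
    ids = _location_ids(config)
    n = config.n_locations
    lat = rng.uniform(25.0, 45.0, n)
    lon = rng.uniform(-95.0, -70.0, n)
    rho = config.mat_ph_corr
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    soil_mat = 14.0 + 4.0 * z[:, 0]
    soil_ph = np.clip(5.5 + 0.8 * z[:, 1], 3.5, 8.5)
    cn_ratio = np.clip(rng.normal(15.0, 3.0, n), 5.0, None)
    annual = precip.groupby(["location_id", "year"])["precip_mm"].sum()
    map_mm = annual.groupby("location_id").mean()
    year = config.start_year + config.years - 1
    return pd.DataFrame({
        "location_id": ids,
        "name": [f"Synthetic site {i}" for i in range(1, n + 1)],
        "latitude": lat,
        "longitude": lon,
        "year": year,
        "soil_ph": soil_ph,
        "soil_mat": soil_mat,
        "cn_ratio": cn_ratio,
        "map_mm": map_mm.loc[ids].to_numpy(),
    })


def _plackett_p11(pa: np.ndarray, pb: float, psi: float) -> np.ndarray:
    """Joint success probability of a 2x2 table with margins (pa, pb) and
    odds ratio psi (the standard quadratic-root cell construction)."""
    pa = np.asarray(pa, dtype=float)
    if not np.isfinite(psi) or psi <= 0:
        raise ValueError("odds ratio must be finite and > 0")
    if abs(psi - 1.0) < 1e-12:
        return pa * pb
    s = 1.0 + (pa + pb) * (psi - 1.0)
    disc = s * s - 4.0 * psi * (psi - 1.0) * pa * pb
    if (disc < 0).any():
        raise ValueError("requested odds ratio infeasible for the margins")
    p11 = (s - np.sqrt(disc)) / (2.0 * (psi - 1.0))
    lo = np.maximum(0.0, pa + pb - 1.0)
    hi = np.minimum(pa, pb)
    if ((p11 < lo - 1e-9) | (p11 > hi + 1e-9)).any():
        raise ValueError("requested odds ratio infeasible for the margins")
    return np.clip(p11, lo, hi)


def simulate_hosts(
    config: SimConfig,
    per_location_P: np.ndarray,
    random_intercepts: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Host table with ground-truth infection model; returns (hosts, u).

    The focal symbiont follows Bernoulli(expit(beta0 + beta_pred * P + u));
    every other symbiont is drawn conditionally on the focal status so that
    its marginal prevalence and the pair's odds ratio (from
    ``coinfection_log_or``, default independence) are matched given each
    host's focal probability.
    """
    config.validate()
    rng = _rng(config, 3)
    ids = _location_ids(config)
    counts = config.host_counts()
    P = np.asarray(per_location_P, dtype=float)
    if len(P) != config.n_locations:
        raise ValueError("per_location_P length != n_locations")
    if random_intercepts is None:
        u = rng.normal(0.0, config.tau, size=config.n_locations)
    else:
        u = np.asarray(random_intercepts, dtype=float)

    loc_idx = np.repeat(np.arange(config.n_locations), counts)
    eta = config.beta0 + config.beta_pred * P[loc_idx] + u[loc_idx]
    p_focal = special.expit(eta)
    focal_status = (rng.random(len(eta)) < p_focal).astype(int)

    data = {
        "host_id": [f"H{i:05d}" for i in range(1, len(eta) + 1)],
        "location_id": [ids[i] for i in loc_idx],
        "year": config.start_year + config.years - 1,
        config.focal: focal_status,
    }
    for sym in SYMBIONTS:
        if sym == config.focal:
            continue
        pb = config.marginal_p.get(sym, 0.2)
        pair = tuple(sorted((config.focal, sym)))
        log_or = config.coinfection_log_or.get(pair, 0.0)
        try:
            p11 = _plackett_p11(p_focal, pb, np.exp(log_or))
        except ValueError as err:
            raise ValueError(f"pair {pair}: {err}") from err
        p_given = np.where(
            focal_status == 1,
            p11 / np.maximum(p_focal, 1e-12),
            (pb - p11) / np.maximum(1.0 - p_focal, 1e-12),
        )
        data[sym] = (rng.random(len(eta)) < np.clip(p_given, 0, 1)).astype(int)
    hosts = pd.DataFrame(data)[["host_id", "location_id", "year", *SYMBIONTS]]
    return hosts, u


def simulate_study(
    config: SimConfig,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Full synthetic study: precip + locations + hosts (+ CSVs on disk).

    Per-location long-term Colwell P is computed from the simulated climate
    and drives host infection; the realized values and random intercepts are
    returned as ground truth for parameter-recovery checks.
    """
    precip = simulate_precip(config)
    locations = simulate_locations(config, precip)
    collection_year = config.start_year + config.years - 1
    table = cw.colwell_table(precip, locations,
                             n_states=config.n_states, offset_mm=config.offset_mm)
    P = table.set_index("location_id").loc[_location_ids(config), "colwell_long"].to_numpy()
    hosts, u = simulate_hosts(config, P)
    truth = SimTruth(
        config=config,
        location_ids=_location_ids(config),
        random_intercepts=u,
        colwell_long=P,
        collection_year=collection_year,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hosts.to_csv(out / "hosts.csv", index=False)
        locations.to_csv(out / "locations.csv", index=False)
        precip.to_csv(out / "precip.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    return hosts, locations, precip, truth
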