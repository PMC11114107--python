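"""End-to-end orchestration of the analysis.

Stages: Colwell predictability per location -> per-host model frames ->
pairwise coinfection models -> AICc candidate-set selection (with Moran's I
residual check on the best model) -> niche-separation permutation test ->
subsample robustness.  Every stochastic stage takes an explicit seed and a
rerun with the same config is bit-identical; the manifest records the config
hash and library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import colwell as cw
from . import data_io
from .coinfection import fisher_by_location, pairwise_coinfection
from .model_selection import (DEFAULT_PREDICTORS, fit_candidates, moran_check,
                              rank_models)
from .resampling import niche_test_from_hosts, subsample_robustness

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("symbioclim")

DEFAULT_RESPONSES = (
    "agricolaris", "hayleyella", "bonniea", "amoebophilus", "chlamydiae",
    "any", "hayleyella_x_amoebophilus",
)


@dataclass
class RunConfig:
    hosts_path: str
    locations_path: str
    precip_path: str
    out_dir: str
    responses: tuple[str, ...] = DEFAULT_RESPONSES
    n_states: int = 11
    offset_mm: float = 1.0
    B: int = 10_000          # permutation replicates
    R: int = 1_000           # robustness refits
    n_remove: int = 350
    moran_permutations: int = 999
    moran_nsims: int = 250
    seeds: dict = field(default_factory=dict)  # {"perm":, "robust":, "moran":}

    def validate(self) -> None:
        for key in ("perm", "robust", "moran"):
            if key not in self.seeds:
                raise ValueError(f"missing seed for stochastic stage {key!r}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; writes per-stage outputs and a manifest.

    Returns a dict of the in-memory stage results.  Any stage failure is
    re-raised with the stage name; outputs of completed stages remain on
    disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "read inputs"
    try:
        hosts = data_io.read_host_table(config.hosts_path)
        locations = data_io.read_location_table(config.locations_path)
        precip = data_io.read_precip_table(config.precip_path)

        stage = "prevalence summary"
        prevalence = data_io.summarize_prevalence(hosts)
        prevalence.to_csv(out / "prevalence_summary.csv", index=False)
        results["prevalence"] = prevalence

        stage = "colwell"
        colwell_df = cw.colwell_table(precip, locations,
                                      n_states=config.n_states,
                                      offset_mm=config.offset_mm)
        colwell_df.to_csv(out / "colwell.csv", index=False)
        results["colwell"] = colwell_df

        stage = "coinfection"
        coinf = pairwise_coinfection(hosts)
        fisher = {}
        for pair in (("agricolaris", "hayleyella"), ("agricolaris", "bonniea"),
                     ("bonniea", "hayleyella")):
            fisher["|".join(pair)] = [
                {"location_id": r.location_id, "table": r.table.tolist(),
                 "odds_ratio": r.odds_ratio, "p": r.p, "p_adj": r.p_adj}
                for r in fisher_by_location(hosts, pair)
            ]
        (out / "coinfection.json").write_text(json.dumps(
            {"pairs": [r.to_dict() for r in coinf], "fisher_by_location": fisher},
            indent=2))
        results["coinfection"] = coinf

        stage = "model selection"
        rankings = {}
        for response in config.responses:
            frame = data_io.build_model_frame(hosts, locations, colwell_df, response)
            if frame["response"].nunique() < 2:
                log.warning("response %s is constant; skipped", response)
                continue
            fits = fit_candidates(frame)
            ranking = rank_models(fits)
            best = fits[ranking["predictors"].iloc[0]]
            moran = moran_check(best, frame, locations,
                                n_sims=config.moran_nsims,
                                permutations=config.moran_permutations,
                                seed=config.seeds["moran"])
            payload = {
                "response": response,
                "n": int(frame.shape[0]),
                "models": ranking.drop(columns=["predictors"]).to_dict("records"),
                "moran": {"I": moran.I, "expected": moran.expected,
                          "p": moran.p, "n_perm": moran.n_perm},
            }
            (out / f"ranking_{response}.json").write_text(json.dumps(payload, indent=2))
            rankings[response] = (ranking, frame, fits)
        results["rankings"] = rankings

        stage = "permutation niche test"
        perm = niche_test_from_hosts(hosts, colwell_df, B=config.B,
                                     seed=config.seeds["perm"])
        (out / "perm.json").write_text(json.dumps(perm.to_dict(), indent=2))
        results["perm"] = perm

        stage = "subsample robustness"
        robust = {}
        for response in ("hayleyella", "agricolaris"):
            if response not in rankings:
                continue
            _, frame, _ = rankings[response]
            sizes = frame["location_id"].value_counts()
            pooled = int(sizes.iloc[:2].sum()) if len(sizes) >= 2 else 0
            if pooled <= config.n_remove:
                log.warning("robustness for %s skipped: pooled size %d <= n_remove",
                            response, pooled)
                continue
            rb = subsample_robustness(frame, ["colwell_long"],
                                      n_remove=config.n_remove, R=config.R,
                                      seed=config.seeds["robust"])
            robust[response] = rb
        (out / "robust.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in robust.items()}, indent=2))
        results["robust"] = robust

        stage = "manifest"
        manifest = {
            "symbioclim_version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "config_hash": config.config_hash(),
            "seeds": config.seeds,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        results["manifest"] = manifest
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return results
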