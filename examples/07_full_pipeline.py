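"""End-to-end analysis bundle on a simulated survey.

Writes a synthetic study to disk, then runs the whole analysis (prevalence
tables, Colwell metrics, coinfection, candidate-set selection with residual
diagnostics, permutation test, subsample robustness) into an output
directory.  The same thing is available from the shell as
`symbioclim simulate` + `symbioclim run-all`.
"""

import json
import tempfile
from pathlib import Path

from symbioclim.pipeline import RunConfig, run_all
from symbioclim.synthetic import SimConfig, simulate_study

workdir = Path(tempfile.mkdtemp(prefix="symbioclim-demo-"))
simulate_study(SimConfig(beta0=-1.0, beta_pred=-1.5, tau=0.5, seed=17),
               out_dir=workdir)

cfg = RunConfig(
    hosts_path=str(workdir / "hosts.csv"),
    locations_path=str(workdir / "locations.csv"),
    precip_path=str(workdir / "precip.csv"),
    out_dir=str(workdir / "out"),
    responses=("hayleyella", "any"),
    B=2000, R=100, n_remove=100,
    seeds={"perm": 1, "robust": 2, "moran": 3},
)
run_all(cfg)

out = workdir / "out"
print("report bundle:", *sorted(p.name for p in out.iterdir()), sep="\n  ")
ranking = json.loads((out / "ranking_hayleyella.json").read_text())
best = ranking["models"][0]
print(f"\nbest hayleyella model: {best['model']} (AICc {best['aicc']:.1f})")
perm = json.loads((out / "perm.json").read_text())
print(f"niche-test p (mean diff): {perm['p_mean']:.4f}")
print(f"\nAll outputs and the manifest live in {out}")
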