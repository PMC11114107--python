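# symbioclim

Tools for studying how climate predictability shapes bacterial endosymbiont
prevalence in wild *Dictyostelium discoideum* amoebae.

Soil-dwelling *D. discoideum* hosts several facultative bacterial symbionts —
three *Paraburkholderia* species (*agricolaris*, *hayleyella*, *bonniea*)
plus *Amoebophilus* and Chlamydiae lineages. Surveys screen amoeba isolates
from many collection sites and ask: does the prevalence of each symbiont
track the *predictability* of local precipitation (Colwell's information-
theoretic index), or soil covariates such as temperature, pH, and C:N ratio?
And do symbionts co-occur within hosts more often than chance?

The package implements the full analysis chain:

- **`colwell`** — Colwell's predictability `P`, constancy `C`, and
  contingency `M` from monthly precipitation, over a long-term window
  (1901 → collection year) and the trailing five years. `P = C + M`.
- **`glmm`** — random-intercept Bernoulli-logit GLMMs fit by marginal
  maximum likelihood (adaptive Gauss–Hermite / Laplace), with Wald errors
  and AICc. Cross-validated against `lme4::glmer`.
- **`model_selection`** — the 22-model AICc candidate set per response
  (null + 6 single-predictor + 15 two-predictor), informative/top-set
  classification, simulation-based quantile residuals, and Moran's I
  spatial residual checks.
- **`coinfection`** — pair GLMMs for all 10 symbiont pairs, per-location
  Fisher exact tests with Benjamini–Hochberg correction.
- **`resampling`** — permutation niche-separation tests (with exact
  enumeration for small samples) and subsample robustness against the two
  largest collections.
- **`synthetic`** — a survey-shaped simulator (22 collections with the
  study's host counts) with known ground truth for every knob: climate
  seasonality, prevalence–predictability slopes, random-intercept variance,
  pairwise coinfection odds ratios.
- **`datasets`** — the published per-collection screening counts and a
  host-table reconstruction for prevalence summaries.
- **`pipeline` / CLI** — one call (`run_all` or `symbioclim run-all`) runs
  everything into a reproducible, manifest-stamped report bundle.

## Worked example

Simulate a survey in which *hayleyella* prevalence declines with
precipitation predictability, then recover the relationship:

```python
from symbioclim.colwell import colwell_table
from symbioclim.data_io import build_model_frame
from symbioclim.glmm import fit_logistic_glmm, wald_ci
from symbioclim.synthetic import SimConfig, simulate_study

cfg = SimConfig(beta0=-1.0, beta_pred=-4.0, tau=0.3, seed=5,
                amplitude_range=(0.0, 4.0), noise_sd=0.3)
hosts, locations, precip, _ = simulate_study(cfg)

colwell = colwell_table(precip, locations)
print(colwell[["location_id", "colwell_long", "colwell_5yr"]].head(3))

frame = build_model_frame(hosts, locations, colwell, "hayleyella")
fit = fit_logistic_glmm(frame, "response", ["colwell_long"])
lo, hi = wald_ci(fit)["colwell_long"]
print(f"slope on long-term P: {fit.coef('colwell_long'):+.2f} "
      f"(95% CI {lo:+.2f} to {hi:+.2f}), tau^2 = {fit.tau2:.2f}")
```

Output:

```
  location_id  colwell_long  colwell_5yr
0         L01      0.679623     0.729930
1         L02      0.629461     0.716177
2         L03      0.653314     0.693269
slope on long-term P: -1.28 (95% CI -3.07 to +0.51), tau^2 = 0.00
```

The recovered slope has the generating sign; the wide interval is honest —
at a 22-collection survey size, location-level predictors are weakly
identified, which is exactly what the package's robustness and calibration
tools quantify.

The `examples/` directory has one short script per capability
(predictability, prevalence tables, model selection, coinfection,
resampling, residual diagnostics, and the full pipeline); each prints its
results with a one-line interpretation.

## Command line

```sh
symbioclim simulate --seed 5 --out-dir study/      # synthetic survey
symbioclim run-all --hosts study/hosts.csv --locations study/locations.csv \
    --precip study/precip.csv --out-dir study/report --seed 1
```

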