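# Methods

This document describes the statistical methods implemented in `symbioclim`,
the numerical choices made, and the limitations of the synthetic data
generator. Field notation: `P`, `C`, `M` are Colwell's predictability,
constancy, and contingency; `β` are fixed-effect log-odds coefficients; `τ²`
is the location random-intercept variance.

## Scientific setting

Wild *Dictyostelium discoideum* amoebae carry several facultative bacterial
endosymbionts — three *Paraburkholderia* species (*agricolaris*,
*hayleyella*, *bonniea*) plus *Amoebophilus* and Chlamydiae lineages. The
package asks how the prevalence of each symbiont across collection sites
relates to climate predictability and soil covariates, and whether symbionts
co-occur within hosts more or less often than chance.

## Colwell's predictability (`colwell`)

Monthly precipitation is reduced to a state × month contingency table:

1. Transform monthly totals as `ln(x + 1 mm)`.
2. Cut into `s` equal-width bins (default `s = 11`) between the window's
   minimum and maximum transformed value; intervals are right-closed. A
   constant series occupies a single middle state.
3. Count observations per (state, calendar month) cell.

With Shannon entropies (natural log) of the month marginal `H(X)`, state
marginal `H(Y)`, and joint `H(XY)`:

- predictability `P = 1 − (H(XY) − H(X)) / ln s`
- constancy `C = 1 − H(Y) / ln s`
- contingency `M = (H(X) + H(Y) − H(XY)) / ln s`

`P = C + M` is an algebraic identity and is enforced in tests to 1e−10.
Two windows are computed per location: long-term (1901 through the
collection year) and recent (the trailing five calendar years, inclusive).
Windows shorter than 24 months are refused rather than silently computed.

## Prevalence GLMM (`glmm`)

The core model is a Bernoulli-logit GLMM with a location random intercept:

```
y_ig ~ Bernoulli(p_ig),  logit(p_ig) = x_igᵀβ + u_g,  u_g ~ N(0, τ²)
```

The marginal likelihood integrates `u_g` out per location with adaptive
Gauss–Hermite quadrature centred and scaled at the per-group conditional
mode. One node (the default) is the Laplace approximation, the same default
used by `lme4::glmer`; more nodes refine the integral. The implementation
was cross-validated against `lme4::glmer` on simulated data: coefficients,
standard errors, τ², and log-likelihood agree to ≈1e−5.

Numerical choices:

- Bernoulli log-likelihood via `log1p`/`logaddexp` forms; the quadrature
  sum via `logsumexp` — no underflow for extreme linear predictors.
- Starting values from a ridge-penalized (λ = 1e−4) Newton logistic fit,
  clipped to ±10, which stays finite under complete separation.
- `(β, τ)` maximized jointly by L-BFGS-B (τ bounded in [0, 10]), followed
  by a Nelder–Mead polish. The polish matters: finite-difference gradients
  can stall the quasi-Newton step slightly short of the optimum on nearly
  flat likelihoods, which otherwise injects artificial variance into
  resampling distributions built from many refits.
- Wald standard errors from a central finite-difference observed-information
  matrix of `β` at `(β̂, τ̂)`.
- `|β| ≥ 15` flags (quasi-)complete separation; the fit is returned flagged
  and its Wald interval reported as unbounded.

AICc uses `k = n_fixed + 1` (the random-intercept variance counts as one
parameter): `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`.

## Candidate set and model selection (`model_selection`)

For each response, 22 models are fit on the same observations: the null
(intercept + random intercept), all six single-predictor models, and all
fifteen two-predictor models over {long-term P, recent P, soil mean annual
temperature, soil C:N, mean annual precipitation, soil pH}. A model is
*informative* when its AICc beats the null by ≥ 2; the *top set* is every
model within 2 AICc of the best. Ties break toward fewer parameters, then
lexicographic names. Ranking across fits with different `n` is refused.

### Residual diagnostics

Randomized quantile residuals are computed by simulation: ≥ 100 response
vectors are drawn from the fitted model (fresh random intercepts each
simulation), and each observation's residual is
`P(sim < obs) + U·P(sim = obs)` with `U ~ Uniform(0,1)` — uniform under a
correct model. Residuals are averaged by location and tested for spatial
autocorrelation with Moran's I using row-standardized inverse great-circle
distance weights (distances floored at 1 km to keep repeat-visit sites
finite). Significance is a two-sided permutation test around the null
expectation `E[I] = −1/(n−1)`, with `p = (1 + #extreme)/(1 + B)`.

## Coinfection (`coinfection`)

- **Pair GLMMs**: for each of the 10 unordered symbiont pairs, the
  alphabetically-first member is regressed on the other's infection status
  with a location random intercept; hosts missing either status are dropped
  pairwise. A pair with zero observed coinfections is flagged as an outlier
  rather than trusted to a separated fit.
- **Per-location exact tests**: for *Paraburkholderia* pairs only,
  a two-sided Fisher exact test (probability-mass definition) per eligible
  location — eligible meaning both pair members occur there among hosts with
  both statuses known. P-values are Benjamini–Hochberg adjusted across
  eligible locations. Degenerate tables (a zero margin) return p = 1.

## Resampling (`resampling`)

- **Niche permutation test**: hosts infected with exactly one of two focal
  species contribute their location's predictability under that species'
  label; the labels are permuted `B = 10,000` times (default). Both mean and
  median differences are tested, `p = (1 + #{|T*| ≥ |T|})/(1 + B)`. An
  exhaustive mode enumerates all label assignments for small samples and
  returns the exact fraction.
- **Subsample robustness**: the two largest collections dominate the data,
  so `n_remove = 350` hosts (default) are removed uniformly from their
  pooled hosts, the model refit, and the slope collected over `R = 1,000`
  replicates; the headline number is the fraction of refits preserving the
  full-data sign.

## Synthetic data generator (`synthetic`)

The generator emulates a survey of the study's shape: by default 22
collections with the study's per-collection host counts (4–226, total 692).

- **Climate**: `precip = exp(μ + a·sin(2πm/12 + φ_loc) + ε)`,
  `ε ~ N(0, σ²)`. The seasonal amplitude `a` tunes predictability; the
  defaults (a = 1.0, σ = 0.6) put long-term P around 0.30–0.39, a realistic
  field range. For recovery experiments `amplitude_range` draws per-location
  amplitudes uniformly, spreading P across locations.
- **Hosts**: the focal symbiont follows the GLMM truth
  `Bernoulli(expit(β₀ + β_P·P + u_g))`; other symbionts are drawn
  conditionally on the focal status through a Plackett copula so that
  requested pairwise odds ratios hold exactly in the generating
  distribution.
- **Reproducibility**: each stage draws from its own
  `default_rng([seed, stream])` stream, so host draws don't perturb climate
  draws.

What it does **not** emulate: spatially correlated climate between nearby
sites, temporal trends in precipitation, host relatedness or repeat sampling
of clones, and more-than-pairwise coinfection structure.

### Frozen experiment designs

Two simulation designs are fixed a priori (not tuned to outcomes):

- *Parameter recovery*: 30 locations × 50 hosts, `amplitude_range (0, 4)`,
  σ = 0.3, 60 years, β₀ = −1, β_P = 1, τ = 0.5. Note the information limit:
  with P confined to [0, 1], the slope's standard error cannot fall much
  below ≈ 0.2 even at maximal predictor spread at this size, so single-run
  slope estimates scatter widely around the truth; τ is better identified.
- *Sign recovery*: 80 locations × 40 hosts on a shared climate, two focal
  species with slopes −1.0 and +1.2; the check is that fitted slopes match
  the generating signs in ≥ 95% of replicates.

## Limitations

- Laplace (1-node) integration biases τ̂ slightly downward for tiny groups;
  raise `n_quad` when groups are small and effects large.
- Wald intervals are symmetric and degrade under separation; the code flags
  but does not profile.
- The survey-count reconstruction (`datasets.reconstruct_survey_hosts`)
  fixes marginal counts only; coinfection structure in that table is
  arbitrary, so it supports prevalence summaries, not coinfection analyses.
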