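# Methods

This document describes the statistical model implemented by `deersem`, the
assumptions behind each stage, the main parameters with their units and
defaults, and the numerical choices made in the implementation.  The
synthetic-data generator, its scope and its limits are documented at the end.

## 1. Scientific question and overall design

The pipeline asks whether the fertility (twinning probability) and body
condition (eviscerated body mass) of adult female Roe Deer respond to the
local density of two potential competitors — Reeve's Muntjac and Fallow Deer
— and to their own species' density, after accounting for habitat (arable
extent around the cull location) and survey structure (forest block, year,
week of culling).

Because deer density is not observed at the individual level, the analysis
is a chain:

1. **Distance sampling** of nocturnal line-transect surveys gives a
   detection function per species.
2. A **density surface model** (DSM) converts segment-level abundance
   estimates into annual density rasters with a per-cell coefficient of
   variation (CV).
3. **Buffer extraction** averages each raster inside circles of several
   candidate radii around every cull location, producing individual-level
   covariates.
4. A **piecewise structural equation model** (SEM) expresses the assumed
   causal structure as a set of component regressions (mixed models).
5. **Multimodel inference** (AICc, Akaike weights, an 85% confidence set,
   full model averaging) summarises each component over all predictor
   subsets and over the candidate buffer radii.
6. **Uncertainty propagation** repeats steps 3–5 on density rasters
   resampled from their cell-wise CVs, so that density-estimation error is
   carried into the final coefficients.
7. A **Leslie matrix** side-model checks that senescent females are a
   negligible share of the population, justifying the omission of a
   senescence term from the fertility model.

## 2. Distance sampling (`density_surface`)

**Model.** Half-normal detection of perpendicular distance *d*,
`g(d) = exp(−d² / 2σ²)`, truncated at `w` (default 150 m).  The scale is
log-linear in optional covariates:
`log σ = β₀ + β_vis[class] + β_g · log(group size)`.
Candidate covariate sets (none, visibility, log group size, both) are fitted
by maximum likelihood of the truncated density and compared by AIC; the
lowest-AIC model is retained per species.

**Effective strip half-width.** `esw = σ √(π/2) · erf(w / (σ√2))`, which
tends to `σ√(π/2)` as `w → ∞`.

**Abundance.** Horvitz–Thompson per segment: each detected group of size
`s_i` contributes `s_i / p_i`, where `p_i = esw_i / w` is that observation's
average detection probability over the strip.  The surveyed area of a
segment is `2 w L` (L = segment length, default 450 m).

**Assumptions.** Certain detection on the line (g(0)=1), perpendicular
distances measured without error, groups detected as units, density uniform
with respect to the line within the strip.

## 3. Density surface model (`density_surface.DensitySmoother`)

A penalized Gaussian radial-basis smoother over segment midpoints plays the
role of a two-dimensional spline:

* knots: a `n_knots × n_knots` grid over the surveyed extent (default 7×7);
* basis: Gaussian RBFs with bandwidth set from the knot spacing, plus an
  intercept;
* response: segment abundance with `log(surveyed area in km²)` offset,
  quasi-Poisson (log link), fitted by penalized IRLS;
* smoothing parameter: chosen by generalized cross-validation (GCV);
* uncertainty: a sandwich (robust) coefficient covariance; per-cell CVs come
  from multivariate-normal coefficient draws (default 200) pushed through
  the exponential response.

Predictions are floored at zero and evaluated at the centres of the 100-m
analysis grid.  One surface is fitted per species × year.  For the sparse,
highly aggregated Fallow Deer, the pipeline additionally builds 3-year
moving-average composites (`moving_average_raster`), which stabilises the
surface at the cost of temporal resolution; the SEM then uses the composite
covering each cull year.

**Numerical note.** With ~7×7 knots the effective degrees of freedom under
GCV is ≈16, and the relative noise of a fitted flat field scales as
`≈ 2 √(edf / total count)`.  This rule sizes the package's own recovery
tests.

## 4. Buffer covariates (`features`)

For each cull record (x, y, year) and each radius `r ∈ {400, 450, 500, 550,
600}` m, the mean of every raster over the cells whose centres fall within
`r` is computed (`extract_buffer_mean`; cell membership by centre-in-disc on
the 100-m grid).  Covariates per row:

* `roe_density`, `muntjac_density` — individuals/km², annual surface of the
  cull year;
* `sqrt_fallow` — square root of the 3-year Fallow composite (the square
  root tames the strong right skew of an aggregated species);
* `arable_pct` — percent arable extent from the static habitat raster;
* `body_mass_kg`, `week`, `week_class` (0 for weeks 1–3, 1 for weeks 4–12;
  embryos become reliably detectable a few weeks into the window), `year`,
  `block`.

Eligibility: adult females with intact carcasses (mass ≥ 8 kg); fertility is
only defined inside the post-rut window (weeks 1–12), when embryos are
countable.  `transform_and_screen` centres/scales nothing by itself but
reports pairwise predictor correlations and flags |r| ≥ 0.7 pairs per radius
as collinearity warnings.

## 5. Piecewise SEM (`sem`, `mixedmodels`)

Four component regressions encode the causal graph (predictors in
parentheses; all density/habitat terms are buffer means at one shared
radius):

| component | response | family | candidate predictors | controls |
|---|---|---|---|---|
| `fertility` | twin vs single (binary) | binomial (logit) | body mass, arable, Roe, Muntjac, √Fallow | week class |
| `body_mass` | mass (kg) | gaussian | arable, Roe, Muntjac, √Fallow | week |
| `roe_density` | Roe buffer density | gaussian | arable, √Fallow | — |
| `muntjac_density` | Muntjac buffer density | gaussian | arable, √Fallow | — |

Random effects: candidate intercepts for forest block and year.  The
structure is chosen once per component by AICc over {none, block, year,
block+year} on the full fixed-effect model (`select_random_effects`) and
held fixed during model enumeration, so that AICc comparisons across
fixed-effect subsets are like-for-like.

**Mixed-model engines (in-repo).**

* Gaussian: maximum likelihood with the residual variance and fixed effects
  profiled out, leaving an optimisation over the log relative variance of
  each random factor.  The profiled deviance is evaluated from sufficient
  statistics (`XᵀX, Xᵀy, ZᵀX, Zᵀy, ZᵀZ, yᵀy, n`) via the Woodbury identity,
  so its cost does not grow with n inside the optimiser.  One factor:
  bounded Brent on log-variance in (−20, 12).  Two factors: Nelder–Mead,
  warm-started with a compact simplex when a previous solution is available.
* Binomial: Laplace approximation — penalized IRLS for the joint mode of
  fixed effects and random intercepts, then the Laplace log-likelihood; the
  variance parameters are optimised on top.

Fits were validated against `lme4` (R) on a fixture dataset: gaussian
log-likelihood, coefficients and variance components agree to ~1e-4;
binomial Laplace agrees to ~0.03 in coefficients and ~0.02 in
log-likelihood, reflecting known convention differences between Laplace
implementations.

**Derived quantities.** Marginal/conditional R² follow the
variance-partitioning convention (fixed-effect variance over total, with
the logit-link distribution variance π²/3 for binomial).  Standardised
coefficients are per-SD (binomial: per SD of the latent logit response).
`iq_effect` reports slope × interquartile range of the predictor.  The
residual correlation between the Roe and Muntjac component residuals
measures unexplained spatial association between the two species.

## 6. Multimodel inference (`mmi`)

For each component and each radius, every subset of the candidate predictors
(controls always included) is fitted.  For each model:
`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`.  Akaike weights
`w_i ∝ exp(−Δᵢ/2)` are normalised over the full candidate set.  The **85%
confidence set** is the smallest prefix of the weight-ordered models whose
cumulative weight reaches 0.85 (weights are then renormalised inside the
set).

**Averaging** (default "full"/zero-substitution): a predictor absent from a
model contributes β = 0 with se = 0, so the average shrinks rarely-selected
effects toward zero.  The unconditional standard error is
`Σ wᵢ √(seᵢ² + (βᵢ − β̄)²)`; CIs are ±1.96 unconditional SE.  Every table
additionally carries `natural_*` columns — the "natural" average over
containing models only, with its own CI — as the effect-size estimate
conditional on the predictor being active.  The two answer different
questions: the full average (and the `supported` flag built on it) is a
conservative screen robust to model-selection uncertainty; the natural
average is the consistent estimator of an active effect's magnitude (the
full average under-states a true effect by roughly its importance weight
whenever model weights split).  Predictor
importance is the summed weight of containing models.  The radii are treated
as one extra model dimension: the chain is run per radius and combined with
weights from the best (lowest-AICc) model per radius, giving a weighted mean
radius as a by-product.

**Uncertainty propagation.** Each of `n_iterations` (default 100) draws
replaces every density raster cell by a mean-preserving lognormal draw with
the cell's CV (`σ_ln² = log(1 + CV²)`; CV = 0 reproduces the cell exactly),
then reruns extraction → SEM → averaging.  Final tables report the mean over
iterations of the estimate and of the CI bounds, plus the 2.5/97.5
percentiles of the estimates.  A predictor is **supported** when it sits in
the 85% set and its propagated CI excludes zero.  Iterations that fail to
converge are dropped and counted; the run aborts if more than half fail.

**Effect-strength comparison.** Inter- vs intraspecific strength on
fertility is compared by Welch's t on |standardised coefficient| across
propagation iterations.

## 7. Demography (`demography`)

Female-only Leslie matrix, pre-breeding census, ages 1..`max_age` (default
12) with an absorbing plus-group.  First row `F_a = m_a · s_neonatal`
(embryo counts halved for an even sex ratio), sub-diagonal `P₁ =
s_yearling`, `P_a = s_adult`.  Defaults (illustrative, not site-specific):
fecundity 0.3 (yearling) / 0.72 (adult) female offspring, survival 0.55
(neonatal) / 0.75 (yearling) / 0.70 (adult), giving λ = 1.0396 and 6.4% of
the stable population aged ≥ 8 — the senescence-negligibility check.

**Numerical note.** The stable age distribution is computed by power
iteration on `A + I` (same eigenvectors as `A`, but aperiodic, so the
iteration converges even for cyclic or near-reducible life cycles) and
verified directly against `‖Av − λv‖∞ ≤ 1e-8·max(1, λ)`.  Dense
eigendecomposition is not trusted for the eigenvector: for near-reducible
Leslie matrices it can return a vector of an almost-degenerate eigenvalue.

## 8. Synthetic-data generator (`synthgen`)

`generate_world(SimConfig)` returns a `TrueLandscape` (block raster, arable
raster, true density rasters per species × year), transect segment tables,
distance-sampling observations and cull records.  Defaults emulate the
target study's shape: 14 forest blocks (mean 1,337 ha, SD 836), seven years,
492 adult female culls, ~20% mean buffer arable extent, mean densities 7.4
(Roe), 15.1 (Muntjac) and 1.2 (Fallow) per km² with Fallow concentrated in a
narrow southern band.

* Spatial fields = fixed large-scale gradients + Gaussian-filtered white
  noise; densities floored at 0.
* Muntjac responds to arable extent (`b_arable_muntjac`, default 4 /km² per
  unit fraction) and negatively to Fallow (`b_fallow_muntjac` = −0.15).
* Surveys: north-south transects every 500 m, 450-m segments, half-normal
  detection (σ = 60 m base) modified by visibility class and group size;
  counts are Poisson in the strip with thinning by g(d).
* Culls: body mass ~ Normal(13.7, 1.40) kg + block intercepts (SD 0.30) +
  `b_arable_mass` (default 1.3 kg per unit arable fraction); twinning ~
  Bernoulli on the logit scale with intercept at p = 0.64, week-class
  detectability effect, block/year intercepts, and configurable effects of
  each buffer covariate (standardised scale), all zero by default.  Every
  record carries its *true* buffer covariates (at 500 m) so recovery tests
  can compare against the generating truth.
* All randomness flows from `rng_seed` through per-stage `SeedSequence`
  substreams: identical configs are bit-identical, independent of call
  order.

**Scope and limits.** The generator reproduces the statistical structure the
estimators assume (it is a fidelity-to-the-model generator, not an
individual-based ecological simulation): no animal movement, no density
dependence over time, no spatial autocorrelation in cull placement beyond
the block structure, detection exactly half-normal.  Recovery experiments on
it therefore measure the statistical chain, not robustness to model
misspecification.

## 9. Recovery experiments (`recovery`)

`run_recovery_experiment` measures operating characteristics of the full
chain at the study's n = 492:

* `recovery_config()` programs exactly two effects — Muntjac → fertility
  (−0.4 on the logit scale per SD of true buffer density) and arable → body
  mass (+1.3 kg per unit fraction) — and zeroes every other candidate
  effect, *including* the arable → Muntjac habitat coupling.  Leaving that
  coupling on makes the Muntjac buffer collinear with arable extent, so the
  experiment would measure power under confounding rather than recovery of
  the stated effect (per-replicate full-model z-scores for the Muntjac term
  were observed to range from −1.7 to −4.5 with the coupling on).
* `null_config()` zeroes all candidate effects, to measure the false-support
  rate of the "supported" flag.
* Replicates run propagation on the **true** density surfaces wrapped with a
  nominal constant CV of 0.2, isolating the SEM/MMI chain from DSM smoothing
  error (which is tested separately).
* The two halves of the experiment use the two averaging conventions for
  what each measures.  Effect-size recovery (`sign_and_ci_rate`) evaluates
  the **natural**-average columns: on these designs the full-model per-SD
  estimate is unbiased (mean −0.368 vs programmed −0.4 across 10
  replicates, within one standard error of the mean), but the
  zero-substitution full average attenuates it by 30–60% whenever model
  weights split, so the natural average is the right estimand for "was the
  programmed effect recovered".  The false-support check (`support_rate`)
  evaluates the pipeline's conservative **full**-average `supported` flag —
  the natural CI is conditional on selection and anticonservative under a
  null, which is exactly why it is not used for support decisions.
* A caveat on the landscape-level components (species density ~ habitat):
  each replicate contains a single landscape realisation, and two
  independent smooth spatial fields have a nonzero *realised* correlation
  in any one realisation.  The regressions detect that realised
  association — correctly, in the descriptive sense — so the per-replicate
  "supported" rate for these components under a null generator is well
  above the nominal error rate even though the estimates are unbiased
  (signs balance and the mean estimate is ≈ 0 across replicates).  A
  single-landscape study cannot distinguish a realised habitat association
  from a structural one; this is an inferential limit of the design, not
  of the estimator.  The false-support bound is therefore checked on the
  individual-level components (fertility, body mass), where cull records
  are genuine replicates.

## 10. Problem sizes and runtime choices

Defaults in this package are its own choices, made to keep the full test
suite within a desktop-scale budget: 20 propagation iterations in the
acceptance script and recovery tests (100 in the pipeline default), 10
recovery replicates, 5 candidate radii, 7×7 DSM knots, 200 CV draws.
Increasing `n_iterations` tightens the propagated percentile intervals but
changes no interface.
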