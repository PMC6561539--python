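# Methods

`camsecr` implements the inference machinery for estimating the density of
a territorial, individually identifiable carnivore from a multi-array
camera-trap survey: stratified maximum-likelihood spatially explicit
capture-recapture (SECR) with covariates on detection and density, a
Bayesian multi-species occupancy model that summarises prey availability,
AIC-based model selection with 85% Wald intervals, and reporting-unit
derived quantities (density surfaces, home ranges).  A synthetic-data
module generates complete surveys with the same statistical structure so
that every stage is testable without field data.

## The SECR model

Each individual carries a latent activity centre *s*.  Detection at trap
*j* on a single daily occasion follows a half-normal encounter function

    p(s, j) = p0_j · exp(−d(s, j)² / (2 σ_j²)),

where `p0` is the baseline encounter probability at distance zero and σ
the spatial scale of movement.  Trap-level covariates enter through
`logit(p0)` and `log(σ)`.  Stations are pairs of facing cameras treated
as one *proximity detector*: at most one binary detection per individual
per day, and multiple photographs on one day collapse to a single 1.
Unequal effort is encoded in a per-station binary usage matrix.

Activity centres follow an inhomogeneous Poisson point process over a
discrete habitat mask (pixel centres at 500 m resolution, trap array
plus a 6 km buffer).  Pixel intensity is log-linear in pixel-level
covariates (elevation, distance to river, distance to reserve boundary)
and region-level covariates (array factor, prey encounter index), on the
log(individuals per hectare) scale.  The regional population size is
Poisson with mean Λ_r = Σ_g D(s_g)·a_g.

Arrays are modelled as independent strata (no individual was ever
recaptured across arrays in the kind of survey this emulates).  The full
Poisson-form likelihood for region *r* with *n_r* detected individuals is

    L_r = exp(−Σ_g λ_g p·(s_g)) · Π_i [ Σ_g λ_g Pr(ω_i | s_g) ] / n_r!

with p·(s) the probability of at least one detection anywhere.  Because
the encounter parameters are constant across occasions, the product over
occasions collapses to a binomial form in per-trap effort and detection-
day counts, which is what the implementation evaluates.

**Sex.**  Sex is a known individual class.  When `sex` appears in any
formula the likelihood stratifies each region into female/male groups
with shared non-sex coefficients; the density predictor then carries a
log(1/2) offset per group so the intercept keeps its total-density
meaning, and a male dummy where `sex` is in the density formula.
Individuals of unknown sex are excluded from sex-stratified fits with a
logged warning.  This avoids mixture machinery at the cost of assuming
an even sex ratio when sex is not modelled on density.

**Standardization.**  Continuous covariates are standardized to mean 0,
SD 1 pooled across all regions (each region contributes once), because a
single coefficient spans regions.  The (mean, SD) record is stored on
the fitted model and reused at prediction time.

## Numerical choices

* Optimizer: BFGS on the link-scale parameter vector from documented
  default starts — density intercept `log(n/area)`, logit p0 = −3, log σ
  from half the mean recapture distance (fallback 1500 m); objective
  tolerance 1e-8.  A finite-difference gradient can stall BFGS with a
  "precision loss" flag near the optimum, so the fit alternates with a
  derivative-free Nelder–Mead polish until the central-difference
  gradient is below 0.05 in every coordinate; that flat-gradient test is
  the convergence criterion.
* Standard errors: inverse of a central finite-difference Hessian
  (step 1e-4 on link scales).  A singular or non-positive Hessian yields
  absent SEs, never fabricated ones.
* Non-finite likelihood intermediates return a large penalty value so
  the optimizer can retreat; linear predictors are bounded (|log
  intensity| ≤ 50, |log σ| ≤ 30) for the same reason.
* Detection probabilities are clipped to [1e-300, 1−1e-12] before logs.
* Regions with zero detections are permitted and contribute only the
  no-detection term, with a warning.
* Degenerate inputs (zero-variance covariate, σ ≤ 0, usage outside
  {0,1}, detections where usage is 0) are rejected with messages naming
  the offender.

## Model selection and intervals

AIC = −2 logL + 2k; ΔAIC from the minimum; Akaike weights
exp(−ΔAIC/2), normalized over the supplied set; ties in AIC break on
the model id so ranking is input-order invariant.  Wald intervals are
estimate ± z·SE on the link scale; the default level is 85%
(z = 1.43953), the level compatible with AIC-based screening for
uninformative parameters.  A near-best model (ΔAIC ≤ 2) is flagged
"uninformative extra parameter" when it has exactly one parameter more
than the best, its extra coefficient's 85% CI covers zero, and
|Δ logL| < 1 — the "similar log-likelihood" clause is operationalized
as that unit bound.

## Derived quantities

Density is fitted per hectare and reported per 100 km² (×10⁴).  Mean
density is exp(β₀)·10⁴ — density at the mean of the standardized
covariates — with the interval obtained by exponentiating the Wald
bounds of β₀.  Per-array σ comes from the array-factor σ model,
σ_a = exp(δ₀ + δ_a).  The 95% home range of the bivariate-normal
space-use model is π(σ√5.99)² with σ in km; 5.99 is the 0.95 quantile
of the χ² distribution with 2 df (kept symbolic, evaluated in full
precision, rounded only for display).  The mean home range averages the
per-array areas rather than transforming a mean σ: with these published
estimates area-averaging yields 66 km² at integer rounding, matching
the reported summary.  Home-range uncertainty, where needed, is
propagated on the log-σ scale and transformed.

## The occupancy model and the prey index

Presence of prey species *i* at station *j* is z_ij ~ Bern(ψ_ia(j)) with
logit(ψ_ia) = β_ia ~ Normal(μ_ψ,a, σ_ψ): an array-specific community
mean with between-species heterogeneity.  Detections are
y_ij ~ Bin(k_j, p_i z_ij) with logit(p_i) = α_i ~ Normal(μ_p, σ_p); the
per-station effort k_j (12–49 days) absorbs camera failure.  Hyperpriors
(not dictated by the problem, chosen as weakly-informative standards for
logit-normal community models): μ ~ Normal(0, 1.5²) on the logit scale,
σ ~ Uniform(0, 5), and γ ~ Normal(0, 1.5²) for the optional effect of
standardized boundary distance on logit-occupancy.

The sampler is Metropolis-within-Gibbs: z from its exact full
conditional (1 wherever y > 0); β_ia and α_i by elementwise random-walk
Metropolis; μ_ψ,a and μ_p by conjugate normal updates; σ_ψ, σ_p and γ by
random-walk Metropolis.  Proposal scales adapt every 100 burn-in
iterations toward ~37% acceptance and are then frozen; acceptance rates
outside (1%, 99%) trigger a warning but draws are still returned.
Chains are seeded deterministically from the spec seed, so identical
configurations reproduce identical draws.  Library defaults are 3
chains × 20,000 iterations (10,000 burn-in, thin 10); the test suite
and acceptance script use shorter, seeded runs (1 chain, 3,000
iterations) that mix adequately for this conjugate-heavy model.

The *prey encounter index* is the posterior mean of inverse-logit
(μ_ψ,a) per array — community mean occupancy.  Because "mean estimated
occupancy" is also readable as a species average, the across-species
mean of inverse-logit(β_ia) is emitted alongside, and downstream code
may use either; the hyper-mean definition is the primary one.

## The synthetic-data generator

Defaults are the study conditions this package emulates: 6 arrays of
25–34 stations on a jittered regular grid at 1.6 km spacing (jitter
uniform within ±10% of spacing, to avoid perfectly collinear designs);
per-station contiguous operating spans of 12–49 days (mean ≈ 31);
density 4.22/100 km² with a log-linear boundary-distance effect of
0.44; logit p0 intercept −3.39 with a river-distance effect of −0.21;
log σ intercept 7.517 with array offsets spanning σ ≈ 1.15–2.44 km; an
even sex ratio; and an 18-species prey community with logit-normal
heterogeneity (σ_ψ = 0.8, σ_p = 0.5) around array hypermeans of
0.40–0.65 occupancy and 0.30 detection.

Geometry is synthetic: the reserve boundary is the western edge of each
array's buffered bounding region and rivers are 1–3 random polylines,
which preserves the covariate gradients the models need without any GIS
input; elevation is a smooth plane-plus-hills field.  Activity centres
are drawn per pixel from the Poisson intensity and placed uniformly
within the pixel (the continuous process the mask discretizes), and the
truth object retains undetected individuals for recovery tests while
the observed files are detected-only.

What the generator does **not** emulate: real topography or hydrology,
spatial autocorrelation of prey beyond the array level, behavioural
responses to traps, open-population turnover, misidentification.
Passing recovery tests therefore demonstrate correctness of the
estimator under the model's own assumptions at the study's sampling
intensity — not robustness to the ways real data violate them.

Emergent quantities are approximate by construction: with all generating
parameters at the study-scale values the simulated surveys yield ~45
detected individuals on average (the real survey detected 58), because
detected counts also depend on unreproducible array geometry.  Per-array
counts (≈ 4–11) bracket the reported median of 10 (range 5–15).

## Problem sizes used by the tests and acceptance script

Recovery experiments use the full six-array design at 500 m resolution
(the native mask) in the acceptance suite, and a 1 km mask in the
acceptance script's replicate block; the 1 km mask quarters the pixel
count at the cost of a small discretization bias in σ (about −0.08 on
log σ), which is why the suite prefers the native resolution.  The
occupancy experiments use 18 species × 150 stations (6 arrays × 25).

## Known limitations

* Wald intervals on the array-level log-σ parameters undercover
  slightly (≈ 88–93% at nominal 95% across simulation blocks) because
  several arrays average only 4–5 detected individuals, making the σ
  contrasts heavy-tailed; density and encounter parameters are at
  nominal coverage.  Profile or bootstrap intervals would improve this
  but are out of scope.
* Euclidean distance only; no least-cost or non-Euclidean movement.
* Closed populations within a session; no telemetry integration; no
  Bayesian SECR.
* The occupancy model fixes species richness at the observed species
  list (no data augmentation) and excludes array-specific detectability
  by design.
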