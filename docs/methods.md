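# Methods

## The normative model

For each cognitive test the response y (the raw score; the natural log
of the completion time for TMT-A/B, which are strongly right-skewed) is
modelled as Gaussian around an additive predictor:

    y_i = α + f_age(age_i) + f_edu(edu_i) + γ·female_i + λ_{lang(i)} + ε_i,
    ε_i ~ N(0, σ²),   λ_EN = 0.

The linear baseline (LMR) replaces the two smooths with linear terms.
In the additive model (GAM) each smooth is a cubic B-spline with 8
basis functions and a second-order difference penalty, written in
mixed-model form: the penalty null space (constant + linear trend)
stays among the unpenalized fixed effects, and the penalized part
Z = B D′(DD′)⁻¹ carries i.i.d. N(0, τ²) weights, where D is the
second-difference operator. This is an exact reparameterization of the
usual P-spline and keeps every full conditional Gaussian or
inverse-gamma. Interior knots sit at quantiles of the training data, so
the sparsely observed tails of the age and education distributions get
wide outer intervals and a correspondingly stiff fit; equally spaced
knots were noticeably wigglier at the education boundary.

The drop-one candidate set per test is {LMR, GAM} × {all four
predictors, minus age, minus education, minus gender, minus language} —
ten fits, compared by PSIS-LOO (below).

### Priors

- slope/offset coefficients (age, education, gender, language): improper
  flat priors;
- intercept: wide Gaussian centered on the response median with SD equal
  to 10 × the response SD. A heavy-tailed location prior would behave
  identically here; the Gaussian keeps the coefficient update exactly
  conjugate;
- residual scale σ and each smoothing scale τ: half-Student-t with 3
  degrees of freedom, scaled to the response SD. The half-t is wide
  enough to act as a default yet proper, which the smoothing scales
  need.

### Sampling

Both families are conditionally conjugate, so the posterior is drawn by
a blocked Gibbs sampler:

1. each smoothing scale τ is slice-sampled from its *collapsed*
   conditional p(τ | y, σ², τ₋) with all regression coefficients
   integrated out analytically (one small Cholesky per density
   evaluation). Updating τ conditionally on the spline weights mixes
   slowly because the two are strongly coupled; the collapsed update
   gives essentially independent τ draws (lag-1 autocorrelation ≈ 0.1).
   The collapsed density is verified in development against a direct
   Gaussian-marginal computation;
2. all regression coefficients jointly from their multivariate-normal
   full conditional (a single p×p Cholesky, p ≈ 25 for the full GAM);
3. σ² from its inverse-gamma full conditional, with the half-t prior
   expressed through the standard inverse-gamma scale mixture.

Because the coefficient block is redrawn jointly every sweep, the chain
mixes close to i.i.d. and modest chain lengths suffice. Two profiles
are built in: the **desk profile** (default; 2 chains × 1000 iterations,
500 warm-up, 1000 retained draws) used throughout the test-suite, and
the **study profile** (4 × 2000, 1000 warm-up, 4000 retained draws)
matching the published sampler configuration. Convergence is checked
with split-R̂ (pass: max < 1.01 over all parameters); the sampler has
no divergent transitions by construction, but the report keeps the
field so diagnostics read uniformly. Every fit stores its pointwise
log-likelihood matrix (draws × observations).

## Model comparison

Expected out-of-sample predictive accuracy is estimated by
Pareto-smoothed importance-sampling leave-one-out cross-validation on
the stored log-likelihood matrix; models are ranked on
LOO-IC = −2·elpd_loo. Two models fitted to the same observations are
compared through the paired per-observation elpd differences: the SE of
the difference is √n × sd of the pointwise differences, the 95 % CI is
the normal ±1.96·SE interval (the comparison rule states a 95 % CI
without a formula; the normal interval is the conventional reading),
and a difference is significant when that CI excludes zero.
Observations with Pareto k̂ ≥ 0.5 are counted and reported, not refit.
Within the ladder, the minimum-LOO-IC model is *best*; among candidates
not significantly worse than the best, the simplest (fewest predictors,
linear before additive) is *selected* — parsimony affects only which
tied model is reported.

## Normative mapping

The predictive distribution at demographics d has mean
μ̂(d) = E[x(d)′β] and variance sd_pred²(d) = Var[x(d)′β] + E[σ²], i.e.
coefficient uncertainty plus residual noise (a plug-in σ is available
for sensitivity checks but the predictive SD is the default, following
normative-probability-mapping practice). Then

    z = (transform(raw) − μ̂(d)) / sd_pred(d),

multiplied by −1 for the timed TMT tests *after* the log transform —
flipping before a monotone transform would be wrong. Percentile
= 100·Φ(z). Bands: z < −2 "markedly below (red)", −2 ≤ z < −1 "below
(orange)", −1 ≤ z ≤ 1 "normal (green)" (both endpoints inside, matching
the within-one-SD reading of normal), z > 1 "above (blue)". The −2/−1/+1
thresholds are this package's convention; the hosted calculator's exact
color cut-offs are unpublished.

Lookup tables evaluate μ̂/sd_pred on a dense grid (ages 18–86,
education 1–24, both genders, ten languages) and score by rounding age
and education to the nearest grid node — table semantics rather than
interpolation. The default grid step is 0.25 years: fitted edge slopes
of several raw points per year occur where the training data thin out,
and a 1-year grid leaves nearest-node errors up to ≈ 0.1 z there, while
0.25 years keeps the error below 0.05 z everywhere and the mean error
(over demographics drawn from the population the norms serve) near
0.005. Demographics outside the grid hull are refused with the valid
ranges; model-based scoring flags (rather than refuses) extrapolation
beyond the training range.

## Synthetic cohorts

Real Enroll-HD data are controlled-access, so the generator emulates
the published study conditions:

- **age**: truncated normal on [18, 86] whose *post-truncation* mean
  and SD are moment-matched (numerically) to 46.99 / 14.61. Sampling
  uniformly within the printed age bands would not reproduce the
  printed mean; the band frequencies are kept only for cross-checks;
- **education**: truncated normal on [1, 24] matched to 14.66 / 3.27;
  ISCED levels are derived from years by a documented convention and
  are descriptive only;
- **gender**: Bernoulli, 60.5 % female; **language**: categorical at
  the published frequencies (English 55.3 %, German 19.6 %, …),
  independent of age/education by default since no cross-tabulation is
  published — an assumption, flagged as such; a per-language age shift
  is available for robustness experiments;
- **scores**: Gaussian around the additive truth (log-normal for TMT),
  clipped to the admissible score ranges with clip counts logged
  (< 1 % per test under defaults). The truth curves are closed-form so
  oracles stay exact: age decline is a negative quadratic in decades
  past age 35 (accelerating late decline), education gain a saturating
  exponential (concave, diminishing returns). Gender and language
  offsets default to the published posterior means; total declines
  between 35 and 86 are calibrated per test so that population
  raw-score moments resemble the published descriptives. Residual SDs
  are roughly 80 % of the published total SDs (e.g. SDMT 10); TMT
  residual scales are on the natural-log scale (log base is a free
  choice up to rescaling — natural log throughout);
- **screening violations** (high HADS, low MMSE, non-native testing,
  uncorrected vision/hearing, missing education) are planted
  independently at configurable rates, with marker columns so expected
  attrition is computable exactly.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: item-level structure, floor/ceiling
score discreteness, practice effects, within-language demographic
differences, missingness that depends on ability, and any
ethnicity/handedness effects (collected but never modelled). Recovery
results show the pipeline is correct under its own assumptions, not
that the published coefficients are right.

## Problem sizes and test conditions

The suite fits at desk scale: session fits use n = 1500–3000 with the
desk sampler profile; parameter-recovery targets use n = 3000 (matching
the recovery checks' stated conditions); the GAM-vs-LMR separation
check runs 20 replicates at n = 800 on a *strongly nonlinear* truth,
defined a priori as an SDMT-like curve whose best-linear-fit misfit SD
is about half the residual SD (age decline 1.6 points per squared
decade, σ = 5) — the study-calibrated default curvature is too mild to
separate the families at that n, which is itself informative. The
exact-LOO oracle refits n = 50 cohorts one observation at a time.

## Numerical choices and edge cases

- Coefficient draws use a Cholesky solve of the full conditional
  precision; continuous linear terms are centered at their training
  means for conditioning.
- The slice sampler for log τ uses stepping-out with unit width on
  [−12, 12] (τ between e⁻¹² and e¹²).
- Ties/degeneracies: a zero-variance response sets the internal scale
  reference to 1; point-mass generator configs are allowed (SD = 0);
  empty cohorts yield empty norm tables, not errors; norm-table cells
  with n < 2 report SD as NaN; sample SDs use the n−1 denominator
  throughout.
- Age bands for table norms are the study's ten bands read as
  left-closed right-open ([18,25), [25,30), …, [65,87)) because the
  printed labels overlap at their edges; education dichotomizes with
  12 years in the lower band.
- HDI is the shortest window of ⌈level·n⌉ sorted draws and requires at
  least 100 draws.
- Rows missing a test's score are dropped test-wise, so per-test Ns
  differ, as in the source cohort. Rows with missing HADS/MMSE are
  retained by default (exclusion is on evidence of depression or
  impairment, not on missingness); a strict mode drops them.

## Known limitations

- "Tensor splines" in the source description is under-specified; this
  package implements additive univariate smooths (matching the stated
  additivity). A tensor-product age×education interaction is not
  implemented.
- The two source datasets' complete-battery sizes are printed
  inconsistently (N = 1173 in the flow-chart caption vs N = 2173 in
  the text); nothing here depends on either value.
- Language levels with few training observations (< 50 by default)
  produce warnings, not refusals; their offsets are wide.
- The Gibbs sampler covers Gaussian likelihoods only — adequate for
  this battery's modelling, not a general regression engine.
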