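# Methods

## Model

`respstyle` fits a constrained multidimensional nominal response model
(MNRM) to persons × items Likert data. Each item's K categories follow
a multinomial logit in the latent traits,

    P(U_j = k | θ) ∝ exp(Σ_d a_jkd θ_d + c_jk),

with three kinds of constraint:

* **Substantive slopes fixed.** Each item loads only on its own scale's
  dimension with the equally spaced category-slope vector
  (−1, −0.5, 0, 0.5, 1). This makes each subscale behave like a
  multidimensional partial-credit model and pins the latent metric, so
  the latent variances are not free quantities.
* **ERS slopes fixed.** When the style dimension is included it loads on
  *every* item with slopes (0.75, −0.5, −0.5, −0.5, 0.75). The equal
  positive endpoint values and negative middle values encode the
  construct: θ_ERS moves mass symmetrically to the two extreme
  categories regardless of content or of the substantive trait level.
* **Intercepts effect-coded.** Σ_k c_jk = 0 per item. This matches the
  packaged published estimates, whose rows sum to ≈0 at printed
  precision; `effect_coded_from_baseline` converts parameters identified
  by a baseline category instead.

Identification fixes all latent variances to 1 and leaves the
correlations free (estimable because the slopes are fixed). A
consequence worth knowing: the ERS dimension cannot shrink itself out
of the model — on data with no style variance the four-dimensional
model is simply worse than the three-dimensional one by every
information criterion, which is the behaviour the model-comparison
stage relies on. An ERS *variance* parameter would be identified under
fixed slopes but is deliberately not part of this parameterisation.

## Estimation

Penalised marginal maximum likelihood via EM:

* **Quadrature.** Probabilists' Gauss–Hermite rules, normalised weights,
  tensor product over dimensions, rotated by the Cholesky factor of the
  current correlation matrix. Default 10 nodes per dimension; the
  four-dimensional benchmark fits in this repository use 5 nodes per
  dimension (625 grid points), which on this model class (bounded fixed
  slopes, 36 items) reproduces intercepts to well within the recovery
  tolerances. A per-person **adaptive** variant (grid recentred at the
  Laplace mode with the local curvature, with a fallback to the prior
  scale when the curvature is not positive definite) is implemented for
  likelihood evaluation, where it reaches ~1e−4 absolute accuracy at 10
  nodes; the EM engine itself uses the fixed rotated grid because the
  shared grid lets the E-step and the per-item expected counts be
  computed by dense linear algebra across all persons at once.
* **Prior.** Independent normal(0, σ² = 9) on every effect-coded
  intercept (σ exposed as `prior_sd`). Its role is to keep intercepts of
  rarely or never observed categories off the boundary; items with a
  never-observed category are flagged on the fitted object. The reported
  objective is log-posterior = log-likelihood + log-prior, with the full
  normal log-density (constants included).
* **M-step.** With slopes fixed, the expected complete-data objective
  separates into one strictly concave (K−1)-parameter multinomial-logit
  problem per item, solved to convergence by Newton iterations with step
  halving in the sum-to-zero basis. The correlation matrix is updated
  from the posterior-weighted second-moment matrix rescaled to unit
  diagonal. That rescaling is a moment approximation, not an exact
  ascent step; if it ever decreases the objective (which happens only in
  the last refinement stages) the update is reverted and the
  correlations frozen, after which monotonicity is exact. The iteration
  trace is checked non-decreasing to 1e−8 in the tests.
* **Convergence.** Relative log-posterior change < 1e−7 *and* maximum
  absolute parameter change < 1e−5 (both configurable); hitting
  `max_iter` returns `converged=False` with a warning instead of
  raising.
* **Parameter count.** (K−1) free intercepts per item plus one per free
  correlation: 147 for the three-dimensional model and 150 with ERS on
  the 36-item battery. Criteria: AIC = −2LL + 2p, AIC3 = −2LL + 3p,
  BIC = −2LL + p ln n, CAIC = −2LL + p(ln n + 1), n = persons.

## Scoring

EAP scores are posterior means over the (rotated) quadrature grid;
posterior SDs come from the grid second moments. The scoring grid
defaults to the estimation resolution but takes an independent
`nodes_per_dim` refinement. Plausible values sample a grid node from
the posterior weights and jitter it uniformly within the node's
one-dimensional quadrature cells (in standardised space, mapped through
the correlation Cholesky); the jitter prevents draws from collapsing
onto the abscissae but adds within-cell noise of order (node
spacing)²/12 — draw plausible values on at least ~7 nodes per dimension
when they feed a downstream regression. Randomness: one root seed,
independent spawned substream per person, recorded in the output.

The draws condition on item responses only, not on downstream outcomes.
This is the classical "secondary analysis" caveat: a regression on such
draws is attenuated by the posterior-spread factor
cov(PV, θ)/var(PV) ≈ var(EAP), whereas an EAP used as a fixed covariate
is nearly slope-unbiased but understates uncertainty. The package
supports both and the survival comparison reports both.

## Sum-score bias

ES(θ, θ_ERS) sums the expected item scores of one subscale with all
other substantive traits at 0 (the ERS slopes make other traits
irrelevant to the subscale anyway, since off-scale substantive slopes
are zero). BIAS(θ, θ_ERS) = ES(θ, θ_ERS) − ES(θ, 0). Two anchors of the
bias-curve family are computed:

* the **crossing point**: root of mean expected item score = (K+1)/2,
  by bracketed bisection to 1e−6;
* the **intersection point**: the θ minimising max over style levels of
  |BIAS|, i.e. the family's common zero, by grid scan plus bounded
  scalar minimisation.

On the packaged Neuroticism estimates these are 1.906 and 1.588. They
are conceptually distinct and need not coincide: at the midpoint root
the +2 style curve has already risen to ≈0.7 sum-score points, while at
the intersection the whole family is within ≈0.01 of zero. Accounts
that describe both as "approximately 1.8" are reading a figure at its
resolution. Both numbers are reported side by side in every output.

## Survival propagation

Competing risks (disease of interest = 1, death = 2) are handled by
cause-specific Cox partial likelihood: other causes are censored at
their event time. Fitting is delegated to lifelines (Efron ties); this
package owns the censoring construction, the pooling, and diagnostics.
Per-draw estimates from plausible values are combined by Rubin's rules
(total variance W + (1 + 1/m)B, t reference with
df = (m−1)(1 + W/((1+1/m)B))²; m = 1 returns the single fit flagged
unpooled). Cox–Snell residuals are the estimated cumulative
cause-specific hazards at each subject's time; the diagnostic slope is
a through-the-origin fit of the residuals' Nelson–Aalen curve against
the 45° line, trimmed at the 0.9 event quantile because the upper tail
of a Nelson–Aalen estimate is noise.

The three-predictor comparison (raw subscale sums, EAPs from the model
without ERS, plausible values from the ERS model) keeps each predictor
on its native metric by default, mirroring the design of published
comparisons: the raw-score coefficient is per sum-score point. Because
one unit of trait corresponds to several sum-score points, per-point
raw coefficients are structurally far below a per-trait-unit truth —
that, plus ERS contamination of the raw sum, is the attenuation the
package demonstrates. With `standardize_raw=True` the raw sums are
z-scored instead; note that this removes the scale penalty and the
standardized raw score then attenuates only by cor(sum, θ), which can
be *less* attenuation than plausible values carry (see the scoring
caveat above).

## Synthetic data

The generator emulates the study design the model assumes:

* latent traits for 3 scales × 12 items, K = 5, multivariate normal
  with unit variances; default correlations (N, A, C) of −0.25 (N–A),
  −0.30 (N–C), +0.30 (A–C) — plausible magnitudes for these constructs;
  ERS uncorrelated with content by default (its defining property),
  with an `ers_sd` multiplier (default 1, i.e. full style variance; 0
  gives style-free data);
* item parameters default to the packaged NEO-FFI estimates so
  synthetic items reproduce the published response behaviour (e.g. the
  category-2 dominance of Neuroticism items at θ = 0); a `random`
  source with configurable intercept dispersion exists for generic
  tests;
* responses drawn categorically from the model probabilities;
* competing-risks follow-up: exponential cause-specific hazards
  (disease 0.03/yr, death 0.05/yr at baseline), administrative
  censoring at 20 years, covariates age ~ N(73.81, 6.71²), 30% male,
  education ~ N(18.42, 3.36²) clipped to [3, 30], matching the cohort
  the packaged item estimates come from; default log-hazard ratios
  (centred age 0.134, male 0.05, centred education 0.04, θ_N 0.2) on
  disease and (0.09, 0.40, −0.02, 0) on death, magnitudes in line with
  reported associations for incident dementia in such cohorts.

Everything is reproducible from (config, seed) via spawned substreams;
bundles regenerate byte-identically. What the generator does *not*
emulate: longitudinal waves, acquiescence or other non-ERS styles,
item-level variation in ERS susceptibility, DIF, non-normal latent
distributions, and informative censoring beyond the death channel — so
passing tests demonstrate internal consistency of the method under its
own assumptions, not robustness to these violations.

## Benchmark problem sizes

The deeper checks in `tests/test_acceptance.py` run at reduced but
statistically adequate sizes: parameter recovery fits n = 2000 at
5 quadrature nodes per dimension (intercept recovery r ≈ 0.997,
RMSE ≈ 0.20 against the generating values); model selection fits both
models at n = 1000 with and without style variance; the attenuation
experiment uses 10 replicates of n = 500 with 5 plausible-value draws
each. The bias and criteria identities are exact-scale computations on
the packaged estimates.

## Known limitations

* Free (per-item estimated) category slopes are out of scope; only the
  fixed constraint structures above are supported.
* No standard errors for item parameters (no information matrix,
  bootstrap or MCMC).
* BIC/CAIC use n = number of persons; software packages differ in the
  effective n convention, so cross-package BIC comparisons need care.
* Plausible values ignore item-parameter uncertainty (draws are from
  the θ posterior at the point estimates).
* The EM engine's fixed-grid quadrature is accurate for bounded fixed
  slopes and moderate dimension counts; models far outside that regime
  should increase `nodes_per_dim` and verify against the adaptive
  likelihood evaluator.
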