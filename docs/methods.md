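# Methods

## Model

The path model is a directed acyclic graph over nine observed subject-level
variables: age (years), sex (0 = female, 1 = male), metabolic syndrome MS
(0/1), type 2 diabetes T2DM (0/1), PTH (pmol/l), 25-OH vitamin D (nmol/l),
magnesium (mmol/l), albumin-corrected calcium (mmol/l) and phosphate
(mmol/l). Every endogenous node carries one regression equation on its
parents: Gaussian with homoscedastic residual for continuous nodes (PTH,
calcium), Bernoulli with logit link for binary nodes (MS, T2DM). There are
no latent variables, and residuals are independent across equations, so the
joint likelihood factorizes over equations; the sampler exploits this with
per-equation updates while the reported posterior is the joint one.

Sex enters as an edge-level moderator rather than a network node: a
moderated edge has a female-reference coefficient plus a male-offset
parameter, implemented as a `predictor × male` interaction column. There is
deliberately no male main-effect term in any equation — the moderated final
model is parameterized exactly as its published counterpart, which reports
gender differences on four paths but no male intercept shift. Continuous
variables are standardized before fitting (sample SD, n−1), so coefficients
are per-SD effects; binary variables stay 0/1.

Two builders encode the scientific hypotheses. The *initial* model carries
all literature-suggested paths (seven direct predictors of MS; five
regulators of PTH; vitamin D and phosphate into calcium; age and magnesium
into T2DM). The *final* model is the pruned, sex-moderated structure (12
edges, 4 moderated) retained after the selection procedure below.

## Mediation arithmetic

Indirect effects along pathways whose intermediate nodes are all continuous
are products of edge coefficients; total effects are direct + Σ products.
A binary *terminal* outcome is allowed (the product reads as a log-odds
effect); a binary *intermediate* makes the product meaningless (linear and
logistic coefficients live on different scales), so such pathways are
excluded from sums, carried as "non-quantifiable", and contribute only to
the qualitative classification. An indirect route counts as significant for
a sex iff every edge on it is significant for that sex (joint-significance
rule); no credible intervals are computed for products terminating at MS in
the classification, matching how such tables are conventionally built.
Point estimates are posterior means; in draws mode the sums/products are
applied per draw, which for pure sums (male effect = reference + offset)
commutes exactly with averaging, and for products differs from the
product-of-means by a posterior-covariance term (both are available).

Natural-unit reporting rescales standardized draws: β·SD_y/SD_x for linear
paths, exp(β/SD_x) per-unit odds ratios for logistic paths. A raw-scale
refit is possible by passing unstandardized data through the same equations,
but SD-rescaling is the default and is the route verified by tests.

## Priors, sampler, diagnostics

Priors are weakly informative on the standardized scale: Normal(0, 10²) for
every coefficient and intercept, half-Cauchy(0, 5) for residual SDs. At
n ≈ 10³ these reproduce maximum-likelihood-like estimates (verified against
OLS/logistic-ML oracles in the tests); the contract is distributional, not
tied to any particular MCMC engine.

- **Linear equations**: Gibbs sampling — the coefficient block has a
  conjugate Gaussian full conditional given σ; σ is updated by random-walk
  Metropolis on log σ (step size adapted toward 44% acceptance during
  burn-in only).
- **Logistic equations**: adaptive random-walk Metropolis on the full
  coefficient vector. The proposal covariance starts at the inverse Hessian
  of the log-posterior at its mode (found by Newton iteration), is adapted
  to the empirical chain covariance (scaled 2.38²/p) during burn-in, and is
  frozen at the end of burn-in so the kept draws come from a fixed-kernel
  chain.
- **Initialization**: chain c starts at the posterior mode plus
  c × (posterior-SD-scaled) Gaussian noise. This keeps chains overdispersed
  relative to the posterior — so the EPSR diagnostic is meaningful — while
  letting a random-walk sampler reach stationarity well inside the default
  5,000-iteration burn-in; starts drawn from the full prior scale (SD 10)
  would strand the walk in flat-likelihood regions for the 8-parameter MS
  equation.

Defaults are 3 chains × 10,000 iterations with 5,000 burn-in and no
thinning. Convergence is summarized by the potential scale reduction
(Gelman–Rubin) per parameter, R̂ = sqrt(((n−1)/n·W + B/n)/W); a fit with any
R̂ > 1.1 is returned but flagged non-converged. Model fit is the deviance
information criterion DIC = D̄ + pD with pD = D̄ − D(θ̄) (deviance = −2 ×
log-likelihood, priors excluded), reported per equation and in total;
deviances over draws are evaluated in chunks with the linear-equation SSR
computed from sufficient statistics. Credible intervals are equal-tailed
percentiles (not HPD); "significant" means the 95% interval excludes zero.

## Synthetic cohorts

The generator simulates on the standardized scale in topological order and
de-standardizes at the end:

- **Exogenous continuous variables** are independent Gaussians truncated to
  physiologic ranges (age 18–75 y; biomarkers bounded away from 0) and then
  renormalized by the truncated distribution's own mean/SD, so the declared
  marginal moments are matched exactly in expectation despite truncation.
  Defaults: age 42 (12), vitamin D 52 (22), magnesium 0.84 (0.07), phosphate
  1.09 (0.17); an optional sex-specific mode reproduces by-sex marginals
  (e.g. phosphate 1.10 women vs 1.06 men). No exogenous correlations are
  simulated — the model treats non-adjacent variables as independent, and no
  empirical covariance structure is available to calibrate against; this is
  an assumption, not a data statement.
- **Continuous endogenous variables** are Σ β·z_parent (+ male offsets) plus
  a Gaussian residual whose SD is solved so the marginal z-variance is 1
  (total = explained + residual), then mapped to natural units (calcium
  2.35 (0.07), PTH 5.8 (2.3)); a centering intercept keeps the marginal mean
  on target under moderation.
- **Binary endogenous variables** are Bernoulli(logistic(c + lp)) with the
  intercept c calibrated by monotone root-finding so the simulated marginal
  prevalence hits its target (MS 68.1%, T2DM 25%) to 1e-6 on the calibration
  sample.

Calibration constants (residual SDs, centerings, intercepts) are solved on a
large pilot sample (10⁵ draws) from a seed-derived stream, then frozen for
the production draw, so a fixed seed gives bit-identical cohorts and the
constants carry ~10⁻³ Monte-Carlo error. One emergent, untargeted check:
with the strong diabetes→MS coefficient (3.47) and the calibrated
prevalences, the simulated P(MS | T2DM = 1) comes out ≈ 98%, matching the
reference population.

What the generator does *not* emulate: exogenous correlations (above),
missingness (cohorts are complete-case by construction; the reader applies
the complete-case filter to real files), measurement error, and the raw MS
component criteria (waist, lipids, BP, glucose) — MS enters as a coded 0/1
variable. Passing tests therefore demonstrate correctness of the machinery
under the declared data-generating process, not robustness to real-data
violations of it.

## Model selection

1. **Sex-stratified screen**: the un-moderated model is fitted separately to
   women and men; an edge is flagged when either sex's 95% CrI excludes the
   other sex's posterior mean. The original screening judgment was informal;
   this rule is an explicit, configurable proxy, and on cohorts simulated
   with the default offsets it flags exactly the four generating moderated
   paths (see `examples/05_model_selection.py`).
2. **Moderation**: male-offset parameters are added on flagged edges of the
   pooled model.
3. **Pruning**: one pass removes direct edges whose coefficient CrI covers
   zero (and demotes non-significant moderation terms), with a keep-list for
   edges/moderations retained on DIC grounds despite a null-covering
   interval, and a guard that never leaves an endogenous equation without
   predictors. Competing stages are ranked by DIC computed on the identical
   cohort (enforced by checksum).

## Numerical choices and problem sizes

- Intercept calibration: Brent root-finding, tolerance 1e-9, bracket grown
  geometrically; degenerate (non-finite) predictor samples raise.
- Residual-SD floor 1e-3 on the z scale guards configs that explain ~all
  marginal variance.
- Near-collinear designs (condition number > 1e10) trigger a warning, not an
  error; zero-variance columns raise at standardization.
- Test-suite problem sizes are scaled for quick iteration: short chains
  (≈1,200–1,500 iterations) where only distributional behaviour matters,
  n = 500 cohorts and 20 replicates for the coverage study, 40 replicates of
  n = 150 single-equation fits for the nested-DIC ordering study; the
  recovery acceptance test and the acceptance script use the full default
  configuration (n = 971, 3 × 10,000/5,000).
- The DIC ordering study asserts the smaller of two nested models wins in
  ≥ 75% of replicates: with three spurious coefficients the theoretical win
  rate is P(χ²₃ < 6) ≈ 0.89, so a higher bar would fail by chance alone.

## Known limitations

- Absolute DIC values are data-dependent and not comparable across cohorts;
  only within-cohort differences are meaningful (the ranking enforces this).
- The single-cohort recovery experiment at n = 971 carries cohort-level
  sampling spread comparable to the posterior SD (≈ 0.08 for the PTH→MS
  coefficient), so any one seed's posterior mean scatters around the
  generating value with that SD; across replicates the estimator is
  unbiased and 95% CrI coverage sits at the nominal level.
- Path coefficients quantify conditional associations under the assumed
  graph; nothing here licenses causal claims, and alternative arrow
  orientations would change the decomposition.
- The moderated logistic equations estimate female-reference coefficients
  mostly from the female subsample; with heavy class imbalance or tiny
  subgroups the adaptive Metropolis can need longer chains (the
  non-convergence flag reports this).
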