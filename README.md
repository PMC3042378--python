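# pthpath

Bayesian path analysis of parathyroid hormone (PTH) as a mediator of the
metabolic syndrome (MS) in morbidly obese patients — implemented as a
reusable, tested Python library.

## The problem

Clinical studies of MS usually fit one regression with MS as the outcome.
But several proposed predictors of MS (vitamin D, magnesium, calcium,
phosphate) are *also* regulators of PTH secretion, and PTH itself is
associated with MS — so a variable can act on MS both directly and
indirectly, through PTH. Path analysis handles this by combining several
regression equations into one model in which a variable may be outcome and
predictor at once. Here the system is four linked equations over nine
observed subject-level variables:

- **MS** (binary, logistic): ← T2DM, age\*, PTH\*, phosphate\*
- **PTH** (continuous, linear): ← age\*, magnesium, vitamin D, phosphate, calcium
- **calcium** (continuous, linear): ← phosphate
- **T2DM** (binary, logistic): ← age, magnesium

\* = sex-moderated path: the coefficient is for women (reference) and a male
offset parameter shifts it for men.

Continuous variables are standardized, so a coefficient β is the effect of a
1-SD change (on the log-odds scale for binary outcomes). The indirect effect
along a pathway of continuous mediators is the product of its edge
coefficients, and the total effect is

total(x → y) = β_direct + Σ_paths Π_edges β_edge,

e.g. phosphate on PTH: −0.26 + (−0.09)(0.27) = −0.28. When a *binary*
variable sits strictly inside a pathway (magnesium → T2DM → MS), linear and
logistic coefficients cannot be multiplied; the pathway is flagged
non-quantifiable and enters only the significance classification
(joint-significance rule: an indirect route is significant iff every edge on
it is). Natural-unit conversions use the predictor SD: exp(β/SD) is an odds
ratio per measurement unit, β·SD_y/SD_x a slope in natural units.

Estimation is fully Bayesian: weakly informative priors (Normal(0, 10²) on
coefficients, half-Cauchy(0, 5) on residual SDs), MCMC with 3 parallel
chains × 10,000 iterations (5,000 burn-in), convergence monitored by the
potential scale reduction (EPSR ≈ 1), and model comparison by the deviance
information criterion DIC = D̄ + pD. Because the original patient data were
never deposited, the package ships a synthetic-cohort generator calibrated
to the study population's marginals (n = 971 morbidly obese adults, 67.5%
women, MS 68.1%, T2DM 25%) with the published standardized coefficients as
ground truth, so the whole chain — simulate → screen → moderate → fit →
prune → effects — is testable end to end.

## Worked example

```python
from pthpath import (McmcConfig, build_final_model, generate_cohort,
                     reference_config, sample_posterior, summarize)

model = build_final_model()
cohort = generate_cohort(model, reference_config(n=971, seed=42))
fit = sample_posterior(model, cohort,
                       config=McmcConfig(chains=3, iterations=3000, burnin=1000, seed=1))
print(summarize(fit).round(3))
```

This is `examples/03_fit_path_model.py`, which ends by printing:

```
converged: True (max EPSR 1.018)
DIC = 7163.4  (mean deviance 7141.9 + pD 21.5)

headline effects (generating values 0.36 and -0.27):
  PTH -> MS   +0.422
  vitD -> PTH -0.257
```

i.e. the fit converged (EPSR ≈ 1 for all 22 parameters), and the posterior
means recover the generating coefficients within their credible intervals:
a 1-SD (2.3 pmol/l) increase in PTH raises the log-odds of MS for women by
≈ 0.42 in this simulated cohort (truth 0.36), while 1 SD of vitamin D
(22 nmol/l) lowers PTH by ≈ 0.26 SD (truth −0.27).

The `examples/` directory has one short script per capability: model
building and pathway enumeration, cohort simulation with descriptive
tables, fitting and diagnostics, mediation arithmetic with natural-unit
conversions, and the sex-stratified screen → moderation → DIC-pruning
selection pipeline. `examples/05_model_selection.py`, run on a cohort
simulated from the final model, flags exactly the four generating moderated
paths and recovers all 12 generating edges with none spurious:

```
stratified screen flagged: ['age->MS', 'PTH->MS', 'phosphate->MS', 'age->PTH']

DIC ranking (lower is better):
                    model   dbar   pd    dic  converged  delta_dic
initial+moderation-pruned 7119.9 19.5 7139.4       True        0.0
       initial+moderation 7119.5 26.3 7145.8       True        6.4
                  initial 7149.8 22.3 7172.1       True       32.6
```

A thin CLI wraps the same functions: `pthpath simulate`, `pthpath fit`,
`pthpath effects`, `pthpath run --config pipeline.yaml`, `pthpath
export-model`.

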