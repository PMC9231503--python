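# grouprhp

**Which properties of animal groups predict victory in intergroup contests?**

`grouprhp` is a Python library for estimating proxies of *group resource-holding
potential* (RHP) from observational data on dyadic intergroup contests — the
kind of data produced by long-term field studies of group-living mammals such
as banded mongooses, where two social groups meet, fight, and leave a clear
winner and loser. It implements the complete inference pipeline for that
question, exercisable end-to-end on synthetic data with known ground truth:

- **Data model** — long-format CSV tables (individuals, group memberships,
  weighings, contests, mate-guarding events, evictions, litters), per-contest
  adult rosters (adults > 6 mo; weights from the nearest valid weighing within
  120 d; a male is *dominant* if he mate-guarded within 180 d), and the 15
  relative predictors: focal-minus-rival count, mean/max weight and mean/max
  age for three member classes (all adults, males, subordinate males).
- **Weight imputation** — rosters missing ≤ 20% of weights are completed by
  sampling each missing weight from a truncated normal built from same-group,
  same-sex (and same-pregnancy-status) individuals within ±60 d of age;
  growth-curve validation checks the three-parameter asymptotic weight–age fit
  `w(a) = c + (d − c)(1 − e^{−a/e})` is unchanged by imputation.
- **Mixed models, from scratch** — binomial GLMMs with crossed (or constrained
  equal-and-opposite) random intercepts via the Laplace approximation,
  Gaussian LMMs via the exact marginal likelihood (ML/REML), lognormal-Poisson
  models with observation-level random effects, and single-term-deletion
  likelihood-ratio tests. Fits agree with `lme4::glmer` to ~1e-5.
- **Multimodel inference** — 12 global contest models expanded to all term
  subsets, deduplicated; AICc; ΔAICc < 6 retention; a nesting rule; Akaike
  likelihoods `l_i = exp(−½ΔAICc_i)` and weights `w_i = l_i/Σl_j`;
  model-averaged coefficients `β̄ = Σ w_i β̂_i` (with `β̂_i = 0` where absent)
  and variable importance `Σ w_i` over models containing a predictor.
- **Iterated inference** — the imputation × model-comparison pass repeated many
  times; models occurring in < 50% of iterations dropped; 2.5/50/97.5
  percentiles of per-model statistics, averaged coefficients and importance.
- **Constrained Bayesian check** — because focal/rival labels are arbitrary,
  the model `logit P(focal wins) = Xβ + a_focal − a_rival`, `a_g ~ N(0, σ_a²)`
  is refit by adaptive MCMC and compared with the ML estimates.
- **Follow-up analyses** — senior-male winning/losing datasets, exact binomial
  tests, weight repeatability (ICC with bootstrap CI and permutation p),
  age→contest-experience, senior-age→outcome with the liability-age threshold,
  single-senior-male subset refits, eviction and paternity models, and
  sexual-dimorphism LMMs.
- **Synthetic data** — a generator producing populations (11 groups of ~20
  adults, 1.6:1 male-biased, communal litter cohorts, asymptotic growth with
  sexual dimorphism), contests from a logistic model with latent group
  abilities, and three weight-missingness mechanisms.

## Worked example

`examples/` contains one short script per capability. The central one,
`examples/05_iterated_importance.py`, simulates 300 contests whose outcomes
have real effects only on the relative number of males (+1.0 per SD) and the
relative age of the oldest male (+0.6 per SD), masks weights at the 22.1%
population rate, and runs the full iterated pipeline. It prints:

```
40 iterations (0 skipped); 6 models survive the 50% occurrence filter

                                                   terms  occurrence  aicc_p50  weight_p2.5  weight_p50  weight_p97.5
                                       rel_max_age_males       1.000   127.107        0.035       0.047         0.061
 rel_max_age_males + rel_mean_weight_males + rel_n_males       1.000   122.425        0.450       0.489         0.524
                         rel_max_age_males + rel_n_males       0.975   125.278        0.088       0.116         0.147
rel_mean_age_males + rel_mean_weight_males + rel_n_males       1.000   124.511        0.150       0.174         0.202
                     rel_mean_weight_males + rel_n_males       1.000   126.064        0.070       0.079         0.088
                                               rel_n_all       1.000   125.677        0.072       0.096         0.124

variable importance, median [2.5%, 97.5%] across iterations:
  rel_n_males                0.857 [0.815, 0.892]
  rel_mean_weight_males      0.742 [0.674, 0.814]
  rel_max_age_males          0.652 [0.636, 0.660]
  rel_mean_age_males         0.174 [0.150, 0.202]
  rel_n_all                  0.096 [0.072, 0.124]
  rel_max_weight_all         0.000 [0.000, 0.000]
```

Reading this: the best-supported models all contain the relative male count,
and the two planted drivers carry high importance (summed Akaike weight of the
models containing them), while most null predictors never enter the top set.
The percentile intervals show how much each quantity moves across imputation
re-draws — they quantify imputation uncertainty, not sampling uncertainty. In
any single realisation correlated proxies (here relative mean male weight) can
also pick up support; that is a property of multimodel inference on ~150
surviving contests from 11 groups, not a defect of the machinery.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end-to-end at desk scale — generates a population,
stages contests with known ground truth, applies clustered missingness, runs
the iterated imputation × selection loop and the senior-male follow-ups — and
prints what it finds. The results file records the machine-readable summary
(there are no numeric point targets; all quantitative checks live in the test
suite, chiefly `tests/test_acceptance.py`).

## Layout

```
src/grouprhp/       tables.py (data model) · synthetic.py (generator)
                    imputation.py · glmm.py (mixed models) · selection.py
                    iterate.py · bayes.py · followups.py
examples/           one narrative script per capability
docs/methods.md     the statistical methods, assumptions and limitations
tests/              pytest suites incl. acceptance checks
```
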