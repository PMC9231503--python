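# Methods

This note documents the statistical models the package implements, the
assumptions and defaults behind its synthetic-data generator, the numerical
choices in the estimators, and the limits of what a green test establishes.

## 1. The scientific problem

In group-living animals, dyadic intergroup contests end with a winner and a
loser, and the properties that best predict victory serve as proxies of group
*resource-holding potential* (RHP). The analysis asks which of 15 relative
(focal-group minus rival-group) properties — the count, mean/max weight and
mean/max age of three member classes (all adults, males, subordinate males) —
carry the predictive weight, while treating two practical complications
honestly: missing body-weight data (imputed, with the whole analysis repeated
across imputation draws) and the arbitrariness of which group is labelled
"focal" (randomised labels; group identities as random effects; a constrained
Bayesian check).

## 2. Data model and derivation rules

* **Adults** are individuals aged > 183 d (6 months) on the contest date.
  Ages are exact day counts from birth dates; immigrants are assumed 730 d
  old on their immigration date.
* **Contest weight**: the nearest valid weighing in the closed window
  [contest − 120 d, contest]; none ⇒ missing. Masked observations (values
  flagged unusable) never attach.
* **Dominance**: a male is dominant at a contest if he mate-guarded within the
  closed 180-d window before it; otherwise subordinate.
* **Eligibility**: contests count only if both groups field ≥ 1 male and ≥ 1
  subordinate male.
* **Relative predictors** are antisymmetric by construction: swapping the
  focal/rival labels negates all 15 and flips the outcome, leaving the
  likelihood of every contest model unchanged.

## 3. Weight imputation

Rosters missing ≤ 20% of member weights are eligible. Each missing weight is
drawn once per iteration from a truncated normal whose *untruncated* mean and
SD equal those of the reference sample: same-group, same-sex individuals
(females also matched on pregnancy status at the weighing) within ±60 d of the
target's age, each with a valid weighing in the 120-d window. Choices the
source procedure leaves open, and how they are fixed here:

* **Truncation bounds**: the reference sample's [min, max] (configurable to
  [0, ∞)). Guarantees draws inside the observed biological range.
* **n = 1 reference**: the single value is imputed verbatim (the SD is
  undefined); such draws are logged distinctly.
* **Empty reference set / ineligible roster**: the contest is dropped, once,
  before iteration begins — the missingness pattern is fixed, so eligibility
  and reference sets are too, and iterations differ only in the draws.

Validation fits the three-parameter asymptotic growth curve
`w(a) = c + (d − c)(1 − e^{−a/e})` (self-started nonlinear least squares;
`c` lower limit, `d` asymptote, `e` rise timescale in days) per group to the
observed-only and observed-plus-imputed datasets and compares parameters with
joint SEs. Acceptance testing shows the asymptote difference stays within 2
joint SEs in ≥ 95% of simulated groups at 20% missingness.

## 4. Mixed models

All models are fitted by in-package code (no external mixed-model engine).

* **Binomial / Poisson GLMMs**: Laplace-approximate marginal ML. For
  η = Xβ + Zu, u ~ N(0, Σ) with one variance per grouping factor,
  log L ≈ log f(y|η̂) − ½û′Σ⁻¹û − ½log|Σ| − ½log|H|, H = Z′WZ + Σ⁻¹ at the
  penalised conditional mode û (Newton with step halving). The default fit
  then maximises this over (β, log σ) jointly (L-BFGS-B, gradient tolerance
  1e-6, log σ bounded in [−6, 3]); the iterated pipeline instead keeps β
  profiled inside the penalised inner problem (the fast mode analogous to
  lme4's nAGQ = 0), which is ~2–5× cheaper and differs from the exact optimum
  by O(0.01) in coefficients — immaterial for AICc ranking and documented so
  the two modes are never mixed within one comparison. Exact-mode fits agree
  with `lme4::glmer` to ~1e-5 (β), ~1e-7 (log-likelihood).
* **Paired "ability" random term**: a random term may be a column pair
  (focal, rival); both index one shared set of group levels entering as
  u[focal] − u[rival] — the equal-variance, correlation −1 structure implied
  by arbitrary focal/rival labelling.
* **Gaussian LMMs**: exact marginal likelihood through the Woodbury identity
  (β profiled by GLS), ML or REML. ML is always used when a likelihood-ratio
  test compares fixed structures.
* **Observation-level random effects** (lognormal-Poisson) absorb
  overdispersion in count models; single-factor models take an O(n) diagonal
  path.
* **Standard errors**: exact-mode SEs invert the observed information of the
  full Laplace objective (numeric central differences), matching the reference
  mixed-model convention; profiled-mode SEs use the fixed-effect Schur
  complement and are slightly smaller.
* **Convergence / separation**: optimizer failure flags the fit (excluded from
  model sets, logged); |β| > 15 on the scaled metric flags possible
  separation without excluding the fit.
* **drop1 LR tests**: χ² = 2(llₓ − ll₋ₓ), df = 1, upper-tail χ² p; the reduced
  model keeps the random structure and is fitted by ML.

Predictors are always centred and scaled to unit sample SD (ddof = 1) before
fitting; scaling constants are retained for back-transformation.

## 5. Multimodel inference

The candidate universe is 12 global binomial contest models — one per member
class × weight aggregate (mean/max) × age aggregate (mean/max), each with the
class count plus one weight and one age statistic and the crossed focal/rival
random intercepts. This 3×2×2 catalog yields exactly 12 models, never pairs a
mean with a max of the same trait within a model, and spans all 15 predictors.
All 2³ subsets of each global model's terms are pooled and deduplicated by
term set (52 unique candidates, including one intercept-only model).

AICc = −2ll + 2k + 2k(k+1)/(n−k−1), with k = #fixed effects + #variance
components (+1 residual for Gaussian) and n = number of contests. Models with
ΔAICc ≥ 6 from the pooled best are dropped (strict < 6 retained). The nesting
rule then removes any model with AICc ≥ that of a strictly nested simpler
candidate (ties remove the more complex model; by transitivity, comparing
against all candidates or only survivors is equivalent). Within the surviving
set, ΔAICc is re-based, l_i = exp(−½ΔAICc_i), w_i = l_i/Σl_j, model-averaged
coefficients take β̂_i = 0 where a predictor is absent, and importance is the
summed weight of models containing it. A VIF helper (threshold 10) provides
the collinearity check; violations are logged, not fatal.

## 6. Iterated inference

Iteration i derives its RNG stream solely from (base_seed, i), so results are
independent of execution order. Each iteration re-draws all imputations,
rebuilds and rescales predictors, refits all candidates (warm-started), and
records its post-nesting set. Models present in < 50% of non-skipped
iterations are removed (a model in exactly half is retained); per-iteration
weights and averages are then recomputed on each iteration's surviving subset
before 2.5/50/97.5 percentiles (NumPy's default linear/type-7 estimator,
config-exposed) are taken across iterations. More than 1% skipped iterations
is a pipeline error. With no missing weights the loop reduces exactly to a
single model-selection pass. Focal/rival randomisation is performed once, not
per iteration (only the weight sampling is repeated), configurable upstream.

## 7. Constrained Bayesian model

logit P(focal wins) = Xβ + σ_a(z_focal − z_rival), z_g ~ N(0,1) (non-centered),
priors β ~ N(0, 2.5²) on the scaled metric and σ_a ~ half-Normal(0, 1) — both
config-exposed, since the source priors are not recoverable. The sampler is
adaptive random-walk Metropolis in blocks (β jointly; z single-site with
incremental linear-predictor updates; log σ_a), plus an
ancillarity–sufficiency interweaving move that rescales (σ_a, z) holding the
abilities σ_a·z fixed — the likelihood-invariant direction that defeats a
plain random walk. Acceptance is adapted to ~0.2–0.4 during warmup; split-chain
R̂ < 1.05 for every parameter is required (else an error with diagnostics), and
ESS uses Geyer's initial-positive-sequence rule. `compare_to_ml` reports sign
agreement and (posterior mean − MLE)/SE per fixed effect against the ML fit
with the paired ability term.

## 8. Follow-up analyses

* **Senior males**: the oldest male across the two groups; the group whose
  oldest male is strictly older "has" him (ties across groups contribute no
  records; same-age oldest males within the holding group each contribute
  one). Winning/losing record sets partition all such records.
* **Exact binomial test**: full enumeration; the two-sided p sums P(X = j)
  over j with P(X = j) ≤ P(X = k)(1 + 1e-7) (the small-p rule, matching the
  standard exact test). Because the source leaves the null orientation
  ambiguous, comparisons report both orientations plus one-sided tails.
* **Repeatability**: R = σ²_among/(σ²_among + σ²_within) from a REML one-way
  LMM; parametric-bootstrap CI; permutation p from shuffling individual
  labels.
* **Age → experience**: lifetime contest count ~ scaled maximum age, Poisson,
  log link, OLRE; drop1 LR for age.
* **Senior age → outcome**: win ~ scaled age + (1|male), binomial; the
  liability threshold is the age where the fixed-effect curve crosses
  P(win) = 0.5, reported in years (undefined, with a flag, when the slope is
  non-negative). Invariant to age units.
* **Single-senior-male subset**: the best-fit contest model refitted on
  contests whose senior-holding group had exactly one oldest male;
  side-by-side estimates with differences in SE units.
* **Eviction**: evicted ~ scaled age with crossed random intercepts for male,
  group and eviction event. **Paternity**: (sired, litter − sired) ~ scaled
  senior-male age + (1|male), binomial with litter denominators.
* **Dimorphism**: trait ~ sex + (1|individual), ML, pregnant females excluded
  from the weight model by default.
* Report-level proportions are printed at one decimal; full precision is
  retained in the returned objects.

## 9. The synthetic world

Defaults encode the population the analysis was designed for:

| parameter | default | why |
|---|---|---|
| groups × adults | 11 × 20 (total exact, sizes multinomial) | typical population structure |
| sex ratio | P(male) = 1.6/2.6 | male-biased adult sex ratio (1.6:1) |
| growth | c = 300 g, e = 200 d; d = 1440 g (M), 1293 g (F) | asymptotes equal the reported population weight means; near-asymptotic by ~2 y |
| individual asymptote SD | 150 g | persistent size differences; yields adult weight repeatability ~0.8 and adult SDs approaching the reported ~260–276 g |
| measurement noise | 80 g | plausible field-scale error |
| weighing cadence | 14 d | implies a median weighing-to-contest gap of ~7 d, matching the reported median of 5 d |
| age structure | exponential pyramid (mean 2 y over a 0.75 y floor) + 15% elders uniform on 5–11.5 y; births snapped to annual per-group litter cohorts | bottom-heavy pyramids and communal synchronous litters are features of this system; elders supply the old senior males (~8–10 y) the analyses concern |
| dominance | per-cycle mate-guarding cohorts, Binomial(n males, 0.3), age-weighted | rotating, age-biased guarding; keeps subordinate counts and ages from being deterministic copies of male counts and ages |
| contest model | logit P = Σβ·x_scaled + a_f − a_r; defaults β = {rel_n_males: 1.0, rel_max_age_males: 0.6}, σ_a = 0.5 | two planted drivers plus latent group quality |
| missingness | clustered: whole individuals unweighable, group rates Beta(α = 0.14, mean 0.221) | calibrated so ~72–75% of contest group-pairs carry ≥ 1 missing weight, the reported field statistic; CAR-per-observation and age-dependent MAR variants are also provided |

What the generator does **not** emulate: group fission/formation, dispersal and
membership turnover, pup care dynamics, seasonal contest rates, non-random
contest location, senescence in the outcome model (the liability-threshold
analyses use their own senescence-bearing generator), and any real-data column
dialect. A green end-to-end test therefore establishes that the machinery
recovers planted structure under this stylised world — not that the biological
conclusions of any particular field system are reproduced.

## 10. Known limitations

* **Few-groups inference**: with ~11 groups, Wald CIs for group-level
  predictors are anticonservative (measured coverage ~0.83 at nominal 95%
  under σ_a = 0.5, vs ~0.96 at σ_a = 0), and the identity of the top
  predictors varies across realisations more than large-sample intuition
  suggests. This is a property of the design, shared by the reference
  mixed-model implementations; the constrained Bayesian model helps with the
  symmetry but not with G = 11.
* The two-independent-random-effects contest model is (deliberately, matching
  the source analysis) misspecified relative to equal-and-opposite abilities;
  its variance components partially absorb, and its coefficients slightly
  attenuate under, strong ability variance.
* Laplace (nAGQ = 1) accuracy: adequate for binomial models with many
  observations per group level; no adaptive quadrature is provided.
* The MCMC sampler is a random-walk scheme adequate for ~15-parameter
  posteriors; it is not a general-purpose PPL replacement.
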