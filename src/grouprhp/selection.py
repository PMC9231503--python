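"""Information-theoretic model comparison: global-model catalog, all-subsets
enumeration, AICc, ΔAICc filtering, the nesting rule, Akaike weights,
model-averaged coefficients and variable importance.

The candidate universe is built from 12 global contest models — one per
(member class × weight aggregate × age aggregate), each holding a relative
count, one relative weight statistic and one relative age statistic of that
class — expanded to all subsets of their terms and deduplicated by term set.
Within a candidate set the machinery is the standard Akaike one:

    ΔAICc_i = AICc_i − min AICc,   l_i = exp(−½ΔAICc_i),   w_i = l_i / Σ l_j,
    β̄ = Σ w_i β̂_i (with β̂_i = 0 where absent),  importance = Σ_{models ∋ x} w_i.

Models with ΔAICc ≥ 6 are dropped (strict <6 retained), and the nesting rule
removes any model that fits no better than a strictly simpler model nested in
it (AICc ties remove the more complex model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PipelineError
from .glmm import GlmmFit, ModelSpec, fit_glmm
from .tables import MEMBER_CLASSES, PREDICTOR_NAMES

DELTA_AICC_MAX = 6.0
DEFAULT_RANDOM = ("focal_group_id", "rival_group_id")
VIF_THRESHOLD = 10.0


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = −2·loglik + 2k + 2k(k+1)/(n−k−1); undefined for n ≤ k+1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def global_model_catalog(
    response: str = "focal_win", random: tuple = DEFAULT_RANDOM
) -> list[ModelSpec]:
    """The 12 global binomial contest models.

    One model per member class ∈ {all, males, submales} × weight aggregate ∈
    {mean, max} × age aggregate ∈ {mean, max}; each holds the class's relative
    count plus the chosen weight and age statistics, with the standard crossed
    focal/rival random intercepts.  Together they span all 15 relative
    predictors while never pairing a mean with a max of the same trait.
    """
    specs = []
    for cls in MEMBER_CLASSES:
        for wagg in ("mean", "max"):
            for aagg in ("mean", "max"):
                terms = (
                    f"rel_n_{cls}",
                    f"rel_{wagg}_weight_{cls}",
                    f"rel_{aagg}_age_{cls}",
                )
                specs.append(
                    ModelSpec(response=response, fixed=terms, random=tuple(random),
                              family="binomial")
                )
    assert len(specs) == 12
    return specs


def enumerate_submodels(catalog: list[ModelSpec]) -> list[ModelSpec]:
    """All subsets of every global model's terms, pooled and term-set-deduplicated.

    The intercept-only model appears exactly once.  Order: increasing term
    count, then lexicographic (deterministic).
    """
    seen = {}
    for spec in catalog:
        terms = list(spec.fixed)
        for mask in range(2 ** len(terms)):
            subset = tuple(t for j, t in enumerate(terms) if mask >> j & 1)
            key = frozenset(subset)
            if key not in seen:
                seen[key] = ModelSpec(
                    response=spec.response, fixed=subset, random=spec.random,
                    family=spec.family, olre=spec.olre, trials=spec.trials,
                )
    return sorted(seen.values(), key=lambda s: (len(s.fixed), s.fixed))


@dataclass
class ModelEntry:
    spec: ModelSpec
    fit: GlmmFit
    aicc: float
    delta: float = np.nan
    likelihood: float = np.nan
    weight: float = np.nan

    @property
    def term_key(self) -> frozenset:
        return self.spec.term_key


@dataclass
class ModelSet:
    """A filtered, weighted candidate set."""

    entries: list = field(default_factory=list)

    def __len__(self):
        return len(self.entries)

    def table(self) -> pd.DataFrame:
        rows = [
            dict(
                terms=" + ".join(sorted(e.spec.fixed)) or "(intercept)",
                n_terms=len(e.spec.fixed),
                aicc=e.aicc, delta_aicc=e.delta,
                likelihood=e.likelihood, weight=e.weight,
            )
            for e in self.entries
        ]
        return pd.DataFrame(rows)


def fit_candidates(
    specs: list[ModelSpec], data: pd.DataFrame, *, starts: dict | None = None,
    compute_se: bool = False, profile_beta: bool = True,
) -> tuple[list, list]:
    """Fit every candidate; returns (converged (spec, fit) pairs, failure log).

    By default candidates use the fast profiled-β deviance: the iterated
    pipeline refits every candidate thousands of times, and model ranking only
    needs likelihoods on a consistent scale.
    """
    fits, failures = [], []
    for spec in specs:
        start = starts.get(spec.term_key) if starts else None
        try:
            fit = fit_glmm(spec, data, start=start, compute_se=compute_se,
                           profile_beta=profile_beta)
        except Exception as exc:  # noqa: BLE001 - logged, not fatal per-model
            failures.append((spec, f"error: {exc}"))
            continue
        if not fit.converged:
            failures.append((spec, "non-convergence"))
            continue
        fits.append((spec, fit))
    return fits, failures


def build_top_set(fits: list, n: int, delta_max: float = DELTA_AICC_MAX) -> ModelSet:
    """Retain fits with ΔAICc strictly below ``delta_max`` from the pooled minimum."""
    if not fits:
        raise PipelineError("no converged candidate fits")
    entries = [ModelEntry(spec=s, fit=f, aicc=aicc(f.loglik, f.k, n)) for s, f in fits]
    best = min(e.aicc for e in entries)
    kept = []
    for e in entries:
        e.delta = e.aicc - best
        if e.delta < delta_max:
            kept.append(e)
    return ModelSet(entries=kept)


def nesting_rule(model_set: ModelSet) -> ModelSet:
    """Remove any model dominated by a strictly simpler nested model.

    A model is dropped iff some other candidate whose term set is a strict
    subset has AICc ≤ its AICc (ties remove the more complex model — the
    parsimony reading of "worse fit").  By transitivity, comparing against all
    candidates or only survivors gives the same result.
    """
    entries = model_set.entries
    kept = []
    for e in entries:
        dominated = any(
            other.term_key < e.term_key and other.aicc <= e.aicc for other in entries
        )
        if not dominated:
            kept.append(e)
    return ModelSet(entries=kept)


def weights_and_likelihoods(model_set: ModelSet) -> ModelSet:
    """Akaike likelihoods and weights within the (already filtered) set.

    ΔAICc is re-based on the set's own minimum; l = exp(−½Δ); w = l/Σl.
    """
    if not model_set.entries:
        raise PipelineError("empty model set")
    best = min(e.aicc for e in model_set.entries)
    for e in model_set.entries:
        e.delta = e.aicc - best
        e.likelihood = float(np.exp(-0.5 * e.delta))
    total = sum(e.likelihood for e in model_set.entries)
    for e in model_set.entries:
        e.weight = e.likelihood / total
    return model_set


def model_average(
    model_set: ModelSet, predictors=PREDICTOR_NAMES
) -> pd.DataFrame:
    """Model-averaged coefficients and variable importance per predictor.

    β̂_i is taken as 0 in models that exclude the predictor; importance is the
    summed weight of the models containing it (∈ [0, 1]).
    """
    rows = {}
    for name in predictors:
        beta_bar = 0.0
        importance = 0.0
        for e in model_set.entries:
            if name in e.spec.fixed:
                beta_bar += e.weight * float(e.fit.beta[name])
                importance += e.weight
        rows[name] = dict(beta_bar=beta_bar, importance=importance)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "predictor"
    return out


def variance_inflation(data: pd.DataFrame, terms) -> pd.Series:
    """VIF per term from the predictor correlation structure (collinearity guard)."""
    terms = list(terms)
    if len(terms) < 2:
        return pd.Series(1.0, index=terms)
    X = data[terms].to_numpy(float)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    corr = np.corrcoef(X, rowvar=False)
    vif = np.diag(np.linalg.inv(corr))
    return pd.Series(vif, index=terms)


def select_models(
    data: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    *,
    starts: dict | None = None,
    delta_max: float = DELTA_AICC_MAX,
    predictors=PREDICTOR_NAMES,
) -> tuple[ModelSet, pd.DataFrame, list]:
    """One full selection pass: fit, ΔAICc-filter, nesting rule, weights, averaging.

    ``data`` must hold the scaled predictors, the response, and the random
    grouping columns.  Returns (model set, averaged-estimates frame, failures).
    """
    if specs is None:
        specs = enumerate_submodels(global_model_catalog())
    fits, failures = fit_candidates(specs, data, starts=starts)
    top = build_top_set(fits, n=len(data), delta_max=delta_max)
    top = nesting_rule(top)
    top = weights_and_likelihoods(top)
    averaged = model_average(top, predictors=predictors)
    return top, averaged, failures
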