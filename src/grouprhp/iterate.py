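"""Repeated imputation × model selection, occurrence filtering, and percentile
aggregation.

Because imputation draws are random, the whole model-comparison pass is
repeated many times (the study-scale default is 10,000 iterations).  Each
iteration re-draws every imputed weight, rebuilds the relative predictors,
rescales them, refits every candidate model, and records its post-nesting top
model set.  Models that appear in fewer than 50% of iterations are then
discarded, and the 2.5/50/97.5 percentiles of per-model AICc, likelihood and
weight — and of per-iteration model-averaged coefficients and variable
importance — summarise the remainder.

Iteration i draws its RNG stream solely from (base_seed, i), so results are
independent of execution order or parallel schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tables as T
from .errors import PipelineError
from .glmm import scale_predictors
from .imputation import ImputationConfig, build_plan, draw_imputations
from .selection import (
    build_top_set,
    enumerate_submodels,
    fit_candidates,
    global_model_catalog,
    nesting_rule,
    weights_and_likelihoods,
)
from .tables import PREDICTOR_NAMES, PredictorBuilder


@dataclass
class IterationConfig:
    n_iterations: int = 10_000
    occurrence_min_fraction: float = 0.5
    percentiles: tuple = (2.5, 50.0, 97.5)
    base_seed: int = 0
    max_skip_fraction: float = 0.01

    def validate(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 < self.occurrence_min_fraction <= 1.0):
            raise ValueError("occurrence_min_fraction must lie in (0, 1]")


@dataclass
class IterationSummary:
    """Percentile summaries across iterations (the plot-ready product)."""

    model_table: pd.DataFrame
    predictor_table: pd.DataFrame
    n_iterations: int
    n_skipped: int
    retained_keys: list


def _term_label(key: frozenset) -> str:
    return " + ".join(sorted(key)) or "(intercept)"


@dataclass
class PreparedContests:
    """Fixed ingredients of the iteration loop.

    The missingness pattern, eligibility decisions and reference sets do not
    change across iterations — only the imputed values do — so they are
    derived once.  ``contest_data`` carries outcome + grouping columns for the
    kept contests; ``builder`` recomputes predictors from a weight vector.
    """

    contest_data: pd.DataFrame
    builder: PredictorBuilder
    plan: object
    base_weights: np.ndarray
    specs: list


def prepare_contests(
    tables: T.StudyTables,
    imputation_config: ImputationConfig | None = None,
    specs: list | None = None,
) -> PreparedContests:
    imputation_config = imputation_config or ImputationConfig()
    member_table = T.build_member_table(tables)
    eligible = T.eligible_contest_ids(member_table)
    member_table = member_table.loc[member_table["contest_id"].isin(eligible)]
    plan = build_plan(tables, member_table, imputation_config)
    member_table = member_table.reset_index(drop=True)
    keep_rows = member_table["contest_id"].isin(plan.kept_contests)
    # plan row indices refer to the pre-filter member table; remap
    row_map = -np.ones(len(member_table), dtype=int)
    row_map[np.flatnonzero(keep_rows)] = np.arange(int(keep_rows.sum()))
    plan.rows = row_map[plan.rows]
    member_table = member_table.loc[keep_rows].reset_index(drop=True)

    builder = PredictorBuilder(member_table)
    contest_data = (
        tables.contests.loc[tables.contests["contest_id"].isin(plan.kept_contests)]
        .set_index("contest_id")
        .loc[builder.contest_ids]
        .reset_index()
    )
    if specs is None:
        specs = enumerate_submodels(global_model_catalog())
    return PreparedContests(
        contest_data=contest_data,
        builder=builder,
        plan=plan,
        base_weights=member_table["weight_g"].to_numpy(float),
        specs=specs,
    )


def _one_iteration(prep: PreparedContests, rng, starts, delta_max=6.0):
    weights = prep.base_weights.copy()
    if len(prep.plan.rows):
        weights[prep.plan.rows] = draw_imputations(prep.plan, rng)
    X = prep.builder.predictors(weights)
    data = prep.contest_data.copy()
    for c in PREDICTOR_NAMES:
        data[c] = X[c].to_numpy()
    data, _ = scale_predictors(data, list(PREDICTOR_NAMES))
    fits, failures = fit_candidates(prep.specs, data, starts=starts)
    if not fits:
        return None, failures
    for spec, fit in fits:
        starts[spec.term_key] = fit.theta
    top = weights_and_likelihoods(nesting_rule(build_top_set(fits, len(data), delta_max)))
    models = {
        e.term_key: dict(
            aicc=e.aicc,
            beta={t: float(e.fit.beta[t]) for t in e.spec.fixed},
        )
        for e in top.entries
    }
    return models, failures


def run_iterations(
    tables: T.StudyTables,
    iteration_config: IterationConfig,
    imputation_config: ImputationConfig | None = None,
    specs: list | None = None,
    prepared: PreparedContests | None = None,
) -> list:
    """Raw per-iteration post-nesting model sets.

    Each element is a dict ``term_key -> {aicc, beta}`` or ``None`` for a
    skipped iteration (no converged candidates); more than
    ``max_skip_fraction`` skips is a pipeline error.
    """
    iteration_config.validate()
    prep = prepared or prepare_contests(tables, imputation_config, specs)
    if len(prep.contest_data) == 0:
        raise PipelineError("no contests survive eligibility/imputation filtering")
    starts: dict = {}
    if len(prep.plan.rows) == 0:
        # nothing to impute: every iteration is identical, so the loop reduces
        # exactly to a single model-selection pass
        rng = np.random.default_rng(
            np.random.SeedSequence((iteration_config.base_seed, 0))
        )
        models, _ = _one_iteration(prep, rng, starts)
        return [models] * iteration_config.n_iterations
    raw = []
    for i in range(iteration_config.n_iterations):
        rng = np.random.default_rng(
            np.random.SeedSequence((iteration_config.base_seed, i))
        )
        models, _ = _one_iteration(prep, rng, starts)
        raw.append(models)
    n_skipped = sum(m is None for m in raw)
    if n_skipped > iteration_config.max_skip_fraction * len(raw):
        raise PipelineError(
            f"{n_skipped}/{len(raw)} iterations produced no converged model"
        )
    return raw


def occurrence_filter(raw: list, config: IterationConfig) -> list:
    """Term-set keys appearing in ≥ occurrence_min_fraction of non-skipped iterations.

    The boundary is inclusive: a model present in exactly half the iterations
    is retained (the removal rule targets models occurring in *fewer* than
    half).
    """
    done = [m for m in raw if m is not None]
    if not done:
        raise PipelineError("no successful iterations")
    counts: dict = {}
    for models in done:
        for key in models:
            counts[key] = counts.get(key, 0) + 1
    retained = [
        key for key, c in counts.items()
        if c / len(done) >= config.occurrence_min_fraction
    ]
    if not retained:
        raise PipelineError(
            "occurrence filter removed every model; "
            f"occurrence fractions: { {_term_label(k): c / len(done) for k, c in counts.items()} }"
        )
    return sorted(retained, key=_term_label)


def aggregate(raw: list, retained: list, config: IterationConfig) -> IterationSummary:
    """Percentile summaries over iterations, on the occurrence-filtered set.

    Within each iteration the retained models' ΔAICc, likelihoods and weights
    are recomputed on that iteration's surviving subset (weights renormalise),
    and model-averaged coefficients / importance follow from those weights;
    percentiles are then taken across iterations.
    """
    done = [m for m in raw if m is not None]
    retained = list(retained)
    per_model: dict = {k: dict(aicc=[], likelihood=[], weight=[]) for k in retained}
    beta_bars = {p: [] for p in PREDICTOR_NAMES}
    importances = {p: [] for p in PREDICTOR_NAMES}

    for models in done:
        present = [k for k in retained if k in models]
        if not present:
            continue
        aiccs = np.array([models[k]["aicc"] for k in present])
        delta = aiccs - aiccs.min()
        lik = np.exp(-0.5 * delta)
        w = lik / lik.sum()
        for k, a, l, wi in zip(present, aiccs, lik, w):
            per_model[k]["aicc"].append(a)
            per_model[k]["likelihood"].append(l)
            per_model[k]["weight"].append(wi)
        for p in PREDICTOR_NAMES:
            bb = sum(
                wi * models[k]["beta"].get(p, 0.0)
                for k, wi in zip(present, w)
                if p in models[k]["beta"]
            )
            imp = sum(wi for k, wi in zip(present, w) if p in models[k]["beta"])
            beta_bars[p].append(bb)
            importances[p].append(imp)

    q = list(config.percentiles)
    model_rows = []
    for k in retained:
        vals = per_model[k]
        row = dict(
            terms=_term_label(k),
            occurrence=len(vals["aicc"]) / len(done),
        )
        for stat in ("aicc", "likelihood", "weight"):
            pct = np.percentile(vals[stat], q) if vals[stat] else [np.nan] * len(q)
            for qq, v in zip(q, pct):
                row[f"{stat}_p{qq:g}"] = v
        model_rows.append(row)

    pred_rows = []
    for p in PREDICTOR_NAMES:
        row = dict(predictor=p)
        for stat, series in (("beta_bar", beta_bars[p]), ("importance", importances[p])):
            pct = np.percentile(series, q) if series else [np.nan] * len(q)
            for qq, v in zip(q, pct):
                row[f"{stat}_p{qq:g}"] = v
        pred_rows.append(row)

    return IterationSummary(
        model_table=pd.DataFrame(model_rows),
        predictor_table=pd.DataFrame(pred_rows).set_index("predictor"),
        n_iterations=len(raw),
        n_skipped=len(raw) - len(done),
        retained_keys=retained,
    )


def iterated_model_selection(
    tables: T.StudyTables,
    iteration_config: IterationConfig,
    imputation_config: ImputationConfig | None = None,
    specs: list | None = None,
) -> IterationSummary:
    """Convenience wrapper: run, occurrence-filter, aggregate."""
    raw = run_iterations(tables, iteration_config, imputation_config, specs)
    retained = occurrence_filter(raw, iteration_config)
    return aggregate(raw, retained, iteration_config)
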