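"""Follow-up analyses around the senior-male and male-count effects.

Covers: sexual-dimorphism LMMs, senior-male winning/losing datasets and
descriptive proportions, exact binomial tests, weight repeatability (ICC),
the age→contest-experience Poisson model, the senior-age→outcome model with
its liability-age threshold, the single-senior-male subset refit, the eviction
model, and the paternity model.

A *senior male* is the oldest male across the two competing groups: the group
whose oldest male is strictly older than the rival's "has" the senior male
(equal oldest ages contribute nothing); several same-age oldest males in that
group each count as senior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import tables as T
from .errors import FitError, PipelineError
from .glmm import (
    GlmmFit,
    LRTestResult,
    ModelSpec,
    drop1_lr,
    fit_glmm,
    fit_lmm,
    fit_poisson_olre,
    scale_predictors,
)


# ---------------------------------------------------------------------------
# senior-male datasets


def senior_male_datasets(
    contests: pd.DataFrame, member_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Winning and losing senior-male record sets.

    Returns one row per senior male per contest, columns: contest_id, group_id,
    male_id, age_days, outcome ('win'/'lose'), dominant, ever_dominant (set
    later by :func:`add_ever_dominant` when guard histories are available),
    n_same_age_mates.
    """
    males = member_table.loc[member_table["sex"] == "M"]
    win_rows, lose_rows = [], []
    outcome_map = contests.set_index("contest_id")["focal_win"]
    for cid, grp in males.groupby("contest_id"):
        focal = grp.loc[grp["side"] == "focal"]
        rival = grp.loc[grp["side"] == "rival"]
        if len(focal) == 0 or len(rival) == 0:
            continue
        fmax, rmax = focal["age_days"].max(), rival["age_days"].max()
        if fmax == rmax:
            continue  # neither group "has" the senior male
        holder, other_side = (focal, "focal") if fmax > rmax else (rival, "rival")
        top_age = max(fmax, rmax)
        seniors = holder.loc[holder["age_days"] == top_age]
        focal_won = bool(outcome_map[cid])
        holder_won = focal_won if other_side == "focal" else not focal_won
        for _, s in seniors.iterrows():
            rec = dict(
                contest_id=cid, group_id=s["group_id"], male_id=s["individual_id"],
                age_days=float(s["age_days"]),
                outcome="win" if holder_won else "lose",
                dominant=bool(s["dominant"]),
                n_same_age_mates=int(len(seniors) - 1),
            )
            (win_rows if holder_won else lose_rows).append(rec)
    cols = ["contest_id", "group_id", "male_id", "age_days", "outcome",
            "dominant", "n_same_age_mates"]
    winning = pd.DataFrame(win_rows, columns=cols)
    losing = pd.DataFrame(lose_rows, columns=cols)
    return winning, losing


def _concat_records(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    frames = [f for f in (a, b) if len(f)]
    return pd.concat(frames, ignore_index=True) if frames else a.copy()


def add_ever_dominant(records: pd.DataFrame, guard_events: pd.DataFrame,
                      contests: pd.DataFrame) -> pd.DataFrame:
    """Flag records whose male mate-guarded at any point up to the contest date."""
    out = records.copy()
    dates = contests.set_index("contest_id")["date"]
    ever = []
    for _, r in out.iterrows():
        g = guard_events.loc[guard_events["male_id"] == r["male_id"]]
        ever.append(bool((g["date"] <= dates[r["contest_id"]]).any()))
    out["ever_dominant"] = ever
    return out


# ---------------------------------------------------------------------------
# exact binomial test


def exact_binomial_test(k: int, n: int, p0: float, sided: str = "two-sided") -> float:
    """Exact binomial tail probability by enumeration.

    Two-sided p sums P(X = j) over all j with P(X = j) ≤ P(X = k) (the
    small-probability rule); 'greater'/'less' are the upper/lower tails.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    if not (0.0 < p0 < 1.0):
        raise ValueError("null proportion must lie in (0, 1)")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    if sided == "greater":
        return float(pmf[k:].sum())
    if sided == "less":
        return float(pmf[: k + 1].sum())
    if sided != "two-sided":
        raise ValueError(f"unknown sidedness {sided!r}")
    cutoff = pmf[k] * (1.0 + 1e-7)
    return float(min(pmf[pmf <= cutoff].sum(), 1.0))


def same_age_mate_test(winning: pd.DataFrame, losing: pd.DataFrame) -> dict:
    """Do winning-group senior males have same-age group mates more often?

    The null proportion is not pinned down by the study's description, so both
    orientations are computed: the winning count against the losing-set
    proportion, and vice versa (two-sided by default, one-sided tails
    included).
    """
    kw = int((winning["n_same_age_mates"] > 0).sum())
    nw = len(winning)
    kl = int((losing["n_same_age_mates"] > 0).sum())
    nl = len(losing)
    return _two_orientation_test(kw, nw, kl, nl)


def dominance_test(winning: pd.DataFrame, losing: pd.DataFrame) -> dict:
    """Are winning-group senior males more often behaviourally dominant?"""
    kw, nw = int(winning["dominant"].sum()), len(winning)
    kl, nl = int(losing["dominant"].sum()), len(losing)
    return _two_orientation_test(kw, nw, kl, nl)


def _two_orientation_test(kw, nw, kl, nl) -> dict:
    out = dict(winning_k=kw, winning_n=nw, winning_prop=kw / nw if nw else np.nan,
               losing_k=kl, losing_n=nl, losing_prop=kl / nl if nl else np.nan)
    if nw and nl and 0 < kl < nl:
        out["p_two_sided"] = exact_binomial_test(kw, nw, kl / nl)
        out["p_greater"] = exact_binomial_test(kw, nw, kl / nl, "greater")
    if nw and nl and 0 < kw < nw:
        out["p_two_sided_reversed"] = exact_binomial_test(kl, nl, kw / nw)
    return out


# ---------------------------------------------------------------------------
# repeatability (ICC)


@dataclass
class RepeatabilityResult:
    R: float
    ci: tuple
    p_perm: float
    var_among: float
    var_within: float


def repeatability(
    measurements: pd.DataFrame, n_boot: int = 1000, n_perm: int = 1000,
    seed: int = 0, value_col: str = "value", id_col: str = "individual_id",
) -> RepeatabilityResult:
    """Among-individual repeatability R = σ²_among / (σ²_among + σ²_within).

    Variance components come from a REML one-way random-intercept LMM; the CI
    is a parametric bootstrap (simulate from the fitted components, refit) and
    the p-value permutes individual labels.
    """
    df = measurements[[id_col, value_col]].dropna().copy()
    counts = df.groupby(id_col).size()
    if (counts >= 2).sum() < 2:
        raise FitError("repeatability needs >= 2 individuals with >= 2 measurements")
    spec = ModelSpec(response=value_col, fixed=(), random=(id_col,), family="gaussian")

    def _R(frame) -> tuple:
        fit = fit_lmm(spec, frame, reml=True, compute_se=False)
        va = fit.random_variances[id_col]
        vw = fit.residual_variance
        return va / (va + vw), va, vw, fit

    R, va, vw, fit = _R(df)
    rng = np.random.default_rng(seed)

    boots = []
    ids = df[id_col].to_numpy()
    uniq = pd.unique(ids)
    mu = float(fit.beta.iloc[0])
    for _ in range(n_boot):
        a = rng.normal(0, np.sqrt(va), len(uniq))
        lookup = dict(zip(uniq, a))
        sim = df.copy()
        sim[value_col] = (
            mu + np.array([lookup[i] for i in ids]) + rng.normal(0, np.sqrt(vw), len(df))
        )
        boots.append(_R(sim)[0])
    ci = tuple(np.percentile(boots, [2.5, 97.5])) if boots else (np.nan, np.nan)

    perms = []
    for _ in range(n_perm):
        sim = df.copy()
        sim[id_col] = rng.permutation(ids)
        perms.append(_R(sim)[0])
    p = (1 + sum(r >= R for r in perms)) / (1 + len(perms)) if perms else np.nan

    return RepeatabilityResult(R=float(R), ci=ci, p_perm=float(p),
                               var_among=float(va), var_within=float(vw))


# ---------------------------------------------------------------------------
# GLMM-based follow-ups


def age_experience_model(
    participation: pd.DataFrame, count_col: str = "n_contests",
    age_col: str = "max_age_days",
) -> tuple[GlmmFit, LRTestResult]:
    """Lifetime contest count vs maximum age: Poisson, log link, OLRE.

    One row per male; age is scaled before fitting and tested by single-term
    deletion.
    """
    data = participation.copy()
    data, _ = scale_predictors(data, [age_col])
    spec = ModelSpec(response=count_col, fixed=(age_col,), random=(),
                     family="poisson", olre=True)
    fit = fit_poisson_olre(spec, data)
    lr = drop1_lr(fit, age_col, data)
    return fit, lr


@dataclass
class ThresholdResult:
    threshold_years: float | None
    crosses: bool
    note: str = ""


def senior_age_outcome_model(
    records: pd.DataFrame, age_col: str = "age_days",
) -> tuple[GlmmFit, LRTestResult, ThresholdResult]:
    """Does senior-male age predict the group's win probability?

    Binomial GLMM win ~ scaled(age) + (1 | male), plus the liability
    threshold: the age at which the fixed-effect win probability crosses 0.5,
    reported in years.  A non-negative slope (no decline) yields a
    not-crossing flag instead of a threshold.
    """
    df = records.copy()
    df["win"] = (df["outcome"] == "win").astype(int)
    if df["win"].nunique() < 2:
        raise FitError("need both outcomes present to fit the senior-age model")
    df, rec = scale_predictors(df, [age_col])
    spec = ModelSpec(response="win", fixed=(age_col,), random=("male_id",),
                     family="binomial")
    fit = fit_glmm(spec, df)
    lr = drop1_lr(fit, age_col, df)
    b0 = float(fit.beta["(Intercept)"])
    b1 = float(fit.beta[age_col])
    if b1 >= -1e-8:
        thr = ThresholdResult(None, False, "win probability does not decline with age")
    else:
        x_star = -b0 / b1
        age_days = float(rec.means[age_col] + rec.sds[age_col] * x_star)
        thr = ThresholdResult(age_days / T.DAYS_PER_YEAR, True)
    return fit, lr, thr


def single_senior_subset_refit(
    best_spec: ModelSpec, data: pd.DataFrame,
    winning: pd.DataFrame, losing: pd.DataFrame,
) -> pd.DataFrame:
    """Refit the best-fit contest model on single-senior-male contests.

    The subset keeps contests whose senior-male-holding group had exactly one
    oldest male.  Returns side-by-side coefficient estimates (full vs subset).
    """
    seniors = _concat_records(winning, losing)
    per_contest = seniors.groupby("contest_id").size()
    keep = set(per_contest.index[per_contest == 1])
    sub = data.loc[data["contest_id"].isin(keep)]
    if len(sub) == 0:
        raise PipelineError("no single-senior-male contests in the dataset")
    full_fit = fit_glmm(best_spec, data)
    sub_fit = fit_glmm(best_spec, sub)
    out = pd.DataFrame(
        dict(full=full_fit.beta, full_se=full_fit.se,
             subset=sub_fit.beta, subset_se=sub_fit.se)
    )
    out["abs_diff_in_se"] = (out["subset"] - out["full"]).abs() / out["full_se"]
    return out


def eviction_model(
    evictions: pd.DataFrame, age_col: str = "age_days",
) -> tuple[GlmmFit, LRTestResult]:
    """Eviction probability vs male age.

    Binomial GLMM evicted ~ scaled(age) with crossed random intercepts for
    male, group and eviction event.
    """
    if evictions["evicted"].sum() < 1:
        raise FitError("no eviction events in the table")
    df, _ = scale_predictors(evictions.copy(), [age_col])
    spec = ModelSpec(response="evicted", fixed=(age_col,),
                     random=("male_id", "group_id", "event_id"), family="binomial")
    fit = fit_glmm(spec, df)
    lr = drop1_lr(fit, age_col, df)
    return fit, lr


def paternity_model(
    litters: pd.DataFrame, age_col: str = "senior_male_age_days",
) -> tuple[GlmmFit, LRTestResult]:
    """Share of the litter sired by the senior male vs his age.

    Binomial GLMM on (sired, litter_size − sired) with scaled age and a random
    intercept for male identity.
    """
    if (litters["litter_size"] < 1).any():
        raise FitError("litter sizes must be >= 1")
    df, _ = scale_predictors(litters.copy(), [age_col])
    spec = ModelSpec(response="sired", fixed=(age_col,),
                     random=("senior_male_id",), family="binomial",
                     trials="litter_size")
    fit = fit_glmm(spec, df)
    lr = drop1_lr(fit, age_col, df)
    return fit, lr


def dimorphism_models(
    weights: pd.DataFrame, head_widths: pd.DataFrame, individuals: pd.DataFrame,
    exclude_pregnant: bool = True,
) -> dict:
    """Sex differences in weight and head width.

    trait ~ sex + (1 | individual), ML, with a single-term-deletion LR test for
    sex.  Pregnant females are excluded from the weight model by default.
    """
    sex_map = individuals.set_index("individual_id")["sex"]

    def _one(df, value_col):
        d = df.copy()
        d["sex_male"] = (d["individual_id"].map(sex_map) == "M").astype(float)
        if d["sex_male"].nunique() < 2:
            raise FitError("both sexes must be present")
        if d.groupby("sex_male")["individual_id"].nunique().min() < 2:
            raise FitError("need >= 2 individuals per sex")
        spec = ModelSpec(response=value_col, fixed=("sex_male",),
                         random=("individual_id",), family="gaussian")
        fit = fit_lmm(spec, d, reml=False)
        lr = drop1_lr(fit, "sex_male", d)
        return fit, lr

    w = weights.dropna(subset=["weight_g"])
    if exclude_pregnant and "pregnant" in w.columns:
        w = w.loc[~w["pregnant"].astype(bool)]
    out = {"weight": _one(w, "weight_g")}
    if head_widths is not None and len(head_widths):
        out["head_width"] = _one(head_widths, "head_width_mm")
    return out


# ---------------------------------------------------------------------------
# descriptive proportions


def format_proportion(k: int, n: int) -> str:
    """Report style: 'k/n males, x.y%'."""
    return f"{k}/{n}, {100.0 * k / n:.1f}%"


def descriptive_proportions(
    winning: pd.DataFrame, losing: pd.DataFrame, member_table: pd.DataFrame,
    head_widths: pd.DataFrame | None = None,
) -> dict:
    """The report-level proportions around senior males.

    Returns counts + fractions for: contests with multiple same-age senior
    males, senior-male totals, same-age-mate and dominance proportions by
    outcome, and oldest-also-heaviest / oldest-also-widest-head proportions.
    """
    seniors = _concat_records(winning, losing)
    out = {}
    per_contest = seniors.groupby("contest_id").size()
    n_contests = len(per_contest)
    multi = per_contest[per_contest > 1]
    out["n_contests"] = n_contests
    out["n_senior_records"] = len(seniors)
    out["n_multi_senior_contests"] = int(len(multi))
    out["multi_senior_fraction"] = len(multi) / n_contests if n_contests else np.nan
    out["winning_same_age"] = _prop(
        int((winning["n_same_age_mates"] > 0).sum()), len(winning))
    out["losing_same_age"] = _prop(
        int((losing["n_same_age_mates"] > 0).sum()), len(losing))
    out["winning_dominant"] = _prop(int(winning["dominant"].sum()), len(winning))
    out["losing_dominant"] = _prop(int(losing["dominant"].sum()), len(losing))

    # oldest-also-heaviest among unique (contest, male) senior records with weights
    males = member_table.loc[member_table["sex"] == "M"]
    heaviest_hits, heaviest_n = 0, 0
    for _, r in seniors.drop_duplicates(["contest_id", "male_id"]).iterrows():
        grp = males.loc[
            (males["contest_id"] == r["contest_id"])
            & (males["group_id"] == r["group_id"])
        ]
        if grp["weight_g"].isna().any() or len(grp) < 2:
            continue
        target = grp.loc[grp["individual_id"] == r["male_id"], "weight_g"]
        if len(target) == 0:
            continue
        heaviest_n += 1
        if float(target.iloc[0]) >= grp["weight_g"].max():
            heaviest_hits += 1
    out["oldest_also_heaviest"] = _prop(heaviest_hits, heaviest_n)
    return out


def _prop(k: int, n: int) -> dict:
    return dict(k=k, n=n, fraction=k / n if n else np.nan,
                text=format_proportion(k, n) if n else "0/0")
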