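"""Truncated-normal weight imputation and growth-curve validation.

A group roster is *eligible* for imputation when at most 20% of its members
lack a usable contest weight.  Each missing weight is replaced by one draw
from a truncated normal whose (untruncated) mean and SD equal those of a
reference sample: same-group, same-sex (and, for females, same pregnancy
status) individuals within ±60 d of the target's age, each weighed within the
120 d before the contest.  Truncation bounds default to the reference sample's
[min, max], which keeps every draw inside the observed biological range; an
n = 1 reference set is imputed deterministically as that single value.

Contests in which either roster is ineligible, or in which a missing member
has an empty reference set, are dropped from the contest dataset — the
analysis proceeds on the complete-data subset, with repeated re-draws handled
by :mod:`grouprhp.iterate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import tables as T
from .errors import ConfigurationError, ImputationError


@dataclass
class ImputationConfig:
    max_missing_fraction: float = 0.2
    age_window_days: int = 60
    weight_window_days: int = T.WEIGHT_WINDOW_DAYS
    bounds: str = "minmax"  # or "nonnegative"
    seed: int | None = None

    def validate(self):
        if not (0.0 < self.max_missing_fraction < 1.0):
            raise ConfigurationError("max_missing_fraction must lie in (0, 1)")
        if self.age_window_days <= 0 or self.weight_window_days <= 0:
            raise ConfigurationError("imputation windows must be > 0")
        if self.bounds not in ("minmax", "nonnegative"):
            raise ConfigurationError(f"unknown bounds rule {self.bounds!r}")


def eligibility(roster: pd.DataFrame, config: ImputationConfig) -> tuple[bool, float]:
    """(eligible, missing fraction) for one roster; ≤ max_missing_fraction passes."""
    config.validate()
    if len(roster) == 0:
        raise ImputationError("empty roster")
    frac = float(roster["weight_g"].isna().mean())
    return frac <= config.max_missing_fraction, frac


def reference_set(
    target: pd.Series, members: pd.DataFrame, config: ImputationConfig
) -> np.ndarray:
    """Reference weights for one missing member.

    ``members`` lists the target's group on the contest date (all ages, with
    nearest-in-window weights attached).  Candidates share the target's sex
    (and pregnancy status for females), lie within ±age_window of the target's
    age, have an observed weight, and exclude the target itself.
    """
    cand = members.loc[members["individual_id"] != target["individual_id"]]
    cand = cand.loc[cand["sex"] == target["sex"]]
    if target["sex"] == "F":
        cand = cand.loc[cand["pregnant"] == bool(target["pregnant"])]
    cand = cand.loc[
        (cand["age_days"] - target["age_days"]).abs() <= config.age_window_days
    ]
    cand = cand.loc[cand["weight_g"].notna()]
    return cand["weight_g"].to_numpy(float)


def truncnorm_draw(mean, sd, lo, hi, rng) -> float:
    """One draw from N(mean, sd²) truncated to [lo, hi] (untruncated moments)."""
    if lo > hi:
        raise ImputationError("inverted truncation bounds")
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


@dataclass
class ImputationPlan:
    """Precomputed reference statistics for every missing contest weight.

    The reference sets depend only on the (fixed) missingness pattern, so
    repeated imputation iterations reduce to fresh truncated-normal draws from
    this plan.  ``rows`` indexes the member table; contests listed in
    ``dropped`` failed eligibility or had an empty reference set.
    """

    rows: np.ndarray
    contest_ids: np.ndarray
    individual_ids: np.ndarray
    n_ref: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    dropped: pd.DataFrame
    kept_contests: pd.Index

    def log_frame(self, imputed: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                contest_id=self.contest_ids,
                individual_id=self.individual_ids,
                imputed_weight_g=imputed,
                reference_n=self.n_ref,
                reference_mean=self.mean,
                reference_sd=self.sd,
                lower=self.lo,
                upper=self.hi,
            )
        )


def build_plan(
    tables: T.StudyTables,
    member_table: pd.DataFrame,
    config: ImputationConfig,
    reference_members: pd.DataFrame | None = None,
) -> ImputationPlan:
    """Derive reference statistics for every missing weight in ``member_table``.

    ``reference_members`` defaults to the all-ages member table built from the
    same contests (reference candidates need not be adults).
    """
    config.validate()
    if reference_members is None:
        contests = tables.contests.loc[
            tables.contests["contest_id"].isin(member_table["contest_id"].unique())
        ]
        reference_members = T.build_member_table(tables, contests, adults_only=False)

    mt = member_table.reset_index(drop=True)
    missing = mt.loc[mt["weight_g"].isna()]
    ref_groups = dict(tuple(reference_members.groupby(["contest_id", "group_id"])))

    dropped_rows = []
    # eligibility per roster
    frac = mt["weight_g"].isna().groupby([mt["contest_id"], mt["side"]]).mean()
    bad = frac[frac > config.max_missing_fraction]
    dropped_ids = set()
    for (cid, side), f in bad.items():
        dropped_ids.add(cid)
        dropped_rows.append(dict(contest_id=cid, reason=f"{side} roster {f:.0%} missing"))

    rows, cids, iids, n_ref, means, sds, los, his = ([] for _ in range(8))
    for idx, target in missing.iterrows():
        cid = target["contest_id"]
        if cid in dropped_ids:
            continue
        members = ref_groups.get((cid, target["group_id"]))
        refs = (
            reference_set(target, members, config)
            if members is not None
            else np.empty(0)
        )
        if len(refs) == 0:
            dropped_ids.add(cid)
            dropped_rows.append(
                dict(contest_id=cid,
                     reason=f"empty reference set for {target['individual_id']}")
            )
            continue
        mean = float(refs.mean())
        sd = float(refs.std(ddof=1)) if len(refs) > 1 else 0.0
        if config.bounds == "minmax":
            lo, hi = float(refs.min()), float(refs.max())
        else:
            lo, hi = 0.0, np.inf
        rows.append(idx); cids.append(cid); iids.append(target["individual_id"])
        n_ref.append(len(refs)); means.append(mean); sds.append(sd)
        los.append(lo); his.append(hi)

    keep = ~np.isin(np.array(cids, dtype=object), list(dropped_ids))
    kept_contests = pd.Index(
        [c for c in pd.unique(mt["contest_id"]) if c not in dropped_ids]
    )
    return ImputationPlan(
        rows=np.array(rows, dtype=int)[keep],
        contest_ids=np.array(cids, dtype=object)[keep],
        individual_ids=np.array(iids, dtype=object)[keep],
        n_ref=np.array(n_ref, dtype=int)[keep],
        mean=np.array(means)[keep],
        sd=np.array(sds)[keep],
        lo=np.array(los)[keep],
        hi=np.array(his)[keep],
        dropped=pd.DataFrame(dropped_rows, columns=["contest_id", "reason"]),
        kept_contests=kept_contests,
    )


def draw_imputations(plan: ImputationPlan, rng: np.random.Generator) -> np.ndarray:
    """One imputed weight per plan row (vectorised truncated-normal sampling)."""
    out = plan.mean.copy()
    stochastic = plan.sd > 0
    if stochastic.any():
        mean = plan.mean[stochastic]
        sd = plan.sd[stochastic]
        a = (plan.lo[stochastic] - mean) / sd
        b = (plan.hi[stochastic] - mean) / sd
        out[stochastic] = stats.truncnorm.rvs(
            a, b, loc=mean, scale=sd, random_state=rng
        )
    return out


def impute(
    roster: pd.DataFrame,
    tables: T.StudyTables,
    config: ImputationConfig,
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute one roster's missing weights; returns (completed roster, draw log).

    Raises :class:`ImputationError` if the roster is ineligible or any missing
    member lacks references.  Observed weights are never modified.
    """
    ok, frac = eligibility(roster, config)
    if not ok:
        raise ImputationError(f"roster ineligible: {frac:.0%} of weights missing")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    cid = roster["contest_id"].iloc[0]
    contests = tables.contests.loc[tables.contests["contest_id"] == cid]
    members_all = T.build_member_table(tables, contests, adults_only=False)
    members_all = members_all.loc[members_all["group_id"] == roster["group_id"].iloc[0]]

    out = roster.copy()
    log_rows = []
    for idx, target in roster.loc[roster["weight_g"].isna()].iterrows():
        refs = reference_set(target, members_all, config)
        if len(refs) == 0:
            raise ImputationError(
                f"empty reference set for {target['individual_id']} in contest {cid}"
            )
        mean = float(refs.mean())
        sd = float(refs.std(ddof=1)) if len(refs) > 1 else 0.0
        lo, hi = (
            (float(refs.min()), float(refs.max()))
            if config.bounds == "minmax"
            else (0.0, np.inf)
        )
        value = mean if sd == 0 else truncnorm_draw(mean, sd, lo, hi, rng)
        out.loc[idx, "weight_g"] = value
        log_rows.append(
            dict(contest_id=cid, individual_id=target["individual_id"],
                 imputed_weight_g=value, reference_n=len(refs),
                 reference_mean=mean, reference_sd=sd, lower=lo, upper=hi)
        )
    return out, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# growth-curve validation


def fit_growth_curve(age_days, weight_g) -> dict:
    """Nonlinear least squares for the 3-parameter asymptotic curve.

    Self-started: c from the smallest weights, d from the largest, e from the
    age at half rise.  Returns parameter estimates, SEs and a convergence flag.
    """
    age = np.asarray(age_days, float)
    wt = np.asarray(weight_g, float)
    ok = np.isfinite(age) & np.isfinite(wt)
    age, wt = age[ok], wt[ok]
    if len(age) < 5:
        return dict(converged=False, n=len(age))

    def f(x, c, d, e):
        return c + (d - c) * (1.0 - np.exp(-x / e))

    c0 = max(float(np.percentile(wt, 2)), 1.0)
    d0 = float(np.percentile(wt, 98))
    half = (c0 + d0) / 2.0
    above = age[wt >= half]
    e0 = float(above.min() / np.log(2.0)) if len(above) and above.min() > 0 else 200.0
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                f, age, wt, p0=(c0, max(d0, c0 + 1), max(e0, 1.0)), maxfev=20000
            )
        se = np.sqrt(np.diag(pcov))
        return dict(
            converged=bool(np.all(np.isfinite(se))), n=len(age),
            lower=popt[0], asymptote=popt[1], rate_days=popt[2],
            lower_se=se[0], asymptote_se=se[1], rate_days_se=se[2],
        )
    except (RuntimeError, ValueError):
        return dict(converged=False, n=len(age))


def validate_growth(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Per-group growth-parameter comparison before vs after imputation.

    Both frames need columns group_id, age_days, weight_g; ``pre`` is the
    observed-only dataset, ``post`` includes imputed values.  Reports the three
    parameters from each fit, their differences, joint SEs, and whether the
    approximate 95% intervals overlap.  Non-convergence is flagged per group,
    not fatal.
    """
    rows = []
    for gid in sorted(set(pre["group_id"]) | set(post["group_id"])):
        a = pre.loc[pre["group_id"] == gid]
        b = post.loc[post["group_id"] == gid]
        fa = fit_growth_curve(a["age_days"], a["weight_g"])
        fb = fit_growth_curve(b["age_days"], b["weight_g"])
        row = dict(group_id=gid,
                   converged=bool(fa.get("converged") and fb.get("converged")))
        if row["converged"]:
            for par in ("lower", "asymptote", "rate_days"):
                row[f"{par}_pre"] = fa[par]
                row[f"{par}_post"] = fb[par]
                row[f"{par}_diff"] = fb[par] - fa[par]
                joint = float(np.hypot(fa[f"{par}_se"], fb[f"{par}_se"]))
                row[f"{par}_joint_se"] = joint
                row[f"{par}_ci_overlap"] = bool(
                    abs(row[f"{par}_diff"]) <= 1.96 * joint or joint == 0.0
                )
        rows.append(row)
    return pd.DataFrame(rows)
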