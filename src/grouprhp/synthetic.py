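"""Synthetic study populations, weight trajectories, contests, and missingness.

The generator emulates the structure the contest analysis assumes: ~11 social
groups of ~20 adults with a male-biased sex ratio (1.6 M : 1 F), asymptotic
weight growth with sexual dimorphism (male asymptote ≈ 1440 g, female ≈ 1293 g,
matching the population weight means), and dyadic contests whose outcomes
follow a logistic model on scaled relative predictors plus latent group
abilities.  Three weight-missingness mechanisms are provided:
completely-at-random masking of observations (:func:`apply_missingness`), an
age-dependent missing-at-random variant, and the pipeline default
(:func:`apply_missingness_clustered`) in which whole individuals are
unweighable at group-clustered rates averaging 22.1%, the mechanism that
reproduces the field statistics of long-term studies.

Every generator is a pure function of (config, seed): the same inputs yield
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import tables as T
from .errors import ConfigurationError, GenerationError
from .tables import PREDICTOR_NAMES, StudyTables


@dataclass(frozen=True)
class GrowthParams:
    """Three-parameter asymptotic growth curve.

    ``lower`` (c) is the curve's lower limit in grams, ``asymptote`` (d) its
    upper limit, and ``rate_days`` (e) the e-folding timescale of the rise.
    """

    lower: float
    asymptote: float
    rate_days: float

    def __post_init__(self):
        if not (0 < self.lower < self.asymptote):
            raise ConfigurationError("GrowthParams: need 0 < lower < asymptote")
        if self.rate_days <= 0:
            raise ConfigurationError("GrowthParams: rate_days must be > 0")


def growth_weight(age_days, params: GrowthParams):
    """Expected weight (g) at ``age_days``: c + (d − c)·(1 − exp(−age/e)).

    Strictly increasing in age and bounded above by the asymptote.  Negative
    ages are a domain error.
    """
    age = np.asarray(age_days, dtype=float)
    if np.any(age < 0):
        raise ValueError("growth_weight: age must be >= 0")
    c, d, e = params.lower, params.asymptote, params.rate_days
    out = c + (d - c) * (1.0 - np.exp(-age / e))
    return out if out.ndim else float(out)


#: Default sex-specific growth: asymptotes from the population weight means
#: (males 1440 g, females 1293 g); a shared 300 g lower limit and a 200 d rise
#: timescale give near-asymptotic adult weights by age ~2 y.
DEFAULT_GROWTH = {
    "M": GrowthParams(300.0, 1440.0, 200.0),
    "F": GrowthParams(300.0, 1293.0, 200.0),
}


@dataclass
class PopulationConfig:
    """Stated world for the synthetic population.

    11 groups averaging 20 adults (the total is exact; sizes vary
    multinomially across groups) and per-individual male probability 1.6/2.6 ≈
    0.615 (a 1.6:1 adult sex ratio).  Ages at the window start follow a
    bottom-heavy exponential pyramid (mean ~2 y above a 0.75 y floor, capped by
    the birth-date range), and births snap to a per-group grid of communal
    litter dates — females of a group give birth synchronously, so same-age
    group mates (the imputation reference pool, and occasionally tied senior
    males) are a real feature of these societies; the default grid spacing of
    one year stands for the roughly annual pulses of recruits that survive to
    adulthood.  Each group also carries a cohort of current offspring below the
    adult age floor.  Weighings are fortnightly with 80 g measurement noise; 30%
    of each group's males are flagged dominant per breeding cycle.
    """

    n_groups: int = 11
    adults_per_group: int = 20
    male_fraction: float = 1.6 / 2.6
    birth_date_range: tuple = ("2005-01-01", "2016-06-30")
    study_window: tuple = ("2017-07-01", "2018-12-31")
    growth_params_by_sex: dict = field(default_factory=lambda: dict(DEFAULT_GROWTH))
    weight_noise_sd: float = 80.0
    individual_asymptote_sd: float = 150.0
    weighing_interval_days: int = 14
    dominant_male_fraction: float = 0.3
    guard_cycle_days: int = 90
    age_pyramid_mean_years: float = 2.0
    min_age_at_window_years: float = 0.75
    elder_fraction: float = 0.15
    elder_age_range_years: tuple = (5.0, 11.5)
    litter_interval_days: int = 365
    offspring_per_group: int = 8
    weights_from_age_days: int = 60
    weights_history_days: int | None = None
    seed: int = 0

    def validate(self):
        if self.n_groups < 2:
            raise ConfigurationError("n_groups must be >= 2")
        if self.adults_per_group < 2:
            raise ConfigurationError("adults_per_group must be >= 2")
        if not (0.0 < self.male_fraction < 1.0):
            raise ConfigurationError("male_fraction must lie in (0, 1)")
        if self.weight_noise_sd < 0:
            raise ConfigurationError("weight_noise_sd must be >= 0")
        if self.individual_asymptote_sd < 0:
            raise ConfigurationError("individual_asymptote_sd must be >= 0")
        if self.weighing_interval_days <= 0:
            raise ConfigurationError("weighing_interval_days must be > 0")
        if not (0.0 <= self.dominant_male_fraction < 1.0):
            raise ConfigurationError("dominant_male_fraction must lie in [0, 1)")
        for sex in ("M", "F"):
            if sex not in self.growth_params_by_sex:
                raise ConfigurationError(f"growth_params_by_sex missing sex {sex!r}")


def generate_population(config: PopulationConfig) -> StudyTables:
    """Individuals, memberships, weight histories and guard events.

    Each individual belongs to one group for the whole study.  Weights are
    observed on a per-individual fortnightly grid from ``weights_from_age_days``
    (so trajectories include the juvenile rise, which growth-curve validation
    needs) through the end of the study window, with Gaussian measurement
    noise.  Per group, a fixed fraction of males mate-guards every
    ``guard_cycle_days``, so rosters show a stable dominant/subordinate split.
    ``weights_history_days`` optionally truncates the history to the N days
    before the window's end (a speed knob for simulation studies).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    b0, b1 = (pd.Timestamp(d) for d in config.birth_date_range)
    w0, w1 = (pd.Timestamp(d) for d in config.study_window)
    if not (b0 < b1 <= w1):
        raise ConfigurationError("birth_date_range must precede the study window end")

    n = config.n_groups * config.adults_per_group
    group_ids = [f"G{g:02d}" for g in range(config.n_groups)]
    ind_rows, weight_rows, guard_rows, mem_rows = [], [], [], []
    span_days = (b1 - b0).days
    hist_start = None
    if config.weights_history_days is not None:
        hist_start = w1 - pd.Timedelta(days=int(config.weights_history_days))

    # group sizes vary (real groups do); the population total is forced by the
    # config.  Multinomial allocation, floored at 2 members per group.
    sizes = rng.multinomial(n, np.full(config.n_groups, 1.0 / config.n_groups))
    while sizes.min() < 2:
        sizes[np.argmax(sizes)] -= 1
        sizes[np.argmin(sizes)] += 1

    for g, gid in enumerate(group_ids):
        size = int(sizes[g])
        draws = rng.random(size) < config.male_fraction
        # every group needs both sexes represented
        if draws.all():
            draws[rng.integers(size)] = False
        if not draws.any():
            draws[rng.integers(size)] = True
        sexes = ["M" if d else "F" for d in draws]
        # per-group communal litter grid: births can only fall on these dates
        # (extends past the adult birth range so current offspring have litters)
        phase = int(rng.integers(0, config.litter_interval_days))
        grid = pd.date_range(
            b0 + pd.Timedelta(days=phase), w1, freq=f"{config.litter_interval_days}D"
        )
        grid_days = np.array([(d - b0).days for d in grid])
        adult_grid_days = grid_days[grid_days <= (b1 - b0).days]
        males = []
        min_age_d = config.min_age_at_window_years * T.DAYS_PER_YEAR
        mean_excess_d = max(
            (config.age_pyramid_mean_years - config.min_age_at_window_years)
            * T.DAYS_PER_YEAR,
            1.0,
        )
        # current offspring cohort: under the adult age floor at the window start
        kid_sexes = ["M" if d else "F"
                     for d in rng.random(config.offspring_per_group) < config.male_fraction]
        for k, sex in enumerate(sexes + kid_sexes):
            juvenile = k >= size
            iid = f"{gid}-{sex}{k:02d}"
            if juvenile:
                age_at_w0 = rng.uniform(config.weights_from_age_days + 1, min_age_d)
                pool = grid_days
            elif rng.random() < config.elder_fraction:
                # long-lived elders: the pool senior males come from
                lo, hi = config.elder_age_range_years
                age_at_w0 = rng.uniform(lo, hi) * T.DAYS_PER_YEAR
                pool = adult_grid_days
            else:
                age_at_w0 = min_age_d + rng.exponential(mean_excess_d)
                pool = adult_grid_days
            target = w0 - pd.Timedelta(days=int(age_at_w0))
            target = min(max(target, b0), b1 if not juvenile else w1)
            tdays = (target - b0).days
            birth = b0 + pd.Timedelta(
                days=int(pool[np.argmin(np.abs(pool - tdays))])
            )
            ind_rows.append(
                dict(individual_id=iid, sex=sex, birth_date=birth,
                     immigrant=False, immigration_date=pd.NaT)
            )
            mem_rows.append(dict(individual_id=iid, group_id=gid,
                                 start_date=birth, end_date=pd.NaT))
            if sex == "M" and not juvenile:
                males.append(iid)
            gp = config.growth_params_by_sex[sex]
            if config.individual_asymptote_sd > 0:
                # persistent between-individual size variation: without it the
                # population would show far lower weight repeatability than
                # real long-term datasets do
                d_i = gp.asymptote + rng.normal(0.0, config.individual_asymptote_sd)
                gp = GrowthParams(gp.lower, max(d_i, gp.lower + 50.0), gp.rate_days)
            first = birth + pd.Timedelta(days=int(config.weights_from_age_days))
            first += pd.Timedelta(days=int(rng.integers(0, config.weighing_interval_days)))
            if hist_start is not None and first < hist_start:
                shift = int(
                    np.ceil((hist_start - first).days / config.weighing_interval_days)
                ) * config.weighing_interval_days
                first += pd.Timedelta(days=shift)
            obs_dates = pd.date_range(first, w1, freq=f"{config.weighing_interval_days}D")
            if len(obs_dates) == 0:
                continue
            ages = (obs_dates - birth).days.to_numpy(float)
            mu = growth_weight(ages, gp)
            noise = rng.normal(0.0, config.weight_noise_sd, len(ages))
            for dt, wt in zip(obs_dates, mu + noise):
                weight_rows.append(
                    dict(individual_id=iid, obs_date=dt, weight_g=wt, pregnant=False)
                )
        # mate-guarding rotates by breeding cycle and is age-biased (older males
        # monopolise estrus females); at least one male is always subordinate
        cycle_dates = pd.date_range(
            w0 - pd.Timedelta(days=T.DOMINANCE_WINDOW_DAYS), w1,
            freq=f"{config.guard_cycle_days}D",
        )
        if config.dominant_male_fraction > 0 and len(males) > 1:
            birth_by_male = {
                r["individual_id"]: r["birth_date"]
                for r in ind_rows
                if r["individual_id"] in set(males)
            }
            for dt in cycle_dates:
                # how many males guard varies with the cycle's estrus females
                n_dom = int(rng.binomial(len(males), config.dominant_male_fraction))
                n_dom = min(n_dom, len(males) - 1)
                if n_dom == 0:
                    continue
                ages = np.array(
                    [(dt - birth_by_male[m]).days for m in males], dtype=float
                )
                ages = np.maximum(ages, 1.0)
                prob = ages / ages.sum()
                guards = rng.choice(males, size=n_dom, replace=False, p=prob)
                for male in guards:
                    guard_rows.append(dict(male_id=male, date=dt))

    return StudyTables(
        individuals=pd.DataFrame(ind_rows),
        memberships=pd.DataFrame(mem_rows),
        weights=pd.DataFrame(weight_rows),
        guard_events=pd.DataFrame(guard_rows) if guard_rows else T._empty("guard_events"),
    )


@dataclass
class ContestGenConfig:
    """Ground-truth contest outcome model.

    ``true_beta`` acts on predictors scaled to unit variance across the
    generated contest set; group abilities are i.i.d. Normal(0, ability_sd²)
    on the logit scale.  Defaults put real effects on the male count and the
    oldest-male age only.
    """

    n_contests: int = 300
    true_beta: dict = field(
        default_factory=lambda: {"rel_n_males": 1.0, "rel_max_age_males": 0.6}
    )
    ability_sd: float = 0.5
    seed: int = 0
    max_resample: int = 200

    def validate(self):
        if self.n_contests < 1:
            raise ConfigurationError("n_contests must be >= 1")
        if self.ability_sd < 0:
            raise ConfigurationError("ability_sd must be >= 0")
        unknown = set(self.true_beta) - set(PREDICTOR_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown predictors in true_beta: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Generator ground truth, for recovery tests."""

    true_beta: dict
    group_abilities: dict
    growth_params: dict
    missing_rate: float = 0.0


def generate_contests(
    tables: StudyTables, config: ContestGenConfig,
    population_config: PopulationConfig | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Contest table + ground truth.

    Pairings and dates are uniform over distinct group pairs and the study
    window; pairings whose rosters fail the one-male/one-subordinate-male rule
    are resampled (bounded).  Outcomes are Bernoulli draws from
    logit P(focal wins) = Σβ·x_scaled + a_focal − a_rival, computed on the
    complete (pre-missingness) weights.
    """
    config.validate()
    pc = population_config or PopulationConfig()
    rng = np.random.default_rng(config.seed)
    w0, w1 = (pd.Timestamp(d) for d in pc.study_window)
    span = (w1 - w0).days
    group_ids = sorted(tables.memberships["group_id"].unique())
    if len(group_ids) < 2:
        raise GenerationError("need at least two groups to stage contests")

    abilities = dict(zip(group_ids, rng.normal(0.0, config.ability_sd, len(group_ids))))

    # propose pairings in batches, keep the eligible weight-complete ones, and
    # resample the shortfall (bounded)
    batches, n_kept = [], 0
    for round_ in range(config.max_resample):
        need = config.n_contests - n_kept
        if need == 0:
            break
        dates = w0 + pd.to_timedelta(rng.integers(0, span + 1, need), unit="D")
        pairs = np.array([rng.choice(len(group_ids), size=2, replace=False)
                          for _ in range(need)])
        cand = pd.DataFrame(
            dict(
                contest_id=[f"T{round_:03d}-{j:04d}" for j in range(need)],
                date=dates,
                focal_group_id=[group_ids[i] for i in pairs[:, 0]],
                rival_group_id=[group_ids[i] for i in pairs[:, 1]],
                focal_win=0,
            )
        )
        mt = T.build_member_table(tables, cand)
        ok_ids = set(T.eligible_contest_ids(mt))
        complete = mt.groupby("contest_id")["weight_g"].agg(lambda s: not s.isna().any())
        ok_ids &= set(complete.index[complete])
        good = cand.loc[cand["contest_id"].isin(ok_ids)]
        batches.append(good)
        n_kept += len(good)
    if n_kept < config.n_contests:
        raise GenerationError(
            "could not assemble enough eligible pairings within max_resample rounds"
        )
    contests = pd.concat(batches, ignore_index=True).iloc[: config.n_contests].copy()
    contests["contest_id"] = [f"C{k:04d}" for k in range(len(contests))]
    contests = contests.sort_values("date", kind="stable").reset_index(drop=True)
    mt = T.build_member_table(tables, contests)
    X = T.predictor_matrix(mt).loc[contests["contest_id"]]
    sd = X.std(ddof=1)
    if (sd == 0).any():
        raise GenerationError("degenerate predictor (zero variance) in generated contests")
    Xs = (X - X.mean()) / sd
    eta = np.zeros(len(contests))
    for name, beta in config.true_beta.items():
        eta += beta * Xs[name].to_numpy()
    eta += contests["focal_group_id"].map(abilities).to_numpy()
    eta -= contests["rival_group_id"].map(abilities).to_numpy()
    contests["focal_win"] = (rng.random(len(contests)) < expit(eta)).astype(int)

    truth = SyntheticTruth(
        true_beta=dict(config.true_beta),
        group_abilities=abilities,
        growth_params=dict(pc.growth_params_by_sex),
        missing_rate=0.0,
    )
    return contests, truth


def apply_missingness(
    weights: pd.DataFrame, rate: float, seed: int
) -> pd.DataFrame:
    """Mask each weight observation independently with probability ``rate``.

    Masked rows keep their date (the weighing happened; the value is unusable),
    with ``weight_g`` set to NaN and ``masked=True``.  Completely-at-random is
    the default mechanism; see :func:`apply_missingness_by_age` for a
    missing-at-random alternative.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("missingness rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = weights.copy().reset_index(drop=True)
    mask = rng.random(len(out)) < rate
    out["masked"] = mask
    out.loc[mask, "weight_g"] = np.nan
    return out


def apply_missingness_clustered(
    weights: pd.DataFrame, memberships: pd.DataFrame, rate: float, seed: int,
    concentration: float = 0.14,
) -> pd.DataFrame:
    """Mask whole individuals, with group-clustered unweighability.

    Field reality: missing weights come from animals that cannot be weighed at
    all (unhabituated or trap-shy), and how well a group is weighed varies by
    group.  Each group g draws an unweighability rate r_g ~ Beta(α, α(1−m)/m)
    with mean m = ``rate``; each of its members is masked (all observations)
    with probability r_g.  The default concentration α = 0.14 makes a pair of
    ~20-member rosters carry at least one missing weight about 72% of the time
    at the 22.1% population rate.
    """
    if not (0.0 < rate < 1.0):
        raise ValueError("rate must lie in (0, 1)")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    alpha = concentration
    beta = alpha * (1.0 - rate) / rate
    masked_ids = []
    for gid, grp in memberships.groupby("group_id"):
        r = rng.beta(alpha, beta)
        ids = grp["individual_id"].unique()
        masked_ids.extend(ids[rng.random(len(ids)) < r])
    masked_ids = set(masked_ids)
    out = weights.copy().reset_index(drop=True)
    out["masked"] = out["individual_id"].isin(masked_ids)
    out.loc[out["masked"], "weight_g"] = np.nan
    return out


def apply_missingness_by_age(
    weights: pd.DataFrame, individuals: pd.DataFrame, base_rate: float,
    age_slope_per_year: float, seed: int,
) -> pd.DataFrame:
    """Age-dependent (missing-at-random) masking for robustness experiments.

    The per-observation masking probability is
    logit⁻¹(logit(base_rate) + slope·(age_years − mean age)), clipped to [0, 1).
    """
    if not (0.0 < base_rate < 1.0):
        raise ValueError("base_rate must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    out = weights.merge(
        individuals[["individual_id", "birth_date"]], on="individual_id", how="left"
    ).reset_index(drop=True)
    age_y = (out["obs_date"] - out["birth_date"]).dt.days / T.DAYS_PER_YEAR
    z = np.log(base_rate / (1 - base_rate)) + age_slope_per_year * (age_y - age_y.mean())
    p = expit(z)
    mask = rng.random(len(out)) < p
    out = out.drop(columns=["birth_date"])
    out["masked"] = mask
    out.loc[mask, "weight_g"] = np.nan
    return out
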