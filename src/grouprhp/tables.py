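"""Tabular data model: long-format study tables, per-contest rosters, relative predictors.

The pipeline works from a handful of long-format CSV tables (real or synthetic):

``individuals``
    individual_id, sex (``M``/``F``), birth_date, immigrant (bool),
    immigration_date (blank unless immigrant).
``memberships``
    individual_id, group_id, start_date, end_date (blank = still a member).
``weights``
    individual_id, obs_date, weight_g (may be blank when masked), pregnant (bool,
    status on the weighing date).
``head_widths``
    individual_id, obs_date, head_width_mm.
``contests``
    contest_id, date, focal_group_id, rival_group_id, focal_win (0/1).  Draws are
    excluded upstream; focal/rival labels are arbitrary (see :func:`assign_focal`).
``guard_events``
    male_id, date — one row per observed mate-guarding episode.
``evictions``
    event_id, group_id, male_id, date, evicted (0/1) — one row per male at risk in
    an eviction event.
``litters``
    litter_id, group_id, date, senior_male_id, senior_male_age_days, litter_size,
    sired — pups sired by the senior male out of ``litter_size``.

All dates are ISO-8601 calendar dates.  Ages are integer days everywhere; years
(/365.25) appear only in display-level outputs.

Domain rules implemented here:

* adults are individuals aged strictly more than 183 days (6 months);
* a member's contest weight is the nearest weighing in the closed window
  [contest − 120 d, contest]; otherwise the weight is missing;
* a male is *dominant* at a contest if he mate-guarded within the 180 days before
  the contest (closed window), else *subordinate*;
* immigrants are assumed 2 years (730 d) old on their immigration date;
* a contest is eligible only if both groups field at least one male and at least
  one subordinate male.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

ADULT_AGE_DAYS = 183
WEIGHT_WINDOW_DAYS = 120
DOMINANCE_WINDOW_DAYS = 180
IMMIGRANT_AGE_DAYS = 730
DAYS_PER_YEAR = 365.25

MEMBER_CLASSES = ("all", "males", "submales")

#: The 15 relative (focal minus rival) predictors, grouped by member class.
PREDICTOR_NAMES = tuple(
    f"rel_{stat}_{cls}"
    for cls in MEMBER_CLASSES
    for stat in ("n", "mean_weight", "max_weight", "mean_age", "max_age")
)

_DATE_COLS = {
    "individuals": ["birth_date", "immigration_date"],
    "memberships": ["start_date", "end_date"],
    "weights": ["obs_date"],
    "head_widths": ["obs_date"],
    "contests": ["date"],
    "guard_events": ["date"],
    "evictions": ["date"],
    "litters": ["date"],
}

_BOOL_COLS = {
    "individuals": ["immigrant"],
    "weights": ["pregnant"],
}


@dataclass
class StudyTables:
    """Container for the full set of study tables.

    Optional tables default to empty frames with the right columns so that the
    roster machinery can run on partial datasets.
    """

    individuals: pd.DataFrame
    memberships: pd.DataFrame
    weights: pd.DataFrame
    contests: pd.DataFrame = field(default_factory=lambda: _empty("contests"))
    guard_events: pd.DataFrame = field(default_factory=lambda: _empty("guard_events"))
    head_widths: pd.DataFrame = field(default_factory=lambda: _empty("head_widths"))
    evictions: pd.DataFrame = field(default_factory=lambda: _empty("evictions"))
    litters: pd.DataFrame = field(default_factory=lambda: _empty("litters"))

    def table_names(self):
        return [f.name for f in fields(self)]


_EMPTY_SCHEMAS = {
    "individuals": ["individual_id", "sex", "birth_date", "immigrant", "immigration_date"],
    "memberships": ["individual_id", "group_id", "start_date", "end_date"],
    "weights": ["individual_id", "obs_date", "weight_g", "pregnant"],
    "contests": ["contest_id", "date", "focal_group_id", "rival_group_id", "focal_win"],
    "guard_events": ["male_id", "date"],
    "head_widths": ["individual_id", "obs_date", "head_width_mm"],
    "evictions": ["event_id", "group_id", "male_id", "date", "evicted"],
    "litters": [
        "litter_id", "group_id", "date", "senior_male_id",
        "senior_male_age_days", "litter_size", "sired",
    ],
}


def _empty(name: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in _EMPTY_SCHEMAS[name]})
    for c in _DATE_COLS.get(name, []):
        df[c] = pd.Series(dtype="datetime64[ns]")
    return df


def write_tables(tables: StudyTables, directory) -> None:
    """Write every table as ``<name>.csv`` with ISO dates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in tables.table_names():
        df = getattr(tables, name).copy()
        for c in _DATE_COLS.get(name, []):
            if c in df.columns:
                df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
        df.to_csv(directory / f"{name}.csv", index=False)


def read_tables(directory) -> StudyTables:
    """Read the CSV tables written by :func:`write_tables`.

    Missing optional tables load as empty frames; ``individuals``,
    ``memberships``, ``weights`` and ``contests`` are required.
    """
    directory = Path(directory)
    out = {}
    for name, required in [
        ("individuals", True), ("memberships", True), ("weights", True),
        ("contests", True), ("guard_events", False), ("head_widths", False),
        ("evictions", False), ("litters", False),
    ]:
        path = directory / f"{name}.csv"
        if not path.exists():
            if required:
                raise SchemaError(f"required table {name!r} not found in {directory}")
            continue
        df = pd.read_csv(path)
        for c in _DATE_COLS.get(name, []):
            if c in df.columns:
                df[c] = pd.to_datetime(df[c], format="ISO8601")
        for c in _BOOL_COLS.get(name, []):
            if c in df.columns:
                df[c] = df[c].astype(bool)
        out[name] = df
    return StudyTables(**out)


# ---------------------------------------------------------------------------
# ages


def compute_age(birth_date, on_date, immigrant: bool = False, immigration_date=None) -> int:
    """Age in days on ``on_date``.

    Natives: calendar-day difference from ``birth_date``.  Immigrants: assumed
    730 d old on their immigration date, so 730 + days since immigration.
    """
    on_date = pd.Timestamp(on_date)
    if immigrant:
        if immigration_date is None or pd.isna(immigration_date):
            raise SchemaError("immigrant without an immigration_date")
        base = pd.Timestamp(immigration_date)
        if on_date < base:
            raise ValueError("observation date precedes immigration date")
        return IMMIGRANT_AGE_DAYS + int((on_date - base).days)
    base = pd.Timestamp(birth_date)
    if on_date < base:
        raise ValueError("observation date precedes birth date")
    return int((on_date - base).days)


# ---------------------------------------------------------------------------
# rosters


def build_member_table(
    tables: StudyTables,
    contests: pd.DataFrame | None = None,
    adults_only: bool = True,
) -> pd.DataFrame:
    """One row per (contest, side, group member), with contest-date covariates.

    Columns: contest_id, side ('focal'/'rival'), group_id, date, individual_id,
    sex, age_days, weight_g (NaN when no usable weighing), weight_obs_date,
    pregnant, dominant.

    This vectorised builder is the workhorse behind :func:`build_roster` and the
    predictor machinery.  With ``adults_only=False`` it also lists members aged
    ≤ 183 d (used by imputation reference sets, which window on age, not
    adulthood).
    """
    if contests is None:
        contests = tables.contests
    if len(contests) == 0:
        raise SchemaError("no contests supplied")

    parts = []
    for side, col in (("focal", "focal_group_id"), ("rival", "rival_group_id")):
        t = contests[["contest_id", "date", col]].rename(columns={col: "group_id"})
        t = t.merge(tables.memberships, on="group_id", how="left")
        t["side"] = side
        parts.append(t)
    m = pd.concat(parts, ignore_index=True)
    active = (m["start_date"] <= m["date"]) & (
        m["end_date"].isna() | (m["end_date"] >= m["date"])
    )
    m = m.loc[active].drop(columns=["start_date", "end_date"])
    m = m.merge(tables.individuals, on="individual_id", how="left")

    native_age = (m["date"] - m["birth_date"]).dt.days
    imm_age = IMMIGRANT_AGE_DAYS + (m["date"] - m["immigration_date"]).dt.days
    is_imm = m["immigrant"].fillna(False).astype(bool)
    m["age_days"] = np.where(is_imm, imm_age, native_age)
    m = m.loc[m["age_days"] >= 0]
    if adults_only:
        m = m.loc[m["age_days"] > ADULT_AGE_DAYS]
    m = m.drop(columns=["birth_date", "immigrant", "immigration_date"])

    # nearest *usable* weighing in [date - 120 d, date]: masked observations
    # (weight_g NaN) never attach, so a member is weight-missing only when no
    # valid weighing falls inside the window
    m = m.sort_values("date", kind="stable").reset_index(drop=True)
    w = tables.weights.dropna(subset=["weight_g"]).sort_values("obs_date", kind="stable")
    if len(w):
        matched = pd.merge_asof(
            m[["individual_id", "date"]].reset_index(),
            w[["individual_id", "obs_date", "weight_g", "pregnant"]],
            left_on="date",
            right_on="obs_date",
            by="individual_id",
            direction="backward",
            tolerance=pd.Timedelta(days=WEIGHT_WINDOW_DAYS),
        ).set_index("index")
        m["weight_g"] = matched["weight_g"]
        m["weight_obs_date"] = matched["obs_date"]
        m["pregnant"] = matched["pregnant"].astype("boolean").fillna(False).astype(bool)
    else:
        m["weight_g"] = np.nan
        m["weight_obs_date"] = pd.NaT
        m["pregnant"] = False

    # dominance: male with a guard event in [date - 180 d, date]
    g = tables.guard_events
    if len(g):
        g = g.sort_values("date", kind="stable")
        matched = pd.merge_asof(
            m[["individual_id", "date"]].reset_index(),
            g.rename(columns={"male_id": "individual_id", "date": "guard_date"}),
            left_on="date",
            right_on="guard_date",
            by="individual_id",
            direction="backward",
            tolerance=pd.Timedelta(days=DOMINANCE_WINDOW_DAYS),
        ).set_index("index")
        m["dominant"] = matched["guard_date"].notna() & (m["sex"] == "M")
    else:
        m["dominant"] = False

    cols = [
        "contest_id", "side", "group_id", "date", "individual_id", "sex",
        "age_days", "weight_g", "weight_obs_date", "pregnant", "dominant",
    ]
    return m[cols].reset_index(drop=True)


def build_roster(tables: StudyTables, contest_id) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adult rosters (focal, rival) for a single contest."""
    row = tables.contests.loc[tables.contests["contest_id"] == contest_id]
    if len(row) != 1:
        raise SchemaError(f"contest {contest_id!r} not found (or duplicated)")
    mt = build_member_table(tables, row)
    focal = mt.loc[mt["side"] == "focal"].reset_index(drop=True)
    rival = mt.loc[mt["side"] == "rival"].reset_index(drop=True)
    return focal, rival


def roster_eligible(roster: pd.DataFrame) -> bool:
    """True iff the roster holds ≥1 male and ≥1 subordinate male."""
    males = roster["sex"] == "M"
    return bool(males.any() and (males & ~roster["dominant"]).any())


def eligible_contest_ids(member_table: pd.DataFrame) -> pd.Index:
    """Contests in which *both* groups pass :func:`roster_eligible`."""
    males = member_table["sex"] == "M"
    sub = males & ~member_table["dominant"]
    grp = member_table.groupby(["contest_id", "side"])
    ok = grp.apply(
        lambda d: bool((d["sex"] == "M").any() and ((d["sex"] == "M") & ~d["dominant"]).any()),
        include_groups=False,
    )
    per_contest = ok.groupby(level="contest_id").agg(lambda s: bool(s.all()) and len(s) == 2)
    return per_contest.index[per_contest]


# ---------------------------------------------------------------------------
# relative predictors


class PredictorBuilder:
    """Vectorised computation of the 15 relative predictors.

    Counts and ages are fixed by the member table; only the weight-based
    predictors depend on the (possibly re-imputed) weight vector, so repeated
    imputation iterations can rebuild predictors cheaply via
    :meth:`predictors`.
    """

    def __init__(self, member_table: pd.DataFrame):
        mt = member_table.reset_index(drop=True)
        self.member_table = mt
        self.contest_ids = pd.Index(pd.unique(mt["contest_id"]))
        cidx = self.contest_ids.get_indexer(mt["contest_id"])
        side = (mt["side"].to_numpy() == "rival").astype(int)
        self._key = cidx * 2 + side  # focal slot = 2c, rival slot = 2c+1
        self._nslots = 2 * len(self.contest_ids)
        male = (mt["sex"] == "M").to_numpy()
        sub = male & ~mt["dominant"].to_numpy()
        self._masks = {"all": np.ones(len(mt), bool), "males": male, "submales": sub}
        self._age = mt["age_days"].to_numpy(float)
        self._fixed = {}
        for cls, mask in self._masks.items():
            self._fixed[f"rel_n_{cls}"] = self._diff(self._count(mask))
            self._fixed[f"rel_mean_age_{cls}"] = self._diff(self._mean(self._age, mask))
            self._fixed[f"rel_max_age_{cls}"] = self._diff(self._max(self._age, mask))

    def _count(self, mask):
        return np.bincount(self._key[mask], minlength=self._nslots).astype(float)

    def _mean(self, values, mask):
        n = self._count(mask)
        s = np.bincount(self._key[mask], weights=values[mask], minlength=self._nslots)
        with np.errstate(invalid="ignore", divide="ignore"):
            return s / n

    def _max(self, values, mask):
        out = np.full(self._nslots, -np.inf)
        np.maximum.at(out, self._key[mask], values[mask])
        out[out == -np.inf] = np.nan
        # np.maximum.at ignores NaN order issues only partially; enforce NaN
        # propagation the way mean does: a slot with any NaN value is NaN.
        nan_mask = mask & np.isnan(values)
        if nan_mask.any():
            out[np.unique(self._key[nan_mask])] = np.nan
        return out

    @staticmethod
    def _diff_static(slot_values):
        return slot_values[0::2] - slot_values[1::2]

    def _diff(self, slot_values):
        return self._diff_static(slot_values)

    def predictors(self, weight_g: np.ndarray | None = None) -> pd.DataFrame:
        """Relative-predictor matrix (contests × 15).

        ``weight_g`` overrides the member table's weight column (same row
        order); NaN weights propagate into NaN weight predictors.
        """
        if weight_g is None:
            weight_g = self.member_table["weight_g"].to_numpy(float)
        else:
            weight_g = np.asarray(weight_g, float)
        cols = dict(self._fixed)
        for cls, mask in self._masks.items():
            cols[f"rel_mean_weight_{cls}"] = self._diff(self._mean(weight_g, mask))
            cols[f"rel_max_weight_{cls}"] = self._diff(self._max(weight_g, mask))
        df = pd.DataFrame(cols, index=self.contest_ids)[list(PREDICTOR_NAMES)]
        df.index.name = "contest_id"
        return df


def relative_predictors(focal: pd.DataFrame, rival: pd.DataFrame) -> pd.Series:
    """The 15 focal-minus-rival predictors for one contest.

    Both rosters must be weight-complete; missing weights raise
    ``SchemaError`` directing the caller to imputation.
    """
    for r in (focal, rival):
        if r["weight_g"].isna().any():
            raise SchemaError(
                "roster has missing weights; impute before computing predictors"
            )
    rows = pd.concat(
        [focal.assign(side="focal"), rival.assign(side="rival")], ignore_index=True
    )
    rows["contest_id"] = "_single"
    builder = PredictorBuilder(rows)
    return builder.predictors().iloc[0].rename(None)


def predictor_matrix(member_table: pd.DataFrame) -> pd.DataFrame:
    """Relative predictors for every contest in a member table (NaN-propagating)."""
    return PredictorBuilder(member_table).predictors()


def assign_focal(contests: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Randomise focal/rival labels: each contest kept or swapped with p = 1/2.

    On swap the outcome flips, so the contest's information is unchanged.
    """
    rng = np.random.default_rng(seed)
    out = contests.copy().reset_index(drop=True)
    swap = rng.random(len(out)) < 0.5
    f = out.loc[swap, "focal_group_id"].copy()
    out.loc[swap, "focal_group_id"] = out.loc[swap, "rival_group_id"]
    out.loc[swap, "rival_group_id"] = f
    out.loc[swap, "focal_win"] = 1 - out.loc[swap, "focal_win"]
    return out
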