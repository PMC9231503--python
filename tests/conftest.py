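import pandas as pd
import pytest
from hypothesis import settings

import grouprhp as g
from grouprhp.glmm import scale_predictors
from grouprhp.tables import PREDICTOR_NAMES

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_world():
    """A mid-sized synthetic study: population, contests, clustered missingness.

    Shared (read-only) across tests; anything that mutates tables must copy.
    """
    pc = g.PopulationConfig(seed=0)
    tables = g.generate_population(pc)
    contests, truth = g.generate_contests(
        tables, g.ContestGenConfig(n_contests=200, seed=100), pc
    )
    tables.contests = contests
    complete_weights = tables.weights
    masked = g.apply_missingness_clustered(
        complete_weights, tables.memberships, 0.221, seed=200
    )
    return dict(config=pc, tables=tables, contests=contests, truth=truth,
                complete_weights=complete_weights, masked_weights=masked)


@pytest.fixture(scope="session")
def contest_fit_data(study_world):
    """Scaled complete-data contest frame ready for model fitting."""
    tables = study_world["tables"]
    mt = g.build_member_table(tables)
    X = g.predictor_matrix(mt)
    data = study_world["contests"].copy()
    for c in PREDICTOR_NAMES:
        data[c] = X.loc[data["contest_id"], c].to_numpy()
    data, record = scale_predictors(data, list(PREDICTOR_NAMES))
    return data


@pytest.fixture()
def tiny_tables():
    """Hand-built four-individual world for boundary tests."""
    individuals = pd.DataFrame(
        dict(
            individual_id=["A", "B", "C", "D"],
            sex=["M", "M", "F", "M"],
            birth_date=pd.to_datetime(
                ["2014-01-01", "2015-01-01", "2014-06-01", "2015-01-01"]
            ),
            immigrant=[False, False, False, False],
            immigration_date=[pd.NaT] * 4,
        )
    )
    memberships = pd.DataFrame(
        dict(
            individual_id=["A", "B", "C", "D"],
            group_id=["G1", "G1", "G1", "G2"],
            start_date=individuals["birth_date"],
            end_date=[pd.NaT] * 4,
        )
    )
    weights = pd.DataFrame(
        dict(
            individual_id=["A", "B", "C", "D"],
            obs_date=pd.to_datetime(
                ["2017-01-01", "2017-01-01", "2017-01-01", "2017-01-01"]
            ),
            weight_g=[1500.0, 1300.0, 1200.0, 1400.0],
            pregnant=[False, False, False, False],
        )
    )
    contests = pd.DataFrame(
        dict(
            contest_id=["C1"],
            date=pd.to_datetime(["2017-03-01"]),
            focal_group_id=["G1"],
            rival_group_id=["G2"],
            focal_win=[1],
        )
    )
    guard_events = pd.DataFrame(
        dict(male_id=["A"], date=pd.to_datetime(["2017-01-15"]))
    )
    return g.StudyTables(
        individuals=individuals, memberships=memberships, weights=weights,
        contests=contests, guard_events=guard_events,
    )
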