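import pandas as pd
import pytest

from paneltrans.cohort import (
    COVARIATE_COLUMNS,
    apply_inclusion,
    build_counting_process,
    collapse_to_subject,
    impute_cohort,
    score_cohort,
)
from paneltrans.simulate import SimulationConfig, generate_cohort
from paneltrans.survival import add_exposure_columns


@pytest.fixture(scope="session")
def sim_data():
    """A small synthetic cohort with ground truth (400 participants)."""
    cfg = SimulationConfig(n_participants=400, seed=42)
    cohort, aces, truth = generate_cohort(cfg)
    return cohort, aces, truth


@pytest.fixture(scope="session")
def scored(sim_data):
    cohort, aces, _ = sim_data
    cohort, _ = apply_inclusion(cohort, aces)
    return score_cohort(impute_cohort(cohort))


@pytest.fixture(scope="session")
def intervals(scored, sim_data):
    _, aces, _ = sim_data
    return add_exposure_columns(build_counting_process(scored, aces, horizon=22.0))


@pytest.fixture(scope="session")
def subjects(intervals):
    return add_exposure_columns(collapse_to_subject(intervals))


def make_panel(rows):
    """Build a minimal cohort frame for counting-process tests.

    ``rows``: list of dicts with id, wave, time_years, observed, died, psy_dx
    (covariates filled with innocuous defaults).
    """
    defaults = {c: 0.0 for c in COVARIATE_COLUMNS}
    defaults.update({"sex": "female", "race": "white", "marital": "married", "age": 60.0})
    out = []
    for r in rows:
        rec = dict(defaults)
        rec.update(r)
        out.append(rec)
    df = pd.DataFrame(out)
    return df.drop(columns=["sex_male", "race_black", "race_other", "married"],
                   errors="ignore")
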