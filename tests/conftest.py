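"""Shared fixtures: synthetic truths, simulated tables and a full-scale fit.

Everything is generated programmatically from seeds; the expensive full-scale
fit is session-scoped so the model, bootstrap and projection tests share it.
"""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

import chdprev as c
from chdprev.model import (CHDModel, ModelConfig, observations_from_deaths,
                           observations_from_survey)

settings.register_profile("suite", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_truth() -> c.TruthScenario:
    """The study-condition scenario (seed 1)."""
    return c.make_truth(c.ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def tables(default_truth):
    """survey.csv / deaths.csv / population.csv frames for the default truth."""
    return {
        "survey": c.simulate_survey(default_truth),
        "deaths": c.simulate_deaths(default_truth),
        "population": c.population_table(default_truth),
    }


@pytest.fixture(scope="session")
def fitted(default_truth, tables):
    """Full-scale MAP fit of the default synthetic dataset (both sexes)."""
    model = CHDModel.from_tables(tables["survey"], tables["deaths"],
                                 tables["population"])
    return model.fit()


def reduced_problem(seed: int, sex: str = "male"):
    """Small, fast single-sex model used by bootstrap-heavy tests."""
    truth = c.make_truth(c.ScenarioConfig(seed=seed, death_years=(1991, 2010),
                                          survey_years=(1997, 2011), age_max=70))
    obs = pd.concat([observations_from_survey(c.simulate_survey(truth)),
                     observations_from_deaths(c.simulate_deaths(truth))],
                    ignore_index=True)
    config = ModelConfig(age_knots=(0, 1, 5, 15, 30, 50, 70), year_knot_spacing=10)
    model = CHDModel(obs[obs["sex"] == sex], c.population_table(truth),
                     config=config)
    return truth, model


@pytest.fixture(scope="session")
def reduced_fit():
    truth, model = reduced_problem(seed=1)
    return truth, model, model.fit()
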