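"""MAP fitting: gradients, predictions, recovery and bookkeeping."""

import warnings

import numpy as np
import pandas as pd
import pytest

import chdprev as c
from chdprev.grids import AgeTimeGrid, PrevalenceSurface, RateSurface
from chdprev.model import (CHDModel, ModelConfig, observations_from_deaths,
                           observations_from_survey, predict_observation)

from conftest import reduced_problem


def test_predict_observation_interval_aggregation():
    grid = AgeTimeGrid.from_ranges(70, 2000, 2002)
    p_vals = np.full(grid.shape, 0.003)
    p_vals[11, :] = 0.002
    p_vals[12, :] = 0.004
    p = PrevalenceSurface(grid, p_vals)
    chi = RateSurface(grid, np.full(grid.shape, 0.0177))
    single = {"measure": "prevalence", "age_lo": 5, "age_hi": 5,
              "sex": "male", "year": 2001}
    assert predict_observation(single, p, chi) == pytest.approx(0.003)
    pair = {"measure": "prevalence", "age_lo": 11, "age_hi": 12,
            "sex": "male", "year": 2001}
    pop = pd.DataFrame({"age": [11, 12], "sex": ["male"] * 2,
                        "year": [2001] * 2, "population": [5000, 5000]})
    assert predict_observation(pair, p, chi, pop) == pytest.approx(0.003)
    csmr = {"measure": "csmr", "age_lo": 5, "age_hi": 5,
            "sex": "male", "year": 2001}
    # product oracle p * chi: uniform p = 0.003 with chi = 0.17667 gives the
    # 53 deaths per 100,000 person-years scale
    chi53 = RateSurface(grid, np.full(grid.shape, 53e-5 / 0.003))
    assert predict_observation(csmr, p, chi53) == pytest.approx(53e-5, rel=1e-6)
    assert predict_observation(csmr, p, chi) == pytest.approx(0.003 * 0.0177)


def test_predict_observation_outside_grid_errors():
    grid = AgeTimeGrid.from_ranges(70, 2000, 2002)
    p = PrevalenceSurface(grid, np.full(grid.shape, 0.003))
    chi = RateSurface(grid, np.full(grid.shape, 0.01))
    with pytest.raises(KeyError):
        predict_observation({"measure": "prevalence", "age_lo": 60,
                             "age_hi": 75, "sex": "male", "year": 2001}, p, chi)


def test_objective_gradient_matches_finite_differences():
    _, model = reduced_problem(seed=3)
    prob = model._problems["male"]
    theta = prob.start()
    rng = np.random.default_rng(0)
    theta = theta + rng.normal(scale=0.05, size=theta.size)
    f0, grad = prob.objective(theta)
    for i in rng.choice(theta.size, size=8, replace=False):
        eps = 1e-6
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        fd = (prob.objective(tp)[0] - prob.objective(tm)[0]) / (2 * eps)
        assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)


def test_age_zero_prevalence_rows_dropped_by_default(tables):
    model = CHDModel.from_tables(tables["survey"], tables["deaths"],
                                 tables["population"])
    obs = model._problems["male"].obs
    assert not ((obs["measure"] == "prevalence") & (obs["age_lo"] == 0)).any()
    keep = CHDModel.from_tables(
        tables["survey"], tables["deaths"], tables["population"],
        config=ModelConfig(exclude_age_zero_prevalence=False))
    obs2 = keep._problems["male"].obs
    assert ((obs2["measure"] == "prevalence") & (obs2["age_lo"] == 0)).any()


def test_sex_with_single_data_stream_is_rejected(tables):
    survey_only = observations_from_survey(tables["survey"])
    with pytest.raises(ValueError, match="csmr"):
        CHDModel(survey_only, tables["population"])


def test_noise_free_recovery_within_one_percent():
    """Data generated from surfaces inside the model family, no sampling
    noise (huge effective n): birth prevalence returns to within 1%."""
    truth, model = reduced_problem(seed=5)
    prob = model._problems["male"]
    ka, kt = prob.age_knots, prob.year_knots
    kappa = np.log(truth.chi["male"].values[
        np.ix_(ka, kt - truth.grid.years[0])]).ravel()
    theta_star = np.concatenate([[np.log(3.29e-3)], kappa])
    obs = prob.obs.copy()
    obs["value"] = prob.predicted_values(theta_star)
    obs["effective_n"] = 1e9
    refit = CHDModel(obs, model.population, grid=model.grid,
                     config=model.config).fit()
    bp = refit.birth_prevalence("male", 2010)
    assert bp == pytest.approx(3.29e-3, rel=0.01)


def test_noisy_recovery_and_surface_invariants(fitted, default_truth):
    """Default scenario, full sample sizes: birth prevalence within 10% of
    truth, fitted surfaces positive, prevalence monotone along cohorts."""
    for sex, bp_true in [("male", 3.29e-3), ("female", 3.23e-3)]:
        bp = fitted.birth_prevalence(sex, 2010)
        assert abs(bp - bp_true) / bp_true < 0.10
        p = fitted.prevalence(sex).values
        chi = fitted.chi(sex).values
        assert np.all(chi > 0) and np.all((p >= 0) & (p <= 1))
        # non-increasing along every cohort diagonal
        n_a, n_t = p.shape
        ratios = p[1:, 1:] / np.where(p[:-1, :-1] > 0, p[:-1, :-1], 1.0)
        assert np.all(ratios <= 1 + 1e-12)
    # adult-age hazard recovered within reason (median over ages 20-64)
    ages = slice(20, 65)
    j = fitted.grid.year_index(2010)
    rel = np.abs(fitted.chi("male").values[ages, j]
                 - default_truth.chi["male"].values[ages, j]) \
        / default_truth.chi["male"].values[ages, j]
    assert np.median(rel) <= 0.25


def test_objective_decomposition_bookkeeping(fitted):
    for sex in fitted.sexes:
        d = fitted.objective_decomposition(sex)
        assert d["objective"] == pytest.approx(d["loglik"] - d["penalty"],
                                               abs=1e-8)


def test_non_convergence_is_flagged_not_silent(tables):
    model = CHDModel.from_tables(tables["survey"], tables["deaths"],
                                 tables["population"],
                                 config=ModelConfig(maxiter=2))
    with pytest.warns(RuntimeWarning, match="did not converge"):
        res = model.fit()
    assert not all(res.converged.values())


def test_fitted_observations_reports_residuals(fitted):
    df = fitted.fitted_observations("male")
    assert {"predicted", "log_residual"} <= set(df.columns)
    assert np.isfinite(df["log_residual"]).all()
    # residuals are centred: no gross systematic misfit
    assert abs(df["log_residual"].mean()) < 0.5


def test_summary_mentions_birth_prevalence(fitted):
    text = fitted.summary()
    assert "birth prevalence" in text
    assert "per 1,000" in text
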