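"""Synthetic death-certificate, survey-prevalence and population tables.

Emulates the three data streams the estimation pipeline consumes — national
vital-statistics death counts, a household-survey "recalled CHD" question
asked about children, and midyear population counts — from a known truth, so
every downstream stage is testable without any restricted-access download.

The default scenario mimics the magnitudes of US recalled congenital heart
disease: a birth prevalence near 3.3 per 1,000 (males) and 3.2 per 1,000
(females), an excess-mortality hazard concentrated in infancy and declining
roughly threefold over the four decades of the death-data window, Poisson
death counts against a ~2 million person denominator per single-year
age/sex cell, and binomial survey responses for children under 18.

Truth hazard parameterization: log-linear in calendar year with an age
profile peaked at age 0 and near-flat in adulthood,

    chi(a, t) = (infant_hazard * exp(-a / hazard_age_scale) + adult_hazard)
                * exp(-decline_rate * (t - t_min)).

Reproducibility contract: each output table draws from its own random stream
keyed (seed, table-name), so adding a table never perturbs the others, and
identical seed + config yields identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import AgeTimeGrid, PrevalenceSurface, RateSurface
from .solver import solve_surface

__all__ = ["ScenarioConfig", "TruthScenario", "make_truth",
           "simulate_deaths", "simulate_survey", "population_table"]

SEXES = ("male", "female")

# fixed per-table sub-keys for the (seed, table) random streams
_TABLE_KEYS = {"deaths": 11, "survey": 12, "population": 13}


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the synthetic truth.

    Defaults are the study conditions: death data 1968-2010, survey data
    1997-2011 for ages under 18, birth prevalence 3.29 / 3.23 per 1,000
    (male / female), an infant excess hazard of 0.5 per person-year at the
    start of the window declining threefold by its end, and a near-flat
    adult hazard of 0.01 per person-year.
    """

    birth_prevalence: dict = field(
        default_factory=lambda: {"male": 3.29e-3, "female": 3.23e-3})
    infant_hazard: float = 0.5
    adult_hazard: float = 0.01
    hazard_age_scale: float = 2.0
    decline_rate: float = math.log(3.0) / 42.0
    death_years: tuple = (1968, 2010)
    survey_years: tuple = (1997, 2011)
    survey_max_age: int = 17
    age_max: int = 100
    population_per_cell: int = 2_000_000
    survey_respondents_per_cell: int = 700
    seed: int = 0


@dataclass
class TruthScenario:
    """A fully specified truth: surfaces, population and sampling plan."""

    grid: AgeTimeGrid
    birth_prevalence: dict          # sex -> array over grid years
    chi: dict                       # sex -> RateSurface
    prevalence: dict                # sex -> PrevalenceSurface (solved from truth)
    population: pd.DataFrame        # age, sex, year, population
    survey_sample_sizes: pd.DataFrame  # age, sex, year, respondents
    death_years: tuple
    survey_years: tuple
    seed: int

    def __post_init__(self) -> None:
        for sex in SEXES:
            bp = np.asarray(self.birth_prevalence[sex], dtype=float)
            if np.any(bp <= 0) or np.any(bp >= 0.05):
                raise ValueError("birth prevalence must lie in (0, 0.05)")
            chi = self.chi[sex].values
            if np.any(chi < 0) or not np.all(np.isfinite(chi)):
                raise ValueError("truth hazard must be non-negative and finite")
        pop = self.population["population"].to_numpy()
        if np.any(pop <= 0) or np.any(pop != np.floor(pop)):
            raise ValueError("population counts must be positive integers")


def make_truth(config: ScenarioConfig | None = None, **overrides) -> TruthScenario:
    """Build the truth scenario for a configuration (default: study conditions)."""
    config = replace(config or ScenarioConfig(), **overrides)
    for name in ("infant_hazard", "adult_hazard", "hazard_age_scale"):
        if getattr(config, name) <= 0:
            raise ValueError(f"{name} must be positive")
    if config.decline_rate < 0:
        raise ValueError("decline_rate must be non-negative")
    for sex in SEXES:
        bp = config.birth_prevalence[sex]
        if not (0.0 < bp < 0.05):
            raise ValueError("birth prevalence must lie in (0, 0.05)")
    if config.age_max < 65:
        raise ValueError("age_max must cover the adult band (>= 65)")

    year_min = min(config.death_years[0], config.survey_years[0])
    year_max = max(config.death_years[1], config.survey_years[1])
    grid = AgeTimeGrid.from_ranges(config.age_max, year_min, year_max)

    ages = grid.ages[:, None].astype(float)
    years = grid.years[None, :].astype(float)
    profile = config.infant_hazard * np.exp(-ages / config.hazard_age_scale) + config.adult_hazard
    chi_values = profile * np.exp(-config.decline_rate * (years - year_min))

    birth_prevalence, chi, prevalence = {}, {}, {}
    for sex in SEXES:
        birth_prevalence[sex] = np.full(grid.n_years, config.birth_prevalence[sex])
        chi[sex] = RateSurface(grid, chi_values.copy())
        prevalence[sex] = solve_surface(birth_prevalence[sex], chi[sex])

    a, s, t = np.meshgrid(grid.ages, np.arange(2), grid.years, indexing="ij")
    population = pd.DataFrame({
        "age": a.ravel(), "sex": np.asarray(SEXES)[s.ravel()], "year": t.ravel(),
        "population": config.population_per_cell,
    }).sort_values(["sex", "year", "age"], ignore_index=True)

    sy = np.arange(config.survey_years[0], config.survey_years[1] + 1)
    sa = np.arange(0, config.survey_max_age + 1)
    a, s, t = np.meshgrid(sa, np.arange(2), sy, indexing="ij")
    survey_sizes = pd.DataFrame({
        "age": a.ravel(), "sex": np.asarray(SEXES)[s.ravel()], "year": t.ravel(),
        "respondents": config.survey_respondents_per_cell,
    }).sort_values(["sex", "year", "age"], ignore_index=True)

    return TruthScenario(
        grid=grid, birth_prevalence=birth_prevalence, chi=chi, prevalence=prevalence,
        population=population, survey_sample_sizes=survey_sizes,
        death_years=tuple(config.death_years), survey_years=tuple(config.survey_years),
        seed=config.seed,
    )


def _cell_lookup(truth: TruthScenario, df: pd.DataFrame, surface_name: str) -> np.ndarray:
    """Surface values at each (age, sex, year) row of df."""
    out = np.empty(len(df))
    ai = truth.grid.age_index(df["age"].to_numpy())
    ti = truth.grid.year_index(df["year"].to_numpy())
    for sex in SEXES:
        mask = (df["sex"] == sex).to_numpy()
        out[mask] = getattr(truth, surface_name)[sex].values[ai[mask], ti[mask]]
    return out


def simulate_deaths(truth: TruthScenario) -> pd.DataFrame:
    """Poisson death counts with mean N(a,s,t) * p(a,t) * chi(a,t).

    Output schema matches the tabulator's rate input: columns age, sex, year,
    deaths, population, restricted to the death-data year window.
    """
    rng = np.random.default_rng([truth.seed, _TABLE_KEYS["deaths"]])
    y0, y1 = truth.death_years
    in_window = truth.population["year"].between(y0, y1)
    df = truth.population[in_window].reset_index(drop=True).copy()
    p = _cell_lookup(truth, df, "prevalence")
    chi = _cell_lookup(truth, df, "chi")
    mean = df["population"].to_numpy() * p * chi
    df["deaths"] = rng.poisson(mean)
    return df[["age", "sex", "year", "deaths", "population"]]


def simulate_survey(truth: TruthScenario) -> pd.DataFrame:
    """Binomial survey positives per cell: positives ~ Bin(respondents, p(a,t)).

    Includes age-0 rows so the downstream exclusion rule is exercised.
    Columns: age, sex, year, respondents, positives.
    """
    rng = np.random.default_rng([truth.seed, _TABLE_KEYS["survey"]])
    df = truth.survey_sample_sizes.copy()
    if df["respondents"].le(0).any():
        raise ValueError("survey sample sizes must be positive")
    p = _cell_lookup(truth, df, "prevalence")
    df["positives"] = rng.binomial(df["respondents"].to_numpy(), p)
    return df[["age", "sex", "year", "respondents", "positives"]]


def population_table(truth: TruthScenario) -> pd.DataFrame:
    """Population counts by age, sex, year (columns age, sex, year, population)."""
    return truth.population.copy()
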