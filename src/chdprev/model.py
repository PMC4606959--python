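"""Penalized MAP estimation of birth prevalence and excess mortality.

:class:`CHDModel` is the statsmodels-style entry point: build it from an
observation table (survey prevalence and cause-specific mortality rates) plus
a population table, call :meth:`CHDModel.fit`, and get a
:class:`~chdprev.results.CHDResults` carrying the fitted surfaces,
convergence diagnostics and bootstrap/projection methods.

The estimator maximizes, separately for each sex,

    sum_i log N(log(y_i + d); log(mu_i + d), s_i^2)
      - penalty(log chi; age, cohort, cross)
      - penalty(log p; cohort)

over a log-scale parameterization: one (or a few) birth-prevalence
parameters and the excess hazard chi at knots every few years of age and
calendar time, bilinearly interpolated to the full grid.  Predictions mu_i
come from solving the cohort model: population-weighted means of p over the
observation's age interval for prevalence, and of p * chi for mortality
rates.  Gradients are exact (an adjoint sweep over the cohort recursion), so
fits take well under a second and the bootstrap stays cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp

from .grids import AgeTimeGrid, PrevalenceSurface, RateSurface
from .penalties import second_difference_penalty, second_difference_penalty_grad
from .solver import solve_log_prevalence

__all__ = ["ModelConfig", "CHDModel", "observations_from_survey",
           "observations_from_deaths", "validate_observations",
           "predict_observation", "OBS_COLUMNS"]

OBS_COLUMNS = ["measure", "age_lo", "age_hi", "sex", "year", "value", "effective_n"]
MEASURES = ("prevalence", "csmr")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelConfig:
    """Tunable settings of the MAP fit.

    smoothing_sigma
        Scale of the second-order difference penalties on the log surfaces.
    dispersion
        Global log-scale dispersion tau of the data model, on top of the
        delta-method sampling variance.
    offset_delta
        Mapping measure -> fixed offset.  None (default) uses the half-count
        rule delta_i = 0.5 / effective_n_i per observation, under which
        log(value + delta) is nearly unbiased for the log mean even in cells
        with only a handful of expected events.
    age_knots / year_knot_spacing
        Hazard knots: denser in childhood (0, 1, 5) then every 5 years of
        age, and every 5 calendar years, bilinear in between.
    exclude_age_zero_prevalence
        Drop age-0 prevalence observations before fitting (survey responses
        about infants suffer age-differential nonresponse).
    constrain_constant_birth_prevalence
        Fit a single birth prevalence per sex instead of one per year knot.
    """

    smoothing_sigma: float = 1.0
    dispersion: float = 0.1
    offset_delta: dict | None = None
    age_knots: tuple | None = None
    year_knot_spacing: int = 5
    exclude_age_zero_prevalence: bool = True
    constrain_constant_birth_prevalence: bool = True
    chi_bounds: tuple = (1e-8, 4.0)
    birth_prevalence_bounds: tuple = (1e-7, 0.05)
    gtol: float = 1e-6
    ftol: float = 1e-10
    maxiter: int = 1000
    n_reweight: int = 3

    def __post_init__(self) -> None:
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing_sigma must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.offset_delta is not None and any(v <= 0 for v in self.offset_delta.values()):
            raise ValueError("offset_delta values must be positive")


def validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    obs = obs.copy()
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns {missing}")
    bad = ~obs["measure"].isin(MEASURES)
    if bad.any():
        raise ValueError(f"unknown measures {sorted(obs.loc[bad, 'measure'].unique())}")
    if (obs["age_lo"] > obs["age_hi"]).any():
        raise ValueError("age_lo must be <= age_hi")
    if (obs["value"] < 0).any():
        raise ValueError("observation values must be non-negative")
    if (obs["effective_n"] <= 0).any():
        raise ValueError("effective_n must be positive")
    return obs


def observations_from_survey(survey: pd.DataFrame) -> pd.DataFrame:
    """Prevalence observations from a survey table (age, sex, year,
    respondents, positives)."""
    return pd.DataFrame({
        "measure": "prevalence",
        "age_lo": survey["age"].astype(int),
        "age_hi": survey["age"].astype(int),
        "sex": survey["sex"],
        "year": survey["year"].astype(int),
        "value": survey["positives"] / survey["respondents"],
        "effective_n": survey["respondents"].astype(float),
    })


def observations_from_deaths(deaths: pd.DataFrame) -> pd.DataFrame:
    """CSMR observations from a death-count table (age, sex, year, deaths,
    population): rate = deaths / midyear population."""
    if (deaths["population"] <= 0).any():
        row = deaths[deaths["population"] <= 0].iloc[0]
        raise ValueError(f"non-positive population for cell age={row['age']} "
                         f"sex={row['sex']} year={row['year']}")
    return pd.DataFrame({
        "measure": "csmr",
        "age_lo": deaths["age"].astype(int),
        "age_hi": deaths["age"].astype(int),
        "sex": deaths["sex"],
        "year": deaths["year"].astype(int),
        "value": deaths["deaths"] / deaths["population"],
        "effective_n": deaths["population"].astype(float),
    })


def _interp_matrix(points: np.ndarray, knots: np.ndarray) -> sp.csr_matrix:
    """Sparse 1-d linear interpolation weights from knot values to points."""
    points = np.asarray(points, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.size == 1:
        return sp.csr_matrix(np.ones((points.size, 1)))
    idx = np.clip(np.searchsorted(knots, points, side="right") - 1, 0, knots.size - 2)
    w = (points - knots[idx]) / (knots[idx + 1] - knots[idx])
    w = np.clip(w, 0.0, 1.0)
    rows = np.repeat(np.arange(points.size), 2)
    cols = np.stack([idx, idx + 1], axis=1).ravel()
    vals = np.stack([1.0 - w, w], axis=1).ravel()
    return sp.csr_matrix((vals, (rows, cols)), shape=(points.size, knots.size))


def _default_age_knots(age_max: int) -> np.ndarray:
    knots = [0, 1] + list(range(5, age_max + 1, 5))
    if knots[-1] != age_max:
        knots.append(age_max)
    return np.asarray(knots)


def _default_year_knots(years: np.ndarray, spacing: int) -> np.ndarray:
    knots = list(range(int(years[0]), int(years[-1]) + 1, spacing))
    if knots[-1] != years[-1]:
        knots.append(int(years[-1]))
    return np.asarray(knots)


def predict_observation(obs, prevalence: PrevalenceSurface, chi: RateSurface,
                        population: pd.DataFrame | None = None):
    """Model prediction for one observation (a Series/dict with measure,
    age_lo, age_hi, sex, year).

    Prevalence: population-weighted mean of p over the age interval at the
    observation's year; CSMR: population-weighted mean of p * chi.  With no
    population table, ages are weighted equally.
    """
    grid = prevalence.grid
    ages = np.arange(int(obs["age_lo"]), int(obs["age_hi"]) + 1)
    ai = grid.age_index(ages)
    ti = int(grid.year_index(int(obs["year"])))
    if population is not None and len(ages) > 1:
        pop = population[(population["sex"] == obs["sex"])
                         & (population["year"] == int(obs["year"]))]
        pop = pop.set_index("age")["population"].reindex(ages)
        if pop.isna().any():
            raise ValueError(f"population missing for ages {list(pop[pop.isna()].index)}")
        w = pop.to_numpy(dtype=float)
    else:
        w = np.ones(len(ages))
    w = w / w.sum()
    field_vals = prevalence.values[ai, ti]
    if obs["measure"] == "csmr":
        field_vals = field_vals * chi.values[ai, ti]
    elif obs["measure"] != "prevalence":
        raise ValueError(f"unknown measure {obs['measure']!r}")
    return float(w @ field_vals)


class _SexProblem:
    """Fitting problem for one sex: data, design matrices, objective."""

    def __init__(self, sex: str, obs: pd.DataFrame, pop_grid: np.ndarray,
                 grid: AgeTimeGrid, config: ModelConfig,
                 delta_by_measure: dict | None):
        self.sex = sex
        self.grid = grid
        self.config = config
        self.delta_by_measure = None if delta_by_measure is None else dict(delta_by_measure)
        if config.exclude_age_zero_prevalence:
            drop = (obs["measure"] == "prevalence") & (obs["age_hi"] == 0)
            obs = obs[~drop]
        for measure in MEASURES:
            if not (obs["measure"] == measure).any():
                raise ValueError(f"no {measure} observations for sex {sex!r}")
        self.obs = obs.reset_index(drop=True)
        n_a, n_t = grid.shape

        # knots and interpolation designs
        age_knots = (np.asarray(config.age_knots) if config.age_knots is not None
                     else _default_age_knots(int(grid.ages[-1])))
        year_knots = _default_year_knots(grid.years, config.year_knot_spacing)
        self.age_knots, self.year_knots = age_knots, year_knots
        Ba = _interp_matrix(grid.ages, age_knots)
        Bt = _interp_matrix(grid.years, year_knots)
        self.B_chi = sp.kron(Ba, Bt, format="csr")
        if config.constrain_constant_birth_prevalence:
            self.B_beta = sp.csr_matrix(np.ones((n_t, 1)))
        else:
            self.B_beta = Bt.tocsr()
        self.n_beta = self.B_beta.shape[1]
        self.n_chi = self.B_chi.shape[1]

        # per-observation aggregation weights over [age_lo, age_hi] at year
        rows, cols, vals = [], [], []
        is_prev = (self.obs["measure"] == "prevalence").to_numpy()
        for i, row in enumerate(self.obs.itertuples(index=False)):
            ages = np.arange(int(row.age_lo), int(row.age_hi) + 1)
            ai = grid.age_index(ages)
            ti = int(grid.year_index(int(row.year)))
            w = pop_grid[ai, ti]
            if len(ages) == 1:
                w = np.ones(1)
            elif np.any(~np.isfinite(w)) or w.sum() <= 0:
                raise ValueError(
                    f"population missing in interval [{row.age_lo}, {row.age_hi}] "
                    f"year {row.year} sex {sex!r}")
            w = w / w.sum()
            rows.extend([i] * len(ages))
            cols.extend(ai * n_t + ti)
            vals.extend(w)
        W = sp.csr_matrix((vals, (rows, cols)), shape=(len(self.obs), n_a * n_t))
        self.W_prev = W[is_prev]
        self.W_csmr = W[~is_prev]
        self.is_prev = is_prev
        self.n_prev = np.asarray(self.obs.loc[is_prev, "effective_n"], dtype=float)
        self.n_csmr = np.asarray(self.obs.loc[~is_prev, "effective_n"], dtype=float)
        if self.delta_by_measure is None:  # half-count offsets, per observation
            self.delta_prev = 0.5 / self.n_prev
            self.delta_csmr = 0.5 / self.n_csmr
        else:
            self.delta_prev = np.full(self.n_prev.size,
                                      self.delta_by_measure["prevalence"])
            self.delta_csmr = np.full(self.n_csmr.size,
                                      self.delta_by_measure["csmr"])
        self._set_values(self.obs["value"].to_numpy(dtype=float))

    def _set_values(self, values: np.ndarray) -> None:
        self.y_prev = values[self.is_prev]
        self.y_csmr = values[~self.is_prev]
        self._update_scales(self.start())

    def _update_scales(self, theta: np.ndarray) -> None:
        """Fix the residual scales s_i at the current iterate's predictions.

        Freezing s within each optimizer pass avoids two biases: weights
        computed from observed values upweight upward-fluctuated cells, and
        an s(mu) inside the objective rewards inflating predictions through
        the -log s term.  The outer fit loop re-freezes and refits.
        """
        tau = self.config.dispersion
        mu_prev, mu_csmr = self.predictions(theta)
        self.s2_prev = 1.0 / (self.n_prev * (mu_prev + self.delta_prev)) + tau * tau
        self.s2_csmr = 1.0 / (self.n_csmr * (mu_csmr + self.delta_csmr)) + tau * tau

    def with_values(self, values: np.ndarray) -> "_SexProblem":
        """Shallow copy with replaced observation values (bootstrap refits)."""
        import copy
        new = copy.copy(self)
        new._set_values(np.asarray(values, dtype=float))
        return new

    # --- parameter handling -------------------------------------------------
    def split(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return theta[: self.n_beta], theta[self.n_beta:]

    @property
    def delta_all(self) -> np.ndarray:
        """Per-row offsets aligned with self.obs."""
        out = np.empty(len(self.obs))
        out[self.is_prev] = self.delta_prev
        out[~self.is_prev] = self.delta_csmr
        return out

    def start(self) -> np.ndarray:
        """Deterministic start from empirical crude rates.

        The hazard age profile is initialized by a short fixed-point
        iteration: chi(a) = crude_csmr(a) / p(a) with p re-solved from the
        cohort model each pass.  Without an age-aware start the optimizer can
        fall into a basin where the infant hazard collapses to zero.
        """
        ages = self.grid.ages.astype(float)
        crude_prev = max(float(np.average(self.y_prev, weights=self.n_prev)),
                         float(np.mean(self.delta_prev)))
        # pooled crude mortality rate per age (half-count regularized)
        obs_c = self.obs[~self.is_prev].copy()
        obs_c["_deaths"] = obs_c["value"] * obs_c["effective_n"]
        grp = obs_c.groupby("age_lo")[["_deaths", "effective_n"]].sum()
        rate = ((grp["_deaths"] + 0.5) / grp["effective_n"]).reindex(self.grid.ages)
        rate = rate.interpolate(limit_direction="both").to_numpy(dtype=float)

        prev_ages = np.unique(self.obs.loc[self.is_prev, "age_lo"].to_numpy())
        lo, hi = self.config.chi_bounds
        blo, bhi = self.config.birth_prevalence_bounds
        p = np.full(ages.size, crude_prev)
        beta0 = crude_prev
        for _ in range(5):
            chi = np.clip(rate / np.maximum(p, 1e-12), lo * 10, hi / 10)
            cum = np.concatenate([[0.0], np.cumsum(0.5 * (chi[:-1] + chi[1:]))])
            surv = np.exp(-cum)
            # pick the birth prevalence that reproduces the crude child level
            beta0 = float(np.clip(
                crude_prev / max(surv[self.grid.age_index(prev_ages)].mean(), 1e-6),
                blo * 10, bhi / 2))
            p = beta0 * surv
        kappa0 = np.log(chi[self.grid.age_index(self.age_knots)])
        kappa0 = np.repeat(kappa0, self.year_knots.size)
        return np.concatenate([np.full(self.n_beta, np.log(beta0)), kappa0])

    def bounds(self) -> list:
        blo, bhi = self.config.birth_prevalence_bounds
        clo, chi_hi = self.config.chi_bounds
        return ([(np.log(blo), np.log(bhi))] * self.n_beta
                + [(np.log(clo), np.log(chi_hi))] * self.n_chi)

    # --- forward model ------------------------------------------------------
    def surfaces_arrays(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta_k, kappa = self.split(theta)
        beta_row = self.B_beta @ beta_k
        logX = np.asarray(self.B_chi @ kappa).reshape(self.grid.shape)
        X = np.exp(logX)
        logp = solve_log_prevalence(beta_row, X)
        return logp, X

    def surfaces(self, theta: np.ndarray) -> tuple[PrevalenceSurface, RateSurface]:
        logp, X = self.surfaces_arrays(theta)
        return (PrevalenceSurface(self.grid, np.exp(logp)),
                RateSurface(self.grid, X))

    def predictions(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        logp, X = self.surfaces_arrays(theta)
        p = np.exp(logp)
        return self.W_prev @ p.ravel(), self.W_csmr @ (p * X).ravel()

    def predicted_values(self, theta: np.ndarray) -> np.ndarray:
        """Predictions aligned with self.obs rows."""
        mu_prev, mu_csmr = self.predictions(theta)
        out = np.empty(len(self.obs))
        out[self.is_prev] = mu_prev
        out[~self.is_prev] = mu_csmr
        return out

    # --- objective ----------------------------------------------------------
    @staticmethod
    def _nll_terms(y, mu, n, delta, s2):
        """Negative log-likelihood terms and d(nll)/d(mu), vectorized.

        The model mean is the bias-corrected log: E[log(k + nd)] for a count k
        with mean n*mu differs from log(n*mu + nd) by about
        -n*mu / (2 (n*mu + nd)^2); without that term, sparse cells (a couple
        of expected events) bias the fit low.
        """
        u = mu + delta
        m = np.log(u) - mu / (2.0 * n * u * u)
        r = np.log(y + delta) - m
        nll = 0.5 * _LOG_2PI + 0.5 * np.log(s2) + 0.5 * r * r / s2
        dm = 1.0 / u + (2.0 * mu - u) / (2.0 * n * u**3)
        dnll = -(r / s2) * dm
        return nll, dnll

    def objective(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        cfg = self.config
        beta_k, kappa = self.split(theta)
        beta_row = self.B_beta @ beta_k
        logX = np.asarray(self.B_chi @ kappa).reshape(self.grid.shape)
        X = np.exp(logX)
        logp = solve_log_prevalence(beta_row, X)
        p = np.exp(logp)
        pc = p * X
        mu_prev = self.W_prev @ p.ravel()
        mu_csmr = self.W_csmr @ pc.ravel()

        nll_p, dnll_p = self._nll_terms(self.y_prev, mu_prev, self.n_prev,
                                        self.delta_prev, self.s2_prev)
        nll_c, dnll_c = self._nll_terms(self.y_csmr, mu_csmr, self.n_csmr,
                                        self.delta_csmr, self.s2_csmr)
        pen_chi = second_difference_penalty(logX, cfg.smoothing_sigma,
                                            ("age", "cohort", "cross"))
        pen_p = second_difference_penalty(logp, cfg.smoothing_sigma, ("cohort",))
        f = float(nll_p.sum() + nll_c.sum() + pen_chi + pen_p)

        # adjoint pass
        gp_flat = self.W_prev.T @ dnll_p          # d f / d p (flat)
        gpc_flat = self.W_csmr.T @ dnll_c         # d f / d (p*chi) (flat)
        glogp = (gp_flat * p.ravel() + gpc_flat * pc.ravel()).reshape(self.grid.shape)
        glogX = (gpc_flat * pc.ravel()).reshape(self.grid.shape)
        glogp += second_difference_penalty_grad(logp, cfg.smoothing_sigma, ("cohort",))
        glogX += second_difference_penalty_grad(logX, cfg.smoothing_sigma,
                                                ("age", "cohort", "cross"))
        # reverse the cohort recursion: row a feeds row a-1 and the chi terms
        for a in range(self.grid.n_ages - 1, 0, -1):
            g = glogp[a, 1:]
            glogp[a - 1, :-1] += g
            h = -0.5 * g * X[a, 1:]
            glogX[a, 1:] += h
            glogX[a - 1, :-1] += -0.5 * g * X[a - 1, :-1]
            g0 = glogp[a, 0]
            glogp[a - 1, 0] += g0
            glogX[a, 0] += -0.5 * g0 * X[a, 0]
            glogX[a - 1, 0] += -0.5 * g0 * X[a - 1, 0]
        gbeta = self.B_beta.T @ glogp[0, :]
        gkappa = self.B_chi.T @ glogX.ravel()
        return f, np.concatenate([np.asarray(gbeta).ravel(), np.asarray(gkappa).ravel()])

    def decompose(self, theta: np.ndarray) -> dict:
        """Objective bookkeeping: penalized loglik = loglik - penalties."""
        cfg = self.config
        logp, X = self.surfaces_arrays(theta)
        p = np.exp(logp)
        mu_prev = self.W_prev @ p.ravel()
        mu_csmr = self.W_csmr @ (p * X).ravel()
        nll_p, _ = self._nll_terms(self.y_prev, mu_prev, self.n_prev,
                                   self.delta_prev, self.s2_prev)
        nll_c, _ = self._nll_terms(self.y_csmr, mu_csmr, self.n_csmr,
                                   self.delta_csmr, self.s2_csmr)
        loglik = -float(nll_p.sum() + nll_c.sum())
        pen = (second_difference_penalty(np.log(X), cfg.smoothing_sigma,
                                         ("age", "cohort", "cross"))
               + second_difference_penalty(logp, cfg.smoothing_sigma, ("cohort",)))
        return {"loglik": loglik, "penalty": float(pen),
                "objective": loglik - float(pen)}

    def fit(self, start: np.ndarray | None = None,
            n_reweight: int | None = None) -> dict:
        """Iteratively reweighted MAP fit: freeze scales, optimize, refreeze."""
        x0 = self.start() if start is None else np.asarray(start, dtype=float)
        if n_reweight is None:
            n_reweight = self.config.n_reweight
        res = None
        for _ in range(max(1, n_reweight)):
            self._update_scales(x0)
            res = scipy.optimize.minimize(
                self.objective, x0, jac=True, method="L-BFGS-B",
                bounds=self.bounds(),
                options={"maxiter": self.config.maxiter, "gtol": self.config.gtol,
                         "ftol": self.config.ftol, "maxcor": 25})
            if np.allclose(res.x, x0, rtol=0, atol=1e-9):
                x0 = res.x
                break
            x0 = res.x
        self._update_scales(res.x)
        return {"theta": res.x, "converged": bool(res.success),
                "message": str(res.message), "n_iter": int(res.nit),
                "objective_value": float(res.fun)}


class CHDModel:
    """Joint birth-prevalence / excess-mortality model for a congenital
    condition, fitted separately per sex.

    Parameters
    ----------
    observations : DataFrame
        Columns measure ('prevalence' or 'csmr'), age_lo, age_hi, sex, year,
        value, effective_n.
    population : DataFrame
        Columns age, sex, year, population (midyear person counts).
    grid : AgeTimeGrid, optional
        Defaults to ages 0..100 by the observation year span.
    config : ModelConfig, optional
    """

    def __init__(self, observations: pd.DataFrame, population: pd.DataFrame,
                 grid: AgeTimeGrid | None = None, config: ModelConfig | None = None):
        self.observations = validate_observations(observations)
        self.population = population
        self.config = config or ModelConfig()
        if grid is None:
            years = self.observations["year"]
            # default grid: as high as the population table supports (<= 100),
            # but at least the oldest observed age
            age_max = min(100, int(population["age"].max()))
            age_max = max(age_max, int(self.observations["age_hi"].max()))
            grid = AgeTimeGrid.from_ranges(age_max, int(years.min()), int(years.max()))
        if grid.ages[-1] < 65:
            raise ValueError("grid must reach age 65 to cover the adult band")
        self.grid = grid
        self.sexes = tuple(sorted(self.observations["sex"].unique()))
        # None => per-observation half-count offsets inside each problem
        self.delta_by_measure = self.config.offset_delta
        self._pop_grids = {s: self._population_grid(s) for s in self.sexes}
        self._problems = {
            s: _SexProblem(s, self.observations[self.observations["sex"] == s],
                           self._pop_grids[s], self.grid, self.config,
                           self.delta_by_measure)
            for s in self.sexes}

    @classmethod
    def from_tables(cls, survey: pd.DataFrame, deaths: pd.DataFrame,
                    population: pd.DataFrame, grid: AgeTimeGrid | None = None,
                    config: ModelConfig | None = None) -> "CHDModel":
        """Build from the three raw tables (survey.csv / deaths.csv /
        population.csv schemas)."""
        obs = pd.concat([observations_from_survey(survey),
                         observations_from_deaths(deaths)], ignore_index=True)
        return cls(obs, population, grid=grid, config=config)

    def _population_grid(self, sex: str) -> np.ndarray:
        """Population pivoted onto the grid; NaN where absent."""
        out = np.full(self.grid.shape, np.nan)
        sub = self.population[self.population["sex"] == sex]
        in_grid = (sub["age"].between(self.grid.ages[0], self.grid.ages[-1])
                   & sub["year"].between(self.grid.years[0], self.grid.years[-1]))
        sub = sub[in_grid]
        ai = self.grid.age_index(sub["age"].to_numpy())
        ti = self.grid.year_index(sub["year"].to_numpy())
        out[ai, ti] = sub["population"].to_numpy(dtype=float)
        return out

    def fit(self, start: dict | None = None):
        """Run the per-sex MAP fits and return a CHDResults."""
        from .results import CHDResults

        fits = {}
        for sex, problem in self._problems.items():
            x0 = None if start is None else start.get(sex)
            info = problem.fit(x0)
            if not info["converged"]:
                warnings.warn(f"optimizer did not converge for sex {sex!r}: "
                              f"{info['message']}", RuntimeWarning)
            info["decomposition"] = problem.decompose(info["theta"])
            fits[sex] = info
        return CHDResults(self, fits)
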