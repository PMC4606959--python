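"""Cohort solver for the one-compartment congenital-disease model.

The only inflow into the with-condition compartment is birth (no incidence
after birth, no remission), and the only outflow is the excess-mortality
hazard chi.  Along a birth cohort (the characteristic a = t - birth_year) the
prevalence proportion follows

    dp/da = -chi(a) * p(a),        p(0) = birth prevalence,

for a condition rare enough that depletion of the unaffected population is
negligible.  A logistic variant dp/da = -chi * p * (1 - p) is available for
conditions where that linearization is in doubt.

Integration uses exact per-step survival factors exp(-chibar * da) with
chibar the midpoint (trapezoid) hazard over the step, which is exact for
piecewise-linear hazards and unconditionally positive.
"""

from __future__ import annotations

import numpy as np

from .grids import PrevalenceSurface, RateSurface

__all__ = ["solve_cohort", "solve_surface", "solve_log_prevalence"]


def solve_cohort(p0: float, chi_path: np.ndarray, ages: np.ndarray | None = None,
                 *, logistic: bool = False) -> np.ndarray:
    """Integrate one birth cohort's prevalence along its characteristic.

    Parameters
    ----------
    p0 : float
        Birth prevalence, in [0, 1].
    chi_path : array
        Hazard (per person-year) at each age node along the cohort.
    ages : array, optional
        Age nodes; defaults to 0, 1, ..., len(chi_path)-1.
    logistic : bool
        Use the saturating form dp/da = -chi p (1 - p) instead of the
        rare-disease linearization.

    Returns
    -------
    array of prevalence at each age node; non-increasing, within [0, p0].
    """
    chi_path = np.asarray(chi_path, dtype=float)
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must lie in [0, 1]")
    if np.any(chi_path < 0) or not np.all(np.isfinite(chi_path)):
        raise ValueError("hazard path must be non-negative and finite")
    if ages is None:
        ages = np.arange(chi_path.size, dtype=float)
    else:
        ages = np.asarray(ages, dtype=float)
        if ages.shape != chi_path.shape:
            raise ValueError("ages and chi_path must have the same length")
    da = np.diff(ages)
    # cumulative integral of chi by the trapezoid rule
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (chi_path[:-1] + chi_path[1:]) * da)])
    if p0 == 0.0:
        return np.zeros_like(cum)
    if logistic:
        # exact solution of the logistic ODE given the integrated hazard
        surv = np.exp(-cum)
        return p0 * surv / (1.0 - p0 + p0 * surv)
    return p0 * np.exp(-cum)


def solve_log_prevalence(log_p0_by_year: np.ndarray, chi_values: np.ndarray) -> np.ndarray:
    """Log-prevalence grid from log birth prevalence per year and a chi grid.

    Every cohort diagonal is integrated with midpoint survival factors.
    Cohorts already alive at the first grid year are handled by the boundary
    rule that rates are constant across cohorts before the window: their
    pre-window history uses the first-year age profile of chi, which makes
    the left edge column satisfy the same recursion within the first column.

    This is the fitting kernel: it works on raw arrays (n_ages x n_years)
    and stays in log space so the fit's adjoint pass can reverse it cheaply.
    """
    chi = np.asarray(chi_values, dtype=float)
    n_a, n_t = chi.shape
    logp = np.empty((n_a, n_t))
    logp[0, :] = log_p0_by_year
    for a in range(1, n_a):
        # interior cells: step from (a-1, t-1); left edge: step down column 0
        logp[a, 1:] = logp[a - 1, :-1] - 0.5 * (chi[a - 1, :-1] + chi[a, 1:])
        logp[a, 0] = logp[a - 1, 0] - 0.5 * (chi[a - 1, 0] + chi[a, 0])
    return logp


def solve_surface(birth_prevalence: np.ndarray | float, chi: RateSurface,
                  *, logistic: bool = False) -> PrevalenceSurface:
    """Solve the prevalence surface from per-year birth prevalence and chi.

    ``birth_prevalence`` may be a scalar (constant over time) or one value per
    grid year.  Cohorts entering at the grid's left edge at age > 0 inherit
    the first year's hazard profile and birth prevalence (constant-rate
    boundary rule before the data window).
    """
    grid = chi.grid
    p0 = np.broadcast_to(np.asarray(birth_prevalence, dtype=float), (grid.n_years,)).copy()
    if np.any(p0 < 0) or np.any(p0 > 1):
        raise ValueError("birth prevalence must lie in [0, 1]")
    if np.any(chi.values < 0):
        raise ValueError("hazard surface must be non-negative")
    if logistic:
        values = np.empty(grid.shape)
        n_a, n_t = grid.shape
        # diagonals entering at the top row
        for j in range(n_t):
            length = min(n_a, n_t - j)
            path = chi.values[np.arange(length), j + np.arange(length)]
            values[np.arange(length), j + np.arange(length)] = solve_cohort(
                p0[j], path, logistic=True
            )
        # diagonals entering at the left edge: prepend the frozen pre-window history
        for a0 in range(1, n_a):
            length = min(n_a - a0, n_t)
            pre = chi.values[: a0 + 1, 0]
            path = np.concatenate([pre[:-1], chi.values[a0 + np.arange(length), np.arange(length)]])
            full = solve_cohort(p0[0], path, logistic=True)
            values[a0 + np.arange(length), np.arange(length)] = full[a0:]
        return PrevalenceSurface(grid, values)
    with np.errstate(divide="ignore"):
        logp0 = np.log(p0)
    logp = solve_log_prevalence(logp0, chi.values)
    values = np.exp(logp)
    values[:, :] = np.where(np.isfinite(logp), values, 0.0)
    return PrevalenceSurface(grid, values)
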