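"""Projection of fitted rates beyond the data window and prevalent counts.

Past the last data year, birth prevalence and the excess-mortality hazard
are conservatively held constant across cohorts: projected cohorts inherit
the final year's birth prevalence, and chi beyond the window repeats its
final-year age profile.  The prevalence surface is then re-solved on the
extended grid, multiplied by population to give prevalent counts, and
aggregated to the reporting age bands (0-51 weeks stands in as single-year
age 0; the adult band is ages 20-64 inclusive, upper bound configurable).

Under constant rates and a stationary population the projected age profile
converges to a fixed shape — the prevalent adult population plateaus, with
growth tracking population growth only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import AgeTimeGrid, PrevalenceSurface, RateSurface
from .solver import solve_surface

__all__ = ["AgeBand", "default_bands", "extend_surfaces", "extend_constant",
           "truncate", "prevalent_counts", "aggregate", "project"]


@dataclass(frozen=True)
class AgeBand:
    """A named closed age band, optionally restricted to one sex."""

    name: str
    age_lo: int
    age_hi: int
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.age_lo > self.age_hi:
            raise ValueError(f"band {self.name}: age_lo > age_hi")


def default_bands(adult_upper: int = 64) -> tuple:
    """The reporting bands: infancy, childhood, the 20-64 adult band and
    reproductive-age females (15-49)."""
    return (
        AgeBand("0", 0, 0),
        AgeBand("1-4", 1, 4),
        AgeBand("5-9", 5, 9),
        AgeBand("10-14", 10, 14),
        AgeBand("15-19", 15, 19),
        AgeBand(f"20-{adult_upper}", 20, adult_upper),
        AgeBand("females 15-49", 15, 49, sex="female"),
    )


def extend_surfaces(prevalence: PrevalenceSurface, chi: RateSurface,
                    to_year: int) -> tuple[PrevalenceSurface, RateSurface]:
    """Extend one surface pair to ``to_year`` under constant post-window rates."""
    grid = chi.grid
    if to_year <= grid.years[-1]:
        raise ValueError(f"to_year {to_year} must exceed the fitted window "
                         f"end {grid.years[-1]}")
    n_extra = to_year - int(grid.years[-1])
    new_grid = AgeTimeGrid(grid.ages, np.arange(grid.years[0], to_year + 1))
    chi_ext = np.hstack([chi.values, np.repeat(chi.values[:, -1:], n_extra, axis=1)])
    bp = prevalence.birth_prevalence
    bp_ext = np.concatenate([bp, np.full(n_extra, bp[-1])])
    chi_new = RateSurface(new_grid, chi_ext, allow_zero=bool(np.any(chi.values == 0)))
    return solve_surface(bp_ext, chi_new), chi_new


def extend_constant(results, to_year: int):
    """Extended copy of a fit: constant birth prevalence and hazard after the
    data window, surfaces re-solved on the extended grid.

    Accepts a :class:`~chdprev.results.CHDResults` or a plain mapping
    ``{sex: {"prevalence": ..., "chi": ...}}``; returns the surfaces mapping
    shape either way (projection needs nothing else from the fit).
    """
    surfaces = getattr(results, "surfaces", results)
    out = {}
    for sex, pair in surfaces.items():
        p, chi = extend_surfaces(pair["prevalence"], pair["chi"], to_year)
        out[sex] = {"prevalence": p, "chi": chi}
    return out


def truncate(surfaces: dict, to_year: int) -> dict:
    """Restrict a surfaces mapping back to years <= to_year."""
    out = {}
    for sex, pair in surfaces.items():
        grid = pair["chi"].grid
        if to_year < grid.years[0]:
            raise ValueError("to_year before the fitted window")
        keep = grid.years <= to_year
        new_grid = AgeTimeGrid(grid.ages, grid.years[keep])
        out[sex] = {
            "prevalence": PrevalenceSurface(new_grid, pair["prevalence"].values[:, keep]),
            "chi": RateSurface(new_grid, pair["chi"].values[:, keep],
                               allow_zero=True),
        }
    return out


def _as_surfaces_mapping(obj) -> dict:
    if isinstance(obj, PrevalenceSurface):
        raise TypeError("pass {sex: {'prevalence': ..., 'chi': ...}} or CHDResults")
    return getattr(obj, "surfaces", obj)


def prevalent_counts(prevalence, population: pd.DataFrame) -> pd.DataFrame:
    """Prevalent-case counts: count(a, s, t) = p(a, s, t) * N(a, s, t).

    ``prevalence`` is a mapping {sex: PrevalenceSurface} (or CHDResults /
    surfaces mapping).  Every grid cell must have a population row; grids
    and population table must align.
    """
    if isinstance(prevalence, PrevalenceSurface):
        raise TypeError("prevalent_counts needs per-sex surfaces: "
                        "{sex: PrevalenceSurface} or a surfaces mapping")
    mapping = _as_surfaces_mapping(prevalence)
    frames = []
    for sex, entry in mapping.items():
        surf = entry["prevalence"] if isinstance(entry, dict) else entry
        grid = surf.grid
        pop = population[population["sex"] == sex]
        pivot = np.full(grid.shape, np.nan)
        in_grid = (pop["age"].between(grid.ages[0], grid.ages[-1])
                   & pop["year"].between(grid.years[0], grid.years[-1]))
        pop = pop[in_grid]
        pivot[grid.age_index(pop["age"].to_numpy()),
              grid.year_index(pop["year"].to_numpy())] = pop["population"].to_numpy()
        if np.isnan(pivot).any():
            a, t = np.argwhere(np.isnan(pivot))[0]
            raise ValueError(f"population table does not cover the grid "
                             f"(missing sex={sex} age={grid.ages[a]} "
                             f"year={grid.years[t]})")
        counts = surf.values * pivot
        df = surf.to_frame("prevalence")
        df.insert(2, "sex", sex)
        df["population"] = pivot.ravel()
        df["count"] = counts.ravel()
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def aggregate(counts: pd.DataFrame, bands=None) -> pd.DataFrame:
    """Banded prevalent counts and per-1,000 prevalence by year.

    Bands aggregate over both sexes unless the band names one.  A band that
    matches no rows is an error.
    """
    bands = bands if bands is not None else default_bands()
    rows = []
    for band in bands:
        sel = counts["age"].between(band.age_lo, band.age_hi)
        if band.sex is not None:
            sel &= counts["sex"] == band.sex
        sub = counts[sel]
        if sub.empty:
            raise ValueError(f"band {band.name!r} matches no counts")
        g = sub.groupby("year", as_index=False)[["count", "population"]].sum()
        g.insert(0, "band", band.name)
        g["prev_per_1000"] = 1000.0 * g["count"] / g["population"]
        rows.append(g)
    return pd.concat(rows, ignore_index=True)


def _projection_population(population: pd.DataFrame, years: np.ndarray) -> pd.DataFrame:
    """Population covering the horizon; last observed year held constant
    (with a warning) where the table stops short."""
    have = population[population["year"].isin(years)]
    missing = sorted(set(int(y) for y in years) - set(have["year"].unique()))
    if not missing:
        return have
    last_year = int(population["year"].max())
    warnings.warn(
        f"population table stops at {last_year}; holding it constant for "
        f"{len(missing)} projected years", UserWarning)
    template = population[population["year"] == last_year]
    frames = [have]
    for y in missing:
        block = template.copy()
        block["year"] = y
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def project(results, to_year: int, population: pd.DataFrame | None = None,
            bands=None, bootstrap=None) -> pd.DataFrame:
    """Projected banded counts and prevalence, with optional bootstrap UIs.

    Returns a frame with columns band, year, count, prev_per_1000 and — when
    a :class:`~chdprev.bootstrap.BootstrapResults` is supplied — count_lo /
    count_hi / prev_lo / prev_hi computed per replicate then percentiled.
    """
    extended = extend_constant(results, to_year)
    grid_years = next(iter(extended.values()))["chi"].grid.years
    if population is None:
        population = results.model.population
    population = _projection_population(population, grid_years)
    point = aggregate(prevalent_counts(extended, population), bands)
    if bootstrap is None:
        return point

    reps = []
    n_common = None
    for sex in bootstrap.thetas:
        n = bootstrap.n_kept(sex)
        n_common = n if n_common is None else min(n_common, n)
    for r in range(n_common):
        surfaces = {}
        for sex in bootstrap.thetas:
            problem = bootstrap.base.model._problems[sex]
            p, chi = problem.surfaces(bootstrap.thetas[sex][r])
            surfaces[sex] = {"prevalence": p, "chi": chi}
        ext = extend_constant(surfaces, to_year)
        agg = aggregate(prevalent_counts(ext, population), bands)
        reps.append(agg[["count", "prev_per_1000"]].to_numpy())
    stack = np.stack(reps)
    point["count_lo"] = np.percentile(stack[:, :, 0], 2.5, axis=0)
    point["count_hi"] = np.percentile(stack[:, :, 0], 97.5, axis=0)
    point["prev_lo"] = np.percentile(stack[:, :, 1], 2.5, axis=0)
    point["prev_hi"] = np.percentile(stack[:, :, 1], 97.5, axis=0)
    return point
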