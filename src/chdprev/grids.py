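"""Age x calendar-year grids and the rate/prevalence surfaces defined on them.

The model works on a rectangular grid of single-year ages (rows) by calendar
years (columns).  Two surfaces live on it:

* :class:`RateSurface` — the excess-mortality hazard chi(a, t), in deaths per
  person-year among prevalent cases, strictly positive.
* :class:`PrevalenceSurface` — the with-condition prevalence proportion
  p(a, t), with the birth prevalence p(0, t) as its first row.

Cohorts run along the diagonals a = t - birth_year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AgeTimeGrid", "RateSurface", "PrevalenceSurface"]


@dataclass(frozen=True)
class AgeTimeGrid:
    """Rectangular grid of integer single-year ages by calendar years."""

    ages: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        years = np.asarray(self.years, dtype=int)
        for name, arr in (("ages", ages), ("years", years)):
            if arr.ndim != 1 or arr.size < 2:
                raise ValueError(f"{name} must be a 1-d array with >= 2 entries")
            if not np.all(np.diff(arr) == 1):
                raise ValueError(f"{name} must be contiguous and strictly increasing")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "years", years)

    @classmethod
    def from_ranges(cls, age_max: int, year_min: int, year_max: int) -> "AgeTimeGrid":
        return cls(np.arange(0, age_max + 1), np.arange(year_min, year_max + 1))

    @property
    def n_ages(self) -> int:
        return self.ages.size

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_ages, self.n_years)

    def age_index(self, age) -> np.ndarray:
        idx = np.asarray(age) - self.ages[0]
        if np.any(idx < 0) or np.any(idx >= self.n_ages):
            raise KeyError(f"age {age} outside grid [{self.ages[0]}, {self.ages[-1]}]")
        return idx

    def year_index(self, year) -> np.ndarray:
        idx = np.asarray(year) - self.years[0]
        if np.any(idx < 0) or np.any(idx >= self.n_years):
            raise KeyError(f"year {year} outside grid [{self.years[0]}, {self.years[-1]}]")
        return idx

    def __eq__(self, other) -> bool:
        if not isinstance(other, AgeTimeGrid):
            return NotImplemented
        return np.array_equal(self.ages, other.ages) and np.array_equal(self.years, other.years)

    def __hash__(self) -> int:  # frozen dataclass with arrays
        return hash((self.ages[0], self.ages[-1], self.years[0], self.years[-1]))


def _check_values(grid: AgeTimeGrid, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} does not match grid {grid.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("surface values must be finite")
    return values


@dataclass
class _Surface:
    grid: AgeTimeGrid
    values: np.ndarray

    def at(self, age, year):
        """Value(s) at integer age/year labels."""
        return self.values[self.grid.age_index(age), self.grid.year_index(year)]

    def to_frame(self, name: str = "value") -> pd.DataFrame:
        a, t = np.meshgrid(self.grid.ages, self.grid.years, indexing="ij")
        return pd.DataFrame(
            {"age": a.ravel(), "year": t.ravel(), name: self.values.ravel()}
        )

    def copy(self):
        return type(self)(self.grid, self.values.copy())


class RateSurface(_Surface):
    """Excess-mortality hazard chi(a, t) in events per person-year; positive."""

    def __init__(self, grid: AgeTimeGrid, values: np.ndarray, *, allow_zero: bool = False):
        values = _check_values(grid, values)
        if allow_zero:
            if np.any(values < 0):
                raise ValueError("hazard values must be non-negative")
        elif np.any(values <= 0):
            raise ValueError("hazard values must be strictly positive")
        self.grid = grid
        self.values = values

    def copy(self):
        return RateSurface(self.grid, self.values.copy(), allow_zero=True)


class PrevalenceSurface(_Surface):
    """With-condition prevalence proportion p(a, t) in [0, 1]."""

    def __init__(self, grid: AgeTimeGrid, values: np.ndarray):
        values = _check_values(grid, values)
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("prevalence values must lie in [0, 1]")
        self.grid = grid
        self.values = values

    @property
    def birth_prevalence(self) -> np.ndarray:
        """p(0, t): the proportion of births with the condition, per grid year."""
        return self.values[0, :]
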