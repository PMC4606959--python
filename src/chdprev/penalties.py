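"""Second-order difference smoothing penalties on log-scale surfaces.

The fit shrinks the log hazard surface toward locally linear behaviour in
three directions — down ages, along cohort diagonals, and a mixed age x year
cross term — and the log prevalence surface along cohorts only.  Each
direction contributes the sum of squared second-order finite differences
divided by 2 sigma^2; sigma = 1 by default.  The penalty is zero exactly when
the log surface is affine in every penalized direction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["second_difference_penalty", "second_difference_penalty_grad", "smoothing_penalty"]

_DIRECTIONS = ("age", "cohort", "cross")


def _diffs(x: np.ndarray, direction: str) -> np.ndarray:
    if direction == "age":
        return x[2:, :] - 2.0 * x[1:-1, :] + x[:-2, :]
    if direction == "cohort":
        return x[2:, 2:] - 2.0 * x[1:-1, 1:-1] + x[:-2, :-2]
    if direction == "cross":
        return x[1:, 1:] - x[1:, :-1] - x[:-1, 1:] + x[:-1, :-1]
    raise ValueError(f"unknown direction {direction!r}; expected one of {_DIRECTIONS}")


def second_difference_penalty(x: np.ndarray, sigma: float = 1.0,
                              directions: tuple[str, ...] = _DIRECTIONS) -> float:
    """Sum over directions of squared second differences of x, over 2 sigma^2."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    total = 0.0
    for d in directions:
        diff = _diffs(x, d)
        total += float(np.sum(diff * diff))
    return total / (2.0 * sigma * sigma)


def second_difference_penalty_grad(x: np.ndarray, sigma: float = 1.0,
                                   directions: tuple[str, ...] = _DIRECTIONS) -> np.ndarray:
    """Gradient of :func:`second_difference_penalty` with respect to x."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for direction in directions:
        d = _diffs(x, direction)
        if direction == "age":
            g[2:, :] += d
            g[1:-1, :] -= 2.0 * d
            g[:-2, :] += d
        elif direction == "cohort":
            g[2:, 2:] += d
            g[1:-1, 1:-1] -= 2.0 * d
            g[:-2, :-2] += d
        else:  # cross
            g[1:, 1:] += d
            g[1:, :-1] -= d
            g[:-1, 1:] -= d
            g[:-1, :-1] += d
    return g / (sigma * sigma)


def smoothing_penalty(surface, sigma: float = 1.0,
                      directions: tuple[str, ...] = _DIRECTIONS) -> float:
    """Smoothing penalty of a rate or prevalence surface, on the log scale.

    ``surface`` is a :class:`~chdprev.grids.RateSurface` or
    :class:`~chdprev.grids.PrevalenceSurface` (anything with ``.values``), or a
    bare array.  Values must be strictly positive, since the second
    differences are taken on log values.
    """
    values = getattr(surface, "values", surface)
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("smoothing penalty is defined on the log scale; values must be > 0")
    return second_difference_penalty(np.log(values), sigma, directions)
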