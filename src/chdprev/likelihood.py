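"""Offset log-normal data model for prevalence and mortality-rate observations.

An observation with value y (a proportion or a rate) and effective sample
size n is modelled on the log scale with a small positive offset delta:

    log(y + delta) ~ Normal(log(mu + delta), s^2)

where mu is the model prediction and

    s^2 = 1 / (n * (mu + delta)) + tau^2.

The first term is the delta-method sampling variance of a log rate — n*(mu +
delta) is the expected event count behind the observation (binomial positives
for prevalence, Poisson deaths for rates) — and tau is a global dispersion
term absorbing extra-sampling noise.  The offset keeps zero-valued
observations at finite density, so zero cells are retained, never dropped.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lognormal_scale", "loglik_offset_lognormal", "default_offset"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def lognormal_scale(predicted, effective_n, delta, dispersion: float):
    """Standard deviation s of the log-scale residual at the given prediction."""
    predicted = np.asarray(predicted, dtype=float)
    effective_n = np.asarray(effective_n, dtype=float)
    if np.any(np.asarray(delta) <= 0):
        raise ValueError("offset delta must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    s2 = 1.0 / (effective_n * (predicted + delta)) + dispersion**2
    return np.sqrt(s2)


def loglik_offset_lognormal(obs_value, predicted, effective_n,
                            delta, dispersion: float):
    """Log-density of the observation(s) under the offset log-normal model.

    Vectorized over observations.  Raises on non-finite or negative inputs;
    the whole point of the offset is that ``obs_value == 0`` is fine.
    """
    obs_value = np.asarray(obs_value, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    effective_n = np.asarray(effective_n, dtype=float)
    for name, arr in (("obs_value", obs_value), ("predicted", predicted),
                      ("effective_n", effective_n)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must be finite")
    if np.any(obs_value < 0) or np.any(predicted < 0):
        raise ValueError("values and predictions must be non-negative")
    if np.any(effective_n <= 0):
        raise ValueError("effective_n must be positive")
    s = lognormal_scale(predicted, effective_n, delta, dispersion)
    r = np.log(obs_value + delta) - np.log(predicted + delta)
    return -0.5 * _LOG_2PI - np.log(s) - 0.5 * (r / s) ** 2


def default_offset(values, fraction: float = 0.01) -> float:
    """Fixed offset delta as a fraction of the median non-zero observed value.

    An alternative to the per-observation half-count rule the model uses by
    default; pass the result via ``ModelConfig.offset_delta``.  Falls back to
    ``fraction`` scaled by 1e-3 when every value is zero (a degenerate
    dataset, but the likelihood must still be proper).
    """
    values = np.asarray(values, dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return fraction * 1e-3
    return fraction * float(np.median(nonzero))
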