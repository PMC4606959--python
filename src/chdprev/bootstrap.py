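"""Parametric-bootstrap uncertainty for fitted and derived quantities.

Each replicate draws new observation values from the fitted offset
log-normal data model at the point-estimate predictions

    log(y* + d) ~ Normal(log(mu_hat + d), s^2(mu_hat)),

refits the model (warm-started from the point estimate), and stores the
replicate parameters.  Uncertainty intervals are percentile-based (2.5th /
97.5th); intervals for derived quantities are computed per replicate and
then percentiled, so nonlinear aggregates are handled correctly.

Non-converged replicates are dropped with a warning; if more than 20% drop,
the bootstrap fails loudly.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["parametric_bootstrap", "BootstrapResults"]


def parametric_bootstrap(results, n_reps: int = 1000, seed: int = 0,
                         max_drop_fraction: float = 0.2) -> "BootstrapResults":
    """Bootstrap a converged point fit.  Same seed and n_reps => identical
    intervals."""
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    model = results.model
    thetas = {sex: [] for sex in results.sexes}
    n_dropped = 0
    for s_idx, sex in enumerate(results.sexes):
        problem = model._problems[sex]
        theta_hat = results.fits[sex]["theta"]
        mu = problem.predicted_values(theta_hat)
        delta = problem.delta_all
        n_eff = problem.obs["effective_n"].to_numpy(dtype=float)
        # the fitted data model: same scale and bias-corrected mean as the fit
        u = mu + delta
        s = np.sqrt(1.0 / (n_eff * u) + results.config.dispersion**2)
        m = np.log(u) - mu / (2.0 * n_eff * u * u)
        for rep in range(n_reps):
            rng = np.random.default_rng([seed, s_idx, rep])
            draw = rng.normal(m, s)
            # support of the offset log-normal is y > -delta: do not clip at
            # zero (that would shift replicate refits upward), only keep
            # prevalence draws inside [.., 1]
            y_new = np.exp(draw) - delta
            y_new[problem.is_prev] = np.minimum(y_new[problem.is_prev], 1.0)
            try:
                # scales stay frozen at the generating model's predictions
                info = problem.with_values(y_new).fit(start=theta_hat,
                                                      n_reweight=1)
            except Exception as exc:  # noqa: BLE001 - replicate-level failure
                warnings.warn(f"bootstrap replicate {rep} ({sex}) failed: {exc}",
                              RuntimeWarning)
                n_dropped += 1
                continue
            if not info["converged"]:
                warnings.warn(f"bootstrap replicate {rep} ({sex}) did not converge",
                              RuntimeWarning)
                n_dropped += 1
                continue
            thetas[sex].append(info["theta"])
    n_total = n_reps * len(results.sexes)
    if n_dropped > max_drop_fraction * n_total:
        raise RuntimeError(
            f"{n_dropped}/{n_total} bootstrap replicates dropped "
            f"(> {100 * max_drop_fraction:.0f}%)")
    return BootstrapResults(results, thetas, n_reps=n_reps, seed=seed,
                            n_dropped=n_dropped)


class BootstrapResults:
    """Replicate parameter draws plus percentile-interval helpers."""

    def __init__(self, base, thetas: dict, n_reps: int, seed: int, n_dropped: int):
        self.base = base
        self.thetas = {sex: list(reps) for sex, reps in thetas.items()}
        self.n_reps = n_reps
        self.seed = seed
        self.n_dropped = n_dropped

    def n_kept(self, sex: str) -> int:
        return len(self.thetas[sex])

    def replicate_surfaces(self, sex: str):
        """Yield (PrevalenceSurface, RateSurface) per kept replicate."""
        problem = self.base.model._problems[sex]
        for theta in self.thetas[sex]:
            yield problem.surfaces(theta)

    def derived(self, func, sex: str, lower: float = 2.5, upper: float = 97.5):
        """Percentile interval of ``func(prevalence_surface, chi_surface)``.

        ``func`` may return a scalar or an array; the interval is taken
        elementwise over replicates.  Returns (lo, hi).
        """
        vals = [np.asarray(func(p, chi)) for p, chi in self.replicate_surfaces(sex)]
        stack = np.stack(vals)
        return (np.percentile(stack, lower, axis=0),
                np.percentile(stack, upper, axis=0))

    def ui_surfaces(self, sex: str, kind: str = "prevalence"):
        """(lower, upper) percentile surfaces for 'prevalence' or 'chi'."""
        idx = 0 if kind == "prevalence" else 1
        lo, hi = self.derived(lambda p, c: (p, c)[idx].values, sex)
        return lo, hi

    def birth_prevalence_interval(self, sex: str, year: int | None = None):
        """95% interval for birth prevalence (per grid year, or at one year)."""
        lo, hi = self.derived(lambda p, c: p.birth_prevalence, sex)
        if year is None:
            return lo, hi
        j = self.base.grid.year_index(int(year))
        return float(lo[j]), float(hi[j])

    def replicates_frame(self) -> "pd.DataFrame":
        """Long-format replicate surfaces (for --keep-replicates output)."""
        import pandas as pd

        frames = []
        for sex in self.thetas:
            for r, (p, chi) in enumerate(self.replicate_surfaces(sex)):
                df = p.to_frame("prevalence")
                df["chi"] = chi.values.ravel()
                df.insert(0, "rep", r)
                df.insert(1, "sex", sex)
                frames.append(df)
        return pd.concat(frames, ignore_index=True)
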