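"""Fit results: fitted surfaces, diagnostics, summary, bootstrap, projection."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import PrevalenceSurface, RateSurface

__all__ = ["CHDResults"]


class CHDResults:
    """Result of :meth:`chdprev.model.CHDModel.fit`.

    Carries, per sex, the MAP prevalence and excess-hazard surfaces on the
    full age x year grid, the optimizer diagnostics and the objective
    decomposition (log-likelihood minus smoothing penalties).  Uncertainty
    comes from :meth:`bootstrap`; projection past the data window from
    :func:`chdprev.projection.extend_constant` / :func:`chdprev.projection.project`.
    """

    def __init__(self, model, fits: dict):
        self.model = model
        self.config = model.config
        self.grid = model.grid
        self.fits = fits
        self.surfaces = {}
        for sex, info in fits.items():
            p, chi = model._problems[sex].surfaces(info["theta"])
            self.surfaces[sex] = {"prevalence": p, "chi": chi}

    # --- accessors ----------------------------------------------------------
    @property
    def sexes(self) -> tuple:
        return tuple(self.surfaces)

    @property
    def converged(self) -> dict:
        return {sex: info["converged"] for sex, info in self.fits.items()}

    def prevalence(self, sex: str) -> PrevalenceSurface:
        return self.surfaces[sex]["prevalence"]

    def chi(self, sex: str) -> RateSurface:
        return self.surfaces[sex]["chi"]

    def birth_prevalence(self, sex: str, year: int | None = None) -> float | np.ndarray:
        """Fitted birth prevalence p(0, t), per grid year or at one year."""
        bp = self.prevalence(sex).birth_prevalence
        if year is None:
            return bp
        return float(bp[self.grid.year_index(int(year))])

    def objective_decomposition(self, sex: str) -> dict:
        return dict(self.fits[sex]["decomposition"])

    # --- per-datum diagnostics -----------------------------------------------
    def fitted_observations(self, sex: str | None = None) -> pd.DataFrame:
        """Observation table with model predictions and log-scale residuals."""
        frames = []
        for s, problem in self.model._problems.items():
            if sex is not None and s != sex:
                continue
            df = problem.obs.copy()
            df["predicted"] = problem.predicted_values(self.fits[s]["theta"])
            delta = problem.delta_all
            df["log_residual"] = (np.log(df["value"] + delta)
                                  - np.log(df["predicted"] + delta))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    # --- output -------------------------------------------------------------
    def surfaces_frame(self) -> pd.DataFrame:
        """Long-format surfaces: age, year, sex, prevalence, chi."""
        frames = []
        for sex in self.sexes:
            df = self.prevalence(sex).to_frame("prevalence")
            df["chi"] = self.chi(sex).values.ravel()
            df.insert(2, "sex", sex)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def fit_report(self) -> dict:
        report = {}
        for sex, info in self.fits.items():
            report[sex] = {
                "converged": info["converged"],
                "message": info["message"],
                "n_iter": info["n_iter"],
                "n_observations": int(len(self.model._problems[sex].obs)),
                **info["decomposition"],
            }
        return report

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = ["Congenital disease model: penalized MAP fit",
                 "=" * 46,
                 f"grid: ages {self.grid.ages[0]}-{self.grid.ages[-1]}, "
                 f"years {self.grid.years[0]}-{self.grid.years[-1]}",
                 f"smoothing sigma: {self.config.smoothing_sigma}, "
                 f"dispersion: {self.config.dispersion}"]
        for sex, info in self.fits.items():
            d = info["decomposition"]
            bp = self.birth_prevalence(sex, int(self.grid.years[-1]))
            lines += [
                "-" * 46,
                f"sex: {sex}   converged: {info['converged']} "
                f"({info['n_iter']} iterations)",
                f"  birth prevalence (final year): {1000 * bp:.2f} per 1,000",
                f"  log-likelihood: {d['loglik']:.2f}   penalty: {d['penalty']:.2f}"
                f"   penalized: {d['objective']:.2f}",
            ]
        return "\n".join(lines)

    # --- downstream ----------------------------------------------------------
    def bootstrap(self, n_reps: int = 1000, seed: int = 0, **kwargs):
        from .bootstrap import parametric_bootstrap
        return parametric_bootstrap(self, n_reps=n_reps, seed=seed, **kwargs)

    def project(self, to_year: int, population: pd.DataFrame | None = None,
                bands=None, bootstrap=None) -> pd.DataFrame:
        from .projection import project
        return project(self, to_year, population=population, bands=bands,
                       bootstrap=bootstrap)

    def plot_surfaces(self, sex: str, ax=None):
        """Quick look at fitted prevalence and hazard age profiles over time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.5))
        years = self.grid.years
        sel = np.linspace(0, years.size - 1, 5).astype(int)
        for j in sel:
            ax[0].plot(self.grid.ages, 1000 * self.prevalence(sex).values[:, j],
                       label=str(years[j]))
            ax[1].semilogy(self.grid.ages, self.chi(sex).values[:, j])
        ax[0].set(xlabel="age", ylabel="prevalence per 1,000")
        ax[1].set(xlabel="age", ylabel="excess hazard (/PY)")
        ax[0].legend(title="year", fontsize=8)
        return ax
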