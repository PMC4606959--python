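"""Constant-rate projection, prevalent counts and band aggregation."""

import numpy as np
import pandas as pd
import pytest

import chdprev as c
from chdprev.grids import AgeTimeGrid, PrevalenceSurface, RateSurface
from chdprev.projection import (AgeBand, aggregate, default_bands,
                                extend_constant, extend_surfaces,
                                prevalent_counts, project, truncate)


@pytest.fixture(scope="module")
def truth_surfaces(default_truth):
    t = default_truth
    return {s: {"prevalence": t.prevalence[s], "chi": t.chi[s]}
            for s in ("male", "female")}


def test_extension_holds_rates_constant(truth_surfaces):
    ext = extend_constant(truth_surfaces, 2050)
    for sex in ("male", "female"):
        chi = ext[sex]["chi"]
        grid = chi.grid
        assert grid.years[-1] == 2050
        j2011 = grid.year_index(2011)
        # chi beyond the window repeats the final-year age profile
        assert np.array_equal(chi.values[:, j2011:],
                              np.repeat(chi.values[:, [j2011]],
                                        grid.n_years - j2011, axis=1))
        bp = ext[sex]["prevalence"].birth_prevalence
        assert np.all(bp[j2011:] == bp[j2011])


def test_extend_then_truncate_round_trips(truth_surfaces):
    ext = extend_constant(truth_surfaces, 2060)
    back = truncate(ext, 2011)
    for sex in ("male", "female"):
        orig = truth_surfaces[sex]["prevalence"].values
        assert np.allclose(back[sex]["prevalence"].values, orig, rtol=1e-10)
        assert np.array_equal(back[sex]["chi"].values,
                              truth_surfaces[sex]["chi"].values)


def test_extension_must_exceed_window(truth_surfaces):
    with pytest.raises(ValueError):
        extend_constant(truth_surfaces, 2005)


def test_age_profile_converges_to_plateau(default_truth):
    """Under constant post-window rates and a stationary population the
    year-over-year change in adult prevalence per capita decays toward zero,
    falling below 0.1%/year once the in-window cohorts have left the adult
    band (about six decades after rates freeze)."""
    t = default_truth
    p, chi = extend_surfaces(t.prevalence["male"], t.chi["male"], 2085)
    grid = p.grid
    adult = (grid.ages >= 20) & (grid.ages <= 64)
    series = p.values[adult, :].mean(axis=0)
    rel = np.abs(np.diff(series) / series[:-1])
    j = {y: grid.year_index(y) for y in (2012, 2050, 2075)}
    assert rel[j[2050]] < rel[j[2012]]          # change rate is decaying
    assert rel[j[2075]] < rel[j[2050]]
    assert rel[j[2075]] < 1e-3                  # converged: < 0.1%/year


def test_prevalent_counts_arithmetic():
    grid = AgeTimeGrid.from_ranges(70, 2000, 2001)
    vals = np.full(grid.shape, 0.001)
    vals[5, :] = 0.0
    surfaces = {"male": {
        "prevalence": PrevalenceSurface(grid, vals),
        "chi": RateSurface(grid, np.full(grid.shape, 0.01)),
    }}
    pop = pd.DataFrame([
        {"age": a, "sex": "male", "year": y, "population": 1_000_000}
        for a in grid.ages for y in grid.years])
    counts = prevalent_counts(surfaces, pop)
    assert counts.loc[(counts.age == 10) & (counts.year == 2000), "count"] \
        .iloc[0] == pytest.approx(1000)
    assert (counts.loc[counts.age == 5, "count"] == 0).all()
    # band total equals the brute-force sum of per-age products
    band = aggregate(counts, (AgeBand("20-64", 20, 64),))
    manual = counts[(counts.age >= 20) & (counts.age <= 64)
                    & (counts.year == 2000)]["count"].sum()
    assert band.loc[band.year == 2000, "count"].iloc[0] == pytest.approx(manual)


def test_counts_require_full_population_coverage():
    grid = AgeTimeGrid.from_ranges(70, 2000, 2001)
    surfaces = {"male": {
        "prevalence": PrevalenceSurface(grid, np.full(grid.shape, 0.001)),
        "chi": RateSurface(grid, np.full(grid.shape, 0.01))}}
    pop = pd.DataFrame([{"age": a, "sex": "male", "year": 2000,
                         "population": 1000} for a in grid.ages])
    with pytest.raises(ValueError, match="year=2001"):
        prevalent_counts(surfaces, pop)


def test_aggregate_band_prevalence_is_population_weighted():
    counts = pd.DataFrame({
        "age": [20, 21], "sex": ["male"] * 2, "year": [2000] * 2,
        "prevalence": [0.001, 0.003], "population": [1e6, 1e6],
        "count": [1000.0, 3000.0]})
    out = aggregate(counts, (AgeBand("20-21", 20, 21),))
    assert out["prev_per_1000"].iloc[0] == pytest.approx(2.0)
    single = aggregate(counts, (AgeBand("21", 21, 21),))
    assert single["count"].iloc[0] == pytest.approx(3000.0)


def test_empty_band_is_error():
    counts = pd.DataFrame({"age": [5], "sex": ["male"], "year": [2000],
                           "population": [1.0], "count": [0.0]})
    with pytest.raises(ValueError, match="matches no counts"):
        aggregate(counts, (AgeBand("90-99", 90, 99),))


def test_default_bands_partition_conserves_total(truth_surfaces, default_truth):
    counts = prevalent_counts(truth_surfaces, default_truth.population)
    partition = tuple(AgeBand(f"b{i}", lo, hi) for i, (lo, hi) in
                      enumerate([(0, 0), (1, 4), (5, 9), (10, 14), (15, 19),
                                 (20, 64), (65, 100)]))
    banded = aggregate(counts, partition)
    total_by_year = banded.groupby("year")["count"].sum()
    direct = counts.groupby("year")["count"].sum()
    assert np.allclose(total_by_year.to_numpy(), direct.to_numpy())
    # counts bounded by population everywhere
    assert (counts["count"] <= counts["population"]).all()
    assert (counts["count"] >= 0).all()


def test_female_reproductive_band_filters_sex(truth_surfaces, default_truth):
    counts = prevalent_counts(truth_surfaces, default_truth.population)
    band = aggregate(counts, (AgeBand("females 15-49", 15, 49, sex="female"),))
    manual = counts[(counts.sex == "female") & counts.age.between(15, 49)
                    & (counts.year == 2010)]["count"].sum()
    assert band.loc[band.year == 2010, "count"].iloc[0] == pytest.approx(manual)


def test_project_warns_when_population_stops_short(fitted):
    with pytest.warns(UserWarning, match="holding it constant"):
        table = project(fitted, 2030)
    assert set(table["band"]) == {b.name for b in default_bands()}
    assert table["year"].max() == 2030
    adult = table[table["band"] == "20-64"]
    assert (adult["count"] > 0).all()
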