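"""Profile histogram, power-law fitting and 1-degree gridding."""

import numpy as np
import pandas as pd
import pytest

from firepatches import (
    compare_grids,
    fit_power_law,
    generate_powerlaw_patch_sizes,
    grid_traits,
    profile_histogram,
)
from firepatches.gridstats import fit_patch_sizes, read_trait_grid, write_trait_grid


def toy_catalogue(xs, ys, areas=None, **traits):
    n = len(xs)
    data = {
        "patch_id": [f"SYN_co5_t0_{i:06d}" for i in range(n)],
        "x_deg": xs,
        "y_deg": ys,
        "area_ha": areas if areas is not None else np.full(n, 100.0),
    }
    for k, v in traits.items():
        data[k] = v
    return pd.DataFrame(data)


def test_profile_histogram_conserves_counts():
    rng = np.random.default_rng(0)
    areas = rng.uniform(10, 5000, 400)
    bins = profile_histogram(areas)
    assert bins.counts.sum() == 400
    assert np.all(bins.errors == np.sqrt(bins.counts))
    assert np.all(np.diff(bins.edges) > 0)


def test_profile_histogram_identical_areas():
    bins = profile_histogram(np.full(100, 250.0))
    assert bins.n_bins == 1 and bins.counts[0] == 100 and bins.errors[0] == 10


def test_profile_histogram_rejects_bad_input():
    with pytest.raises(ValueError):
        profile_histogram([])
    with pytest.raises(ValueError):
        profile_histogram([10.0, -1.0])


def test_log_density_slope_matches_exponent():
    """A noiseless inverse-CDF power-law sample is log-log linear, slope -beta."""
    beta = 1.8
    u = (np.arange(20000) + 0.5) / 20000  # deterministic quantile sample
    a, b = 10.0, 1e4
    e = 1.0 - beta
    areas = (a**e + u * (b**e - a**e)) ** (1 / e)
    bins = profile_histogram(areas, bins_per_decade=5)
    occ = bins.counts > 0
    slope = np.polyfit(np.log(bins.centers[occ]), np.log(bins.density[occ]), 1)[0]
    assert slope == pytest.approx(-beta, abs=0.05)
    fit = fit_power_law(bins)
    assert fit.beta == pytest.approx(beta, abs=0.05)


@pytest.mark.parametrize("beta_true", [1.5, 2.0, 2.5])
def test_power_law_recovery_within_three_sigma(beta_true):
    areas = generate_powerlaw_patch_sizes(beta_true, 50_000, (10, 10_000), seed=11)
    fit = fit_patch_sizes(areas)
    assert fit.converged
    assert abs(fit.beta - beta_true) < 3 * fit.sigma_beta + 0.02


def test_flat_density_fits_beta_zero():
    areas = generate_powerlaw_patch_sizes(0.0, 50_000, (10, 1000), seed=5)
    fit = fit_patch_sizes(areas)
    assert abs(fit.beta) < max(3 * fit.sigma_beta, 0.02)


def test_doubling_counts_halves_sigma_beta():
    areas = generate_powerlaw_patch_sizes(2.0, 20_000, (10, 10_000), seed=3)
    fit1 = fit_patch_sizes(areas)
    fit2 = fit_patch_sizes(np.concatenate([areas, areas]))
    ratio = fit2.sigma_beta / fit1.sigma_beta
    assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.10)


def test_too_few_bins_is_missing_fit():
    fit = fit_patch_sizes(np.full(50, 100.0))
    assert not fit.converged and np.isnan(fit.beta)
    assert "bins" in fit.message


def test_grid_single_cell_count():
    cat = toy_catalogue(
        np.full(30, 10.3), np.full(30, 45.7),
        par=np.linspace(0.4, 0.8, 30),
    )
    grid = grid_traits(cat, min_fires_for_fit=100)
    assert int(grid["count"].sum()) == 30
    occupied = grid["count"].values.nonzero()
    assert len(occupied[0]) == 1
    assert grid["par_mean"].values[occupied][0] == pytest.approx(0.6)


def test_grid_cell_mean():
    cat = toy_catalogue([0.5, 0.6], [0.5, 0.4], par=[0.4, 0.8])
    grid = grid_traits(cat, min_fires_for_fit=100)
    assert grid["par_mean"].sel(lat=0.5, lon=0.5).item() == pytest.approx(0.6)


def test_grid_translation_by_one_degree():
    rng = np.random.default_rng(2)
    xs = rng.uniform(0, 3, 200)
    ys = rng.uniform(40, 42, 200)
    cat = toy_catalogue(xs, ys, par=rng.uniform(0.2, 1.0, 200))
    g0 = grid_traits(cat, min_fires_for_fit=10**9)
    shifted = cat.copy()
    shifted["x_deg"] += 1.0
    g1 = grid_traits(shifted, min_fires_for_fit=10**9)
    assert np.array_equal(g1["lon"].values, g0["lon"].values + 1.0)
    np.testing.assert_array_equal(g0["count"].values, g1["count"].values)
    np.testing.assert_allclose(
        g0["par_mean"].values, g1["par_mean"].values, equal_nan=True
    )


def test_grid_beta_on_dense_cell():
    areas = generate_powerlaw_patch_sizes(2.0, 5000, (10, 10_000), seed=9)
    cat = toy_catalogue(np.full(5000, 20.5), np.full(5000, 0.5), areas=areas)
    grid = grid_traits(cat, min_fires_for_fit=20)
    beta = grid["beta"].sel(lat=0.5, lon=20.5).item()
    sigma = grid["sigma_beta"].sel(lat=0.5, lon=20.5).item()
    assert abs(beta - 2.0) < 3 * sigma + 0.05
    assert sigma > 0


def test_compare_grids_agreement():
    cat = toy_catalogue([0.5], [0.5])
    base = grid_traits(cat, min_fires_for_fit=10**9)
    a = base.copy(deep=True)
    b = base.copy(deep=True)
    a["beta"].values[:] = 2.0
    a["sigma_beta"].values[:] = 0.1
    b["beta"].values[:] = 2.5
    b["sigma_beta"].values[:] = 0.1
    out = compare_grids(a, b)
    assert out["beta_difference"].values[0, 0] == pytest.approx(-0.5)
    assert out["agreement_sigma"].values[0, 0] == pytest.approx(0.5 / np.sqrt(0.02))
    # identical grids agree at 0 everywhere
    same = compare_grids(a, a)
    assert np.allclose(same["agreement_sigma"].values, 0.0)
    # missing cells propagate
    b["beta"].values[:] = np.nan
    assert np.isnan(compare_grids(a, b)["agreement_sigma"].values).all()


def test_compare_grids_geometry_mismatch():
    a = grid_traits(toy_catalogue([0.5], [0.5]), min_fires_for_fit=10**9)
    b = grid_traits(toy_catalogue([5.5], [0.5]), min_fires_for_fit=10**9)
    with pytest.raises(ValueError):
        compare_grids(a, b)


def test_netcdf_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    cat = toy_catalogue(
        rng.uniform(0, 2, 50), rng.uniform(0, 2, 50),
        par=rng.uniform(0.2, 1.0, 50), si=rng.uniform(1, 3, 50),
    )
    grid = grid_traits(cat, min_fires_for_fit=10**9)
    path = tmp_path / "trait_map_SYN_1.0deg_co_5.nc"
    write_trait_grid(grid, path)
    back = read_trait_grid(path)
    np.testing.assert_array_equal(back["count"].values, grid["count"].values)
    np.testing.assert_allclose(
        back["par_mean"].values, grid["par_mean"].values, equal_nan=True
    )
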