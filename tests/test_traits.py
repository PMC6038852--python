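"""Morphological trait computations: perimeter, core, areas, indices."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from firepatches import (
    core_pixels,
    areas,
    flood_fill_patches,
    fractal_dimension,
    perimeter,
    pixel_area_ha,
    shape_index,
    scalar_traits,
)
from firepatches.patches import FirePatch
from firepatches.traits import min_compact_perimeter

from conftest import make_raster, random_date_raster


def patch_from_mask(mask, date=10):
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    pixels = np.column_stack((rows, cols, np.full(len(rows), date)))
    return FirePatch("test_co5_t0_000000", pixels, 5)


@pytest.mark.parametrize(
    "mask,expected",
    [
        ([[1]], 4),
        ([[1, 1], [1, 1]], 8),
        ([[1, 1, 1], [1, 0, 1], [1, 1, 1]], 16),  # 12 outer + 4 hole
        ([[1, 1, 1, 1, 1]], 12),
    ],
)
def test_perimeter_counts_all_boundaries(mask, expected):
    assert perimeter(patch_from_mask(mask)) == expected


@pytest.mark.parametrize(
    "mask,expected",
    [
        (np.ones((3, 3)), 1),
        (np.ones((2, 8)), 0),
        (np.ones((5, 5)), 9),
    ],
)
def test_core_pixels(mask, expected):
    assert core_pixels(patch_from_mask(mask)) == expected


def test_core_four_neighbour_variant():
    plus = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    assert core_pixels(patch_from_mask(plus), neighbourhood=4) == 1
    assert core_pixels(patch_from_mask(plus), neighbourhood=8) == 0


def test_pixel_area_equator_modis():
    # a 463 m pixel at the equator covers ~21.44 ha
    deg = 463.0 / 111_195.0
    assert pixel_area_ha(0.0, deg) == pytest.approx(21.44, abs=0.05)


def test_area_scales_with_cos_latitude():
    deg = 0.01
    ratio = pixel_area_ha(60.0, deg) / pixel_area_ha(0.0, deg)
    assert ratio == pytest.approx(math.cos(math.radians(60.0)), rel=1e-4)


def test_areas_strip_has_no_core():
    vals = np.zeros((6, 6), dtype=np.int32)
    vals[2, 1:5] = 10
    raster = make_raster(vals)
    (patch,) = flood_fill_patches(raster, 3)
    a, a_core = areas(patch, raster)
    assert a > 0 and a_core == 0.0


@pytest.mark.parametrize(
    "n,p,compact,sqrt_form",
    [
        (49, 42, 1.5, 1.5),  # N a perfect square: variants agree
        (63, 52, 1.625, 0.25 * 52 / math.sqrt(63)),
        (295, 220, 220 / 70, 0.25 * 220 / math.sqrt(295)),
    ],
)
def test_shape_index_variants(n, p, compact, sqrt_form):
    assert shape_index(p, n) == pytest.approx(compact, abs=1e-9)
    assert shape_index(p, n, "sqrt_formula") == pytest.approx(sqrt_form, abs=1e-9)


def test_shape_index_square_is_one():
    for n in (2, 3, 7):
        assert shape_index(4 * n, n * n) == 1.0
    with pytest.raises(ValueError):
        shape_index(12, 9, variant="nope")


@pytest.mark.parametrize(
    "n,p,expected",
    [
        (171, 136, 1.37),
        (63, 52, 1.24),
        (4, 8, 1.0),
    ],
)
def test_fractal_dimension(n, p, expected):
    assert round(fractal_dimension(p, n), 2) == expected


def test_fractal_dimension_singleton_missing():
    assert math.isnan(fractal_dimension(4, 1))


def test_scalar_traits_fields():
    vals = np.zeros((10, 10), dtype=np.int32)
    vals[2:5, 2:5] = 40
    raster = make_raster(vals, year=2007)
    (patch,) = flood_fill_patches(raster, 3)
    t = scalar_traits(patch, raster)
    assert t["n_pixels"] == 9 and t["n_core_pixels"] == 1
    assert t["par"] == pytest.approx(12 / 9)
    assert t["si"] == 1.0
    assert t["bd_min"] == t["bd_max"] == t["bd_mean"] == 40
    assert t["year"] == 2007
    assert 0 <= t["ca"] <= 1
    assert t["n_core_pixels"] <= t["n_pixels"] and t["core_area_ha"] <= t["area_ha"]


def test_translation_changes_only_center():
    vals = np.zeros((20, 20), dtype=np.int32)
    vals[2:5, 2:7] = 10
    vals[12:15, 9:14] = 10  # same footprint shifted by (10, 7)
    raster = make_raster(vals)
    a, b = flood_fill_patches(raster, 3)
    ta, tb = scalar_traits(a, raster), scalar_traits(b, raster)
    for key in ("n_pixels", "n_core_pixels", "perimeter", "par", "si", "d2"):
        assert ta[key] == tb[key]
    assert ta["x_deg"] != tb["x_deg"] and ta["y_deg"] != tb["y_deg"]


def test_indices_invariant_under_rotation_and_mirror():
    rng = np.random.default_rng(3)
    base = rng.random((7, 9)) < 0.6
    base[3, 4] = True
    for transform in (np.rot90, np.fliplr, np.flipud):
        p0 = patch_from_mask(base)
        p1 = patch_from_mask(transform(base))
        assert perimeter(p0) == perimeter(p1)
        assert core_pixels(p0) == core_pixels(p1)


def test_par_decreases_along_squares():
    pars = [4 * n / (n * n) for n in range(1, 10)]
    patches = [patch_from_mask(np.ones((n, n))) for n in range(1, 10)]
    measured = [perimeter(p) / p.n_pixels for p in patches]
    assert measured == pytest.approx(pars)
    assert all(a > b for a, b in zip(measured, measured[1:]))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_perimeter_at_least_compact_minimum(seed):
    """Any patch's perimeter is >= that of the compact arrangement, so SI >= 1."""
    raster = random_date_raster(seed, shape=(15, 15), p_burn=0.5, day_range=(1, 5))
    for patch in flood_fill_patches(raster, 14):
        assert perimeter(patch) >= min_compact_perimeter(patch.n_pixels)
        assert shape_index(perimeter(patch), patch.n_pixels) >= 1.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_d2_bounds_for_real_patches(seed):
    """1 <= D2 <= 2 for patches of at least 5 pixels."""
    raster = random_date_raster(seed, shape=(20, 20), p_burn=0.55, day_range=(1, 5))
    for patch in flood_fill_patches(raster, 14):
        if patch.n_pixels >= 5:
            d2 = fractal_dimension(perimeter(patch), patch.n_pixels)
            assert 1.0 <= d2 <= 2.0
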