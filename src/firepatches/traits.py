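"""Scalar morphological functional traits of a fire patch.

All counting traits (perimeter, core pixels) are evaluated on the patch's
own pixel footprint in grid units; areas are geodesic (spherical Earth) in
hectares. The derived complexity indices follow the landscape-ecology
conventions:

* perimeter-to-area ratio  PAR = P / N_pixels
* shape index              SI  = P / p_min(N)  (compact normalization,
  p_min = perimeter of the maximally compact arrangement of N cells), or
  the literal formula 0.25 * P / sqrt(N) as an alternative variant
* fractal correlation dimension  D2 = 2 ln(P/4) / ln(N)
* core area index          CA  = A_core / A
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .patches import FirePatch
from .raster_io import BurnDateRaster

EARTH_RADIUS_KM = 6371.0

SI_VARIANTS = ("compact_min_perimeter", "sqrt_formula")

#: trait CSV column order (catalogue layout); SDE fields follow the
#: scalar fields, dates close the record.
TRAIT_COLUMNS = [
    "patch_id",
    "n_pixels",
    "n_core_pixels",
    "area_ha",
    "core_area_ha",
    "perimeter",
    "par",
    "si",
    "d2",
    "ca",
    "x_deg",
    "y_deg",
    "sigma_x_deg",
    "sigma_y_deg",
    "theta_deg",
    "sigma_x_km",
    "sigma_y_km",
    "theta_km_deg",
    "r_sde",
    "e_sde",
    "bd_min",
    "bd_max",
    "bd_mean",
    "year",
]


def perimeter(patch: FirePatch) -> int:
    """Patch perimeter in pixel sides.

    Counts unit cell edges adjacent to exactly one patch pixel, so both the
    outer boundary and any interior hole boundaries contribute.
    """
    mask, _ = patch.mask()
    n = int(mask.sum())
    horiz = int((mask[:, 1:] & mask[:, :-1]).sum())
    vert = int((mask[1:, :] & mask[:-1, :]).sum())
    return 4 * n - 2 * (horiz + vert)


def core_pixels(patch: FirePatch, neighbourhood: int = 8) -> int:
    """Number of core pixels: patch pixels totally surrounded by the patch.

    A core pixel has all its neighbours (8 by default; 4 with
    ``neighbourhood=4``) inside the patch footprint.
    """
    if neighbourhood not in (4, 8):
        raise ValueError("neighbourhood must be 4 or 8")
    mask, _ = patch.mask()
    structure = (
        np.ones((3, 3), dtype=bool)
        if neighbourhood == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    core = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return int(core.sum())


def pixel_area_ha(lat_deg, pixel_size_deg: float) -> np.ndarray:
    """Geodesic area (ha) of a square angular pixel centred at ``lat_deg``.

    Exact spherical quadrangle area on a sphere of radius 6371 km:
    R^2 * dlon * (sin(lat_n) - sin(lat_s)), converted to hectares.
    """
    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    half = np.deg2rad(pixel_size_deg) / 2.0
    dlon = np.deg2rad(pixel_size_deg)
    area_km2 = EARTH_RADIUS_KM**2 * dlon * (np.sin(lat + half) - np.sin(lat - half))
    return area_km2 * 100.0  # 1 km^2 = 100 ha


def areas(patch: FirePatch, raster: BurnDateRaster,
          neighbourhood: int = 8) -> tuple[float, float]:
    """(A, A_core) in hectares, summing per-pixel geodesic areas.

    Each pixel contributes the spherical area of its own cell, so A varies
    with latitude (~cos(lat)) for a fixed angular pixel size.
    """
    _, lats = raster.pixel_center(patch.rows, patch.cols)
    per_pixel = pixel_area_ha(lats, raster.pixel_size_deg)
    total = float(per_pixel.sum())
    mask, (r0, c0) = patch.mask()
    structure = (
        np.ones((3, 3), dtype=bool)
        if neighbourhood == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    core = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    is_core = core[patch.rows - r0, patch.cols - c0]
    return total, float(per_pixel[is_core].sum())


def min_compact_perimeter(n_pixels: int) -> int:
    """Perimeter of the maximally compact arrangement of ``n_pixels`` cells.

    With n = floor(sqrt(N)): 4n for a perfect square, 4n + 2 while the
    extra cells still fit along one side (N <= n(n+1)), else 4n + 4.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    n = math.isqrt(n_pixels)
    if n_pixels == n * n:
        return 4 * n
    if n_pixels <= n * (n + 1):
        return 4 * n + 2
    return 4 * n + 4


def shape_index(p: float, n_pixels: int,
                variant: str = "compact_min_perimeter") -> float:
    """Shape index: 1 for a maximally compact patch, larger = more complex.

    ``compact_min_perimeter`` (default) normalizes the perimeter by the
    minimum perimeter achievable with the same cell count; this is the
    convention of the classical landscape-metrics packages and matches
    published patch catalogues. ``sqrt_formula`` is the literal
    0.25 * P / sqrt(N) form, which only agrees when N is a perfect square.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    if variant == "compact_min_perimeter":
        return p / min_compact_perimeter(n_pixels)
    if variant == "sqrt_formula":
        return 0.25 * p / math.sqrt(n_pixels)
    raise ValueError(
        f"unknown shape-index variant {variant!r}; expected one of {SI_VARIANTS}"
    )


def fractal_dimension(p: float, n_pixels: int) -> float:
    """Fractal correlation dimension D2 = 2 ln(P/4) / ln(N).

    Ranges from 1 (smooth boundary) to 2 (highly convoluted) for patches
    of at least a few pixels; undefined for singletons (returns NaN).
    """
    if n_pixels <= 1:
        return float("nan")
    if p < 4:
        raise ValueError("perimeter must be >= 4 pixel sides")
    return 2.0 * math.log(0.25 * p) / math.log(n_pixels)


def year_of_mean_date(mean_day: float, year: int) -> int:
    """Calendar year containing a (possibly fractional) day-of-year.

    Days beyond the year length (multi-year axes) roll forward.
    """
    import calendar

    y = year
    day = mean_day
    while day > (366 if calendar.isleap(y) else 365):
        day -= 366 if calendar.isleap(y) else 365
        y += 1
    return y


def scalar_traits(patch: FirePatch, raster: BurnDateRaster,
                  si_variant: str = "compact_min_perimeter",
                  core_neighbourhood: int = 8) -> dict:
    """All non-ellipse traits of one patch as a dict keyed by CSV column."""
    n = patch.n_pixels
    p = perimeter(patch)
    n_core = core_pixels(patch, neighbourhood=core_neighbourhood)
    a, a_core = areas(patch, raster, neighbourhood=core_neighbourhood)
    lons, lats = raster.pixel_center(patch.rows, patch.cols)
    mean_day = float(np.mean(patch.dates))
    return {
        "patch_id": patch.patch_id,
        "n_pixels": n,
        "n_core_pixels": n_core,
        "area_ha": a,
        "core_area_ha": a_core,
        "perimeter": p,
        "par": p / n,
        "si": shape_index(p, n, variant=si_variant),
        "d2": fractal_dimension(p, n),
        "ca": a_core / a if a > 0 else float("nan"),
        "x_deg": float(np.mean(lons)),
        "y_deg": float(np.mean(lats)),
        "bd_min": int(patch.dates.min()),
        "bd_max": int(patch.dates.max()),
        "bd_mean": round(mean_day, 2),
        "year": year_of_mean_date(mean_day, raster.year),
    }
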