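"""Burn-date raster container, GeoTIFF I/O and the overlapping tile scheme.

Rasters live on a regular geographic (lat/lon) grid. Pixel values are
integer day-of-burn (day of year, or day on any consistent axis), with 0
meaning unburned and negative values meaning unmapped/no-data. Row 0 is the
northernmost row; pixel (row, col) are 0-based.

GeoTIFF georeferencing is carried by the standard ModelPixelScale,
ModelTiepoint and GeoKeyDirectory tags (read and written through tifffile),
restricted to geographic CRSs — projected rasters must be reprojected
upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

UNBURNED = 0
UNMAPPED = -1

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKey ids
_GT_MODEL_TYPE = 1024  # 1 = projected, 2 = geographic
_GT_RASTER_TYPE = 1025  # 1 = PixelIsArea
_GEOGRAPHIC_TYPE = 2048  # 4326 = WGS84


@dataclass
class BurnDateRaster:
    """A georeferenced grid of integer burn dates.

    Parameters
    ----------
    values
        2-D integer array; 0 = unburned, negative = unmapped.
    origin
        (lon, lat) of the *outer corner* of pixel (0, 0), i.e. the
        north-west corner of the raster.
    pixel_size_deg
        Angular pixel size in degrees (square pixels).
    year
        Calendar year the date axis refers to (day 1 = 1 January).
    months
        Inclusive (first, last) month span covered by the raster.
    """

    values: np.ndarray
    origin: tuple[float, float]
    pixel_size_deg: float
    year: int = 2000
    months: tuple[int, int] = (1, 12)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise TypeError("burn dates must be integers")
        if self.pixel_size_deg <= 0:
            raise ValueError("pixel_size_deg must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer bounds in degrees."""
        rows, cols = self.values.shape
        west, north = self.origin
        return (
            west,
            north - rows * self.pixel_size_deg,
            west + cols * self.pixel_size_deg,
            north,
        )

    def pixel_center(self, row, col):
        """Longitude/latitude of pixel centers (vectorized)."""
        west, north = self.origin
        lon = west + (np.asarray(col) + 0.5) * self.pixel_size_deg
        lat = north - (np.asarray(row) + 0.5) * self.pixel_size_deg
        return lon, lat

    @property
    def burned_mask(self) -> np.ndarray:
        return self.values > 0

    def crop(self, extent: tuple[float, float, float, float]) -> "BurnDateRaster":
        """Sub-raster covering ``extent`` = (west, south, east, north).

        The crop is aligned to the pixel grid and clipped at the raster
        edge; pixels whose *any* part falls in the extent are included.
        """
        west, south, east, north = extent
        w0, s0, e0, n0 = self.bounds
        ps = self.pixel_size_deg
        rows, cols = self.values.shape
        c_lo = max(0, int(np.floor((west - w0) / ps)))
        c_hi = min(cols, int(np.ceil((east - w0) / ps)))
        r_lo = max(0, int(np.floor((n0 - north) / ps)))
        r_hi = min(rows, int(np.ceil((n0 - south) / ps)))
        if c_lo >= c_hi or r_lo >= r_hi:
            raise ValueError("crop extent does not intersect the raster")
        return BurnDateRaster(
            values=self.values[r_lo:r_hi, c_lo:c_hi].copy(),
            origin=(w0 + c_lo * ps, n0 - r_lo * ps),
            pixel_size_deg=ps,
            year=self.year,
            months=self.months,
        )


def write_burndate(raster: BurnDateRaster, path) -> None:
    """Write a burn-date raster as a single-band int GeoTIFF (WGS84)."""
    ps = raster.pixel_size_deg
    west, north = raster.origin
    values = raster.values
    dtype = np.int16 if values.max(initial=0) < 2**15 else np.int32
    geokeys = (
        1, 1, 0, 3,
        _GT_MODEL_TYPE, 0, 1, 2,
        _GT_RASTER_TYPE, 0, 1, 1,
        _GEOGRAPHIC_TYPE, 0, 1, 4326,
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (ps, ps, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, west, north, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_GDAL_NODATA, "s", 0, str(UNMAPPED)),
    ]
    tifffile.imwrite(
        path,
        values.astype(dtype),
        extratags=extratags,
        metadata=None,
        description=f"burn dates year={raster.year} months={raster.months[0]}-{raster.months[1]}",
    )


def read_burndate(path, year: int | None = None,
                  months: tuple[int, int] | None = None) -> BurnDateRaster:
    """Read a single-band integer GeoTIFF of burn dates.

    No-data pixels (per the GDAL nodata tag) are mapped to the unmapped
    code. Projected rasters are rejected; reproject to lat/lon first.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: expected a single-band, single-page GeoTIFF")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: multi-band rasters are not supported")
        values = page.asarray()
        if not np.issubdtype(values.dtype, np.integer):
            raise TypeError(f"{path}: burn dates must be an integer band")
        tags = page.tags
        if _GEO_KEY_DIRECTORY in tags:
            gkd = tags[_GEO_KEY_DIRECTORY].value
            keys = {gkd[i]: gkd[i + 3] for i in range(4, len(gkd), 4)}
            if keys.get(_GT_MODEL_TYPE, 2) != 2:
                raise ValueError(
                    f"{path}: projected CRS detected; reproject to a "
                    "geographic (lat/lon) grid before reading"
                )
        scale = tags[_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_MODEL_TIEPOINT].value
        nodata = None
        if _GDAL_NODATA in tags:
            nodata = int(float(tags[_GDAL_NODATA].value))
    if abs(scale[0] - scale[1]) > 1e-12:
        raise ValueError(f"{path}: non-square pixels are not supported")
    # tiepoint maps raster (i, j) -> model (x, y); require the origin pixel
    i, j, _, x, y, _ = tiepoint
    west = x - j * scale[0]
    north = y + i * scale[1]
    values = values.astype(np.int32)
    if nodata is not None and nodata != UNMAPPED:
        values[values == nodata] = UNMAPPED
    kwargs = {}
    if year is not None:
        kwargs["year"] = year
    if months is not None:
        kwargs["months"] = months
    return BurnDateRaster(values, (west, north), float(scale[0]), **kwargs)


# ---------------------------------------------------------------------------
# Tiling with overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TileScheme:
    """Overlapping tiling used to parallelize patch construction.

    Full tiles of ``tile_size_deg`` overlap their neighbours by
    ``border_deg`` on every side; the central non-overlapping cores of
    ``core_size_deg`` partition the domain. The invariant
    core + 2 * border = tile must hold.
    """

    tile_size_deg: float = 3.5
    border_deg: float = 0.5
    core_size_deg: float = 2.5

    def __post_init__(self) -> None:
        if abs(self.core_size_deg + 2 * self.border_deg - self.tile_size_deg) > 1e-9:
            raise ValueError(
                "invalid tile scheme: core_size_deg + 2*border_deg must "
                f"equal tile_size_deg (got {self.core_size_deg} + "
                f"2*{self.border_deg} != {self.tile_size_deg})"
            )


@dataclass(frozen=True)
class Tile:
    tile_id: int
    full: tuple[float, float, float, float]  # (west, south, east, north)
    core: tuple[float, float, float, float]


def make_tiles(domain_bounds: tuple[float, float, float, float],
               scheme: TileScheme = TileScheme()) -> list[Tile]:
    """Cover a domain with overlapping tiles.

    Cores step by ``core_size_deg`` from the domain's north-west corner and
    partition the domain exactly (the last row/column core is clipped);
    each full extent is its core dilated by ``border_deg`` and clipped to
    the domain.
    """
    west, south, east, north = domain_bounds
    core = scheme.core_size_deg
    border = scheme.border_deg
    if east - west < core - 1e-9 or north - south < core - 1e-9:
        raise ValueError("domain must span at least one tile core")
    n_x = int(np.ceil((east - west) / core - 1e-9))
    n_y = int(np.ceil((north - south) / core - 1e-9))
    tiles = []
    tid = 0
    for iy in range(n_y):
        c_n = north - iy * core
        c_s = max(south, c_n - core)
        for ix in range(n_x):
            c_w = west + ix * core
            c_e = min(east, c_w + core)
            full = (
                max(west, c_w - border),
                max(south, c_s - border),
                min(east, c_e + border),
                min(north, c_n + border),
            )
            tiles.append(Tile(tid, full, (c_w, c_s, c_e, c_n)))
            tid += 1
    return tiles


def assign_patch_to_tile(patch_center: tuple[float, float],
                         tiles: list[Tile]) -> int | None:
    """Tile whose core contains the patch center, or None.

    Cores are half-open [west, east) x [south, north) so a center on a
    shared core boundary is assigned to exactly one tile; this keeps each
    patch exactly once when the same patch is reconstructed in several
    overlapping tiles.
    """
    lon, lat = patch_center
    for tile in tiles:
        w, s, e, n = tile.core
        if w <= lon < e and s <= lat < n:
            return tile.tile_id
    return None


def write_tile_manifest(tiles: list[Tile], path) -> None:
    """One tile per line: id, full bounds, core bounds (space separated)."""
    with open(path, "w") as fh:
        fh.write("# tile_id full_w full_s full_e full_n core_w core_s core_e core_n\n")
        for t in tiles:
            fields = [t.tile_id, *t.full, *t.core]
            fh.write(" ".join(f"{v:g}" if isinstance(v, float) else str(v)
                              for v in fields) + "\n")
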