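"""GeoTIFF round-trips and the overlapping tile scheme."""

import numpy as np
import pytest
import tifffile

from firepatches import (
    BurnDateRaster,
    TileScheme,
    assign_patch_to_tile,
    make_tiles,
    read_burndate,
    write_burndate,
)
from firepatches.raster_io import UNMAPPED, write_tile_manifest

from conftest import make_raster, random_date_raster


def test_geotiff_round_trip(tmp_path):
    raster = random_date_raster(1, shape=(25, 30), day_range=(1, 365))
    path = tmp_path / "burn.tif"
    write_burndate(raster, path)
    back = read_burndate(path, year=raster.year)
    np.testing.assert_array_equal(back.values, raster.values)
    assert back.origin == pytest.approx(raster.origin)
    assert back.pixel_size_deg == pytest.approx(raster.pixel_size_deg)
    assert back.values.max() == raster.values.max()


def test_all_zero_raster(tmp_path):
    raster = make_raster(np.zeros((5, 5)))
    path = tmp_path / "zero.tif"
    write_burndate(raster, path)
    back = read_burndate(path)
    assert back.burned_mask.sum() == 0


def test_nodata_maps_to_unmapped(tmp_path):
    vals = np.array([[10, -1], [0, 20]], dtype=np.int32)
    raster = make_raster(vals)
    path = tmp_path / "nodata.tif"
    write_burndate(raster, path)
    back = read_burndate(path)
    assert back.values[0, 1] == UNMAPPED


def test_projected_crs_rejected(tmp_path):
    path = tmp_path / "utm.tif"
    geokeys = (1, 1, 0, 1, 1024, 0, 1, 1)  # model type 1 = projected
    tifffile.imwrite(
        path,
        np.zeros((4, 4), dtype=np.int16),
        extratags=[
            (33550, "d", 3, (10.0, 10.0, 0.0)),
            (33922, "d", 6, (0, 0, 0, 500000.0, 4000000.0, 0)),
            (34735, "H", len(geokeys), geokeys),
        ],
    )
    with pytest.raises(ValueError, match="reproject"):
        read_burndate(path)


def test_multiband_rejected(tmp_path):
    path = tmp_path / "multi.tif"
    tifffile.imwrite(path, np.zeros((4, 4, 3), dtype=np.int16),
                     photometric="rgb")
    with pytest.raises(ValueError):
        read_burndate(path)


def test_invalid_raster_construction():
    with pytest.raises(ValueError):
        BurnDateRaster(np.zeros((0, 3), dtype=np.int32), (0, 0), 0.01)
    with pytest.raises(ValueError):
        BurnDateRaster(np.zeros((3, 3), dtype=np.int32), (0, 0), -0.01)
    with pytest.raises(TypeError):
        BurnDateRaster(np.zeros((3, 3)), (0, 0), 0.01)


def test_crop_preserves_georeferencing():
    raster = random_date_raster(4, shape=(100, 100))
    sub = raster.crop((0.2, raster.bounds[1] + 0.2, 0.5, raster.bounds[3] - 0.3))
    r0 = round((raster.origin[1] - sub.origin[1]) / raster.pixel_size_deg)
    c0 = round((sub.origin[0] - raster.origin[0]) / raster.pixel_size_deg)
    np.testing.assert_array_equal(
        sub.values, raster.values[r0:r0 + sub.shape[0], c0:c0 + sub.shape[1]]
    )
    lon_sub, lat_sub = sub.pixel_center(0, 0)
    lon_full, lat_full = raster.pixel_center(r0, c0)
    assert lon_sub == pytest.approx(lon_full) and lat_sub == pytest.approx(lat_full)


# --- tiling -----------------------------------------------------------------

def test_tile_scheme_invariant():
    TileScheme()  # 2.5 + 2*0.5 = 3.5 ok
    with pytest.raises(ValueError):
        TileScheme(tile_size_deg=3.5, border_deg=0.5, core_size_deg=3.0)


def test_make_tiles_cores_partition_domain():
    domain = (0.0, 0.0, 7.0, 7.0)
    tiles = make_tiles(domain)
    # ceil(7 / 2.5) = 3 core columns and rows
    assert len(tiles) == 9
    core_area = sum(
        (t.core[2] - t.core[0]) * (t.core[3] - t.core[1]) for t in tiles
    )
    assert core_area == pytest.approx(49.0)
    for t in tiles:
        fw, fs, fe, fn = t.full
        cw, cs, ce, cn = t.core
        assert fw <= cw and fs <= cs and fe >= ce and fn >= cn
        # dilation by the border except where clipped at the domain edge
        assert fw == pytest.approx(max(domain[0], cw - 0.5))
        assert fe == pytest.approx(min(domain[2], ce + 0.5))
    # adjacent cores share no interior point
    for a in tiles:
        for b in tiles:
            if a.tile_id >= b.tile_id:
                continue
            ow = min(a.core[2], b.core[2]) - max(a.core[0], b.core[0])
            oh = min(a.core[3], b.core[3]) - max(a.core[1], b.core[1])
            assert min(ow, oh) <= 1e-12


def test_make_tiles_single_core_domain():
    tiles = make_tiles((0.0, 0.0, 2.5, 2.5))
    assert len(tiles) == 1
    assert tiles[0].core == (0.0, 0.0, 2.5, 2.5)
    with pytest.raises(ValueError):
        make_tiles((0.0, 0.0, 1.0, 1.0))


def test_assign_center_unique_on_shared_boundary():
    tiles = make_tiles((0.0, 0.0, 7.0, 7.0))
    inside = assign_patch_to_tile((1.2, 6.0), tiles)
    assert inside is not None
    # a center exactly on a shared core edge lands in exactly one core
    boundary_assignments = [
        t.tile_id for t in tiles
        if t.core[0] <= 2.5 < t.core[2] and t.core[1] <= 4.0 < t.core[3]
    ]
    assert len(boundary_assignments) == 1
    assert assign_patch_to_tile((2.5, 4.0), tiles) == boundary_assignments[0]
    assert assign_patch_to_tile((-3.0, 4.0), tiles) is None


def test_tile_manifest(tmp_path):
    tiles = make_tiles((0.0, 0.0, 5.0, 5.0))
    path = tmp_path / "tiles.txt"
    write_tile_manifest(tiles, path)
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == len(tiles)
    assert all(len(l.split()) == 9 for l in lines)
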