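import numpy as np
import pytest

from firepatches import BurnDateRaster


def make_raster(values, origin=(0.0, 10.0), pixel_size_deg=0.01, year=2008):
    return BurnDateRaster(
        np.asarray(values, dtype=np.int32), origin, pixel_size_deg, year=year
    )


def random_date_raster(seed, shape=(40, 40), p_burn=0.3, day_range=(1, 60)):
    """Random burn-date grid: Bernoulli burned mask with uniform dates."""
    rng = np.random.default_rng(seed)
    burned = rng.random(shape) < p_burn
    dates = rng.integers(day_range[0], day_range[1] + 1, size=shape)
    return make_raster(np.where(burned, dates, 0))


@pytest.fixture
def small_raster():
    """Two events 2 px apart in space, 10 days apart in time."""
    vals = np.zeros((12, 12), dtype=np.int32)
    vals[2:5, 2:5] = 10
    vals[2:5, 7:10] = 20
    vals[3, 5] = 11  # bridge pixel adjacent to the first block
    return make_raster(vals)
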