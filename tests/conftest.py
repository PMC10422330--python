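import numpy as np
import pytest

from reef3d.raster_io import FLOAT_NODATA, GridTransform, Raster
from reef3d.synthetic import SceneParams, generate_scene


@pytest.fixture
def transform():
    return GridTransform(10.0, 20.0, 0.001)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_height(data, transform=None, nodata=FLOAT_NODATA):
    transform = transform or GridTransform(0.0, data.shape[0] * 0.001, 0.001)
    return Raster(data=np.asarray(data, dtype=np.float64),
                  transform=transform, nodata=nodata, band_meaning="height")


def make_scalar(data, transform=None, nodata=FLOAT_NODATA):
    transform = transform or GridTransform(0.0, data.shape[0] * 0.001, 0.001)
    return Raster(data=np.asarray(data, dtype=np.float64),
                  transform=transform, nodata=nodata, band_meaning="scalar")


def make_label(data, transform=None):
    data = np.asarray(data, dtype=np.uint8)
    transform = transform or GridTransform(0.0, data.shape[0] * 0.001, 0.001)
    return Raster(data=data, transform=transform, nodata=255.0,
                  band_meaning="label")


@pytest.fixture(scope="session")
def small_scene():
    """A 192x192 scene with 4 colonies, shared across read-only tests."""
    params = SceneParams(extent_px=(192, 192), n_colonies=4,
                         colony_radius_range=(0.015, 0.03),
                         colony_height_range=(0.03, 0.06),
                         dead_fraction=0.25, seed=42)
    return generate_scene(params)
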