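import numpy as np
import pytest

from vinesense.containers import GeoTransform, SpectralCube
from vinesense.synthetic import (
    VineyardConfig,
    generate_layout,
    generate_point_cloud,
    generate_reflectance_cube,
    generate_terrain,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small block that keeps point-cloud and cube stages fast."""
    return VineyardConfig(seed=3, n_rows=3, vines_per_row=8)


@pytest.fixture(scope="session")
def scene():
    """One fully generated small vineyard shared by read-only tests."""
    config = VineyardConfig(seed=11, n_rows=3, vines_per_row=10)
    terrain = generate_terrain(config)
    truth = generate_layout(config)
    cloud, truth = generate_point_cloud(config, terrain, truth)
    cube, truth = generate_reflectance_cube(config, truth)
    return {"config": config, "terrain": terrain, "truth": truth,
            "cloud": cloud, "cube": cube}


def random_cube(rng, shape=(4, 4, 6), kind="reflectance"):
    rows, cols, bands = shape
    return SpectralCube(
        values=rng.uniform(0.01, 1.0, shape),
        wavelengths=np.linspace(400, 1000, bands),
        transform=GeoTransform(300000.0, 6000000.0, 0.5),
        kind=kind,
    )
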