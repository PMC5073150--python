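import numpy as np
import pytest

from shrubmap.raster import RasterGrid
from shrubmap.synthetic_scene import SceneConfig, generate_scene, generate_truth


def small_scene_config(seed: int = 1, **overrides) -> SceneConfig:
    """A quick-to-generate scene that still exercises every stage."""
    defaults = dict(
        extent_m=(200.0, 200.0),
        presence_plots_per_stratum=12,
        absence_plots_per_stratum=24,
        seed=seed,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


@pytest.fixture(scope="session")
def scene():
    """One shared small synthetic scene (truth, cloud, cube, plots)."""
    return generate_scene(small_scene_config(seed=1))


@pytest.fixture(scope="session")
def truth():
    return generate_truth(small_scene_config(seed=2))


@pytest.fixture
def flat_dem():
    return RasterGrid(np.full((40, 40), 50.0), (0.0, 40.0), 1.0)


def make_plane(nrow=21, ncol=21, sx=0.0, sy=0.0, cell=1.0, z0=10.0):
    """DEM of the plane z = z0 + sx*x + sy*y (y pointing north)."""
    x = (np.arange(ncol) + 0.5) * cell
    y = (nrow - np.arange(nrow)[:, None] - 0.5) * cell
    return RasterGrid(z0 + sx * x + sy * y, (0.0, nrow * cell), cell)
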