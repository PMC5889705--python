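import numpy as np
import pytest

from pinyonmap.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """A reduced scene for unit tests: same structure, fewer cells and samples."""
    return SceneConfig(grid_rows=96, grid_cols=96, samples_per_class=60, seed=7)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def flat_dem():
    from pinyonmap.grid import Grid

    return Grid(values=np.full((8, 8), 500.0), cell_size=10.0)


def make_plane(rows=9, cols=9, dzdx=0.0, dzdy_north=0.0, cell=10.0, base=100.0):
    """DEM of a plane: dzdx metres rise per metre east, dzdy_north per metre north.

    Rows increase southward, so a plane rising northward falls with row index.
    """
    from pinyonmap.grid import Grid

    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    z = base + dzdx * cc * cell - dzdy_north * rr * cell
    return Grid(values=z, cell_size=cell)
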