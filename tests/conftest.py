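import numpy as np
import pytest
from hypothesis import settings

from coastveg import LandscapeSpec, generate_scene
from coastveg.grids import GridGeometry, RasterGrid

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


def make_grid(values, cell_size=200.0, mask=None, crs="EPSG:32650"):
    """A RasterGrid on a simple origin-at-zero geometry, for unit tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    rows, cols = values.shape
    geom = GridGeometry(
        rows=rows,
        cols=cols,
        cell_size=cell_size,
        x_origin=0.0,
        y_origin=rows * cell_size,
        crs=crs,
    )
    return RasterGrid(values, geom, mask)


@pytest.fixture(scope="session")
def small_scene():
    """One fixed 64×128 summer scene with ground truth (seed 42)."""
    spec = LandscapeSpec(rows=64, cols=128, cell_size=200.0, seed=42, date="2020.06")
    scene, truth = generate_scene(spec)
    return spec, scene, truth
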