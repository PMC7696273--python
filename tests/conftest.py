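import numpy as np
import pytest

from resifc.grids import GridSpec
from resifc import synthetic as syn


def make_grid(shape=(10, 10, 10), voxel=3.0, tr=2.0, origin=None) -> GridSpec:
    affine = np.diag([voxel, voxel, voxel, 1.0])
    if origin is None:
        origin = tuple(-voxel * (s - 1) / 2.0 for s in shape)
    affine[:3, 3] = origin
    return GridSpec(shape=shape, affine=affine, tr=tr)


@pytest.fixture
def small_grid() -> GridSpec:
    return make_grid()


@pytest.fixture
def subject() -> syn.Subject:
    return syn.Subject("ms001", "MS", 0.1)


def make_plant(grid: GridSpec, **overrides) -> syn.PlantSpec:
    """Seed block on one side of the grid, target block on the other.

    Regions sit mid-grid so they stay clear of the corner CSF/WM masks
    (whose mean signals become nuisance regressors).
    """
    seed = np.zeros(grid.shape, dtype=bool)
    target = np.zeros(grid.shape, dtype=bool)
    nx, ny, nz = grid.shape
    mid_y = slice(ny // 2 - 1, ny // 2 + 2)
    mid_z = slice(nz // 2 - 1, nz // 2 + 2)
    seed[:2, mid_y, mid_z] = True
    target[-2:, mid_y, mid_z] = True
    defaults = dict(seed_region=seed, target_region=target)
    defaults.update(overrides)
    return syn.PlantSpec(**defaults)
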