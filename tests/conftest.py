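import numpy as np
import pytest

from slpattern import CohortSpec, VolumeGrid, generate_cohort
from slpattern.synthetic_cohort import Blob, EffectSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def iso_grid():
    """10^3 all-true grid at 1.5 mm isotropic spacing."""
    return VolumeGrid((10, 10, 10), 1.5)


def interior_grid(n_grid, margin, voxel_size=1.5):
    grid = VolumeGrid((n_grid,) * 3, voxel_size)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[margin:-margin, margin:-margin, margin:-margin] = True
    return grid.with_mask(mask)


@pytest.fixture
def tiny_cohort():
    """Small null cohort (no effect), cheap enough for unit tests."""
    grid = interior_grid(10, 2)
    spec = CohortSpec(n1=6, n2=6, grid=grid, seed=7)
    spec.group1_moments.n_males = 3
    spec.group2_moments.n_males = 3
    return generate_cohort(spec)


@pytest.fixture
def blob_cohort():
    """Cohort with one strong central blob on a small masked grid."""
    grid = interior_grid(12, 2)
    blob = Blob((6, 6, 6), 4.5, 3.0)
    spec = CohortSpec(n1=7, n2=7, grid=grid, effect=EffectSpec([blob]), seed=11)
    spec.group1_moments.n_males = 3
    spec.group2_moments.n_males = 3
    return generate_cohort(spec), blob
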