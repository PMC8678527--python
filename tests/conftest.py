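import numpy as np
import pytest

from rinan.containers import BoldRun, MaskIndex, SpatialMap, VolumeGrid
from rinan.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Noiseless 2-source cohort, one subject per group."""
    cfg = SimulationConfig(grid_dims=(10, 10, 10), n_time=80, n_sources=2,
                           noise_sd=0.0, n_subjects_per_group=1, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def eight_source_cohort():
    """Noisy 8-source cohort used by decomposition and splitting tests."""
    cfg = SimulationConfig(grid_dims=(10, 10, 10), n_time=150, n_sources=8,
                           noise_sd=0.2, n_subjects_per_group=5, seed=11)
    return generate_cohort(cfg)


@pytest.fixture
def full_mask():
    grid = VolumeGrid((4, 4, 4))
    return MaskIndex(np.ones((4, 4, 4), dtype=bool)), grid


@pytest.fixture
def random_run(full_mask):
    idx, grid = full_mask
    rng = np.random.default_rng(5)
    return BoldRun(rng.standard_normal((30, idx.n_voxels)), idx, grid,
                   subject_id="sub-000")


@pytest.fixture
def random_zmap(full_mask):
    idx, grid = full_mask
    rng = np.random.default_rng(6)
    v = rng.standard_normal(idx.n_voxels)
    return SpatialMap((v - v.mean()) / v.std(), idx, grid, label="net")
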