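import numpy as np
import pytest

from petrad.grids import VolumeGrid
from petrad.synthcohort import GeneratorConfig, make_brain_mask


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    """A small cohort configuration for fast end-to-end tests."""
    return GeneratorConfig(
        grid_shape=(20, 24, 18),
        voxel_size_mm=(8.0, 8.0, 8.0),
        n_controls=16,
        n_patients_by_subtype={"AD": 8, "FTD": 8},
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_mask(tiny_config):
    return make_brain_mask(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_volume(rng):
    """A positive random volume on a small grid with an ellipsoidal mask."""
    cfg = GeneratorConfig(grid_shape=(16, 16, 16), voxel_size_mm=(2.0, 2.0, 2.0))
    mask = make_brain_mask(cfg)
    data = np.abs(rng.normal(1.0, 0.25, cfg.grid_shape)) + 0.1
    return VolumeGrid(data, cfg.voxel_size_mm), mask
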