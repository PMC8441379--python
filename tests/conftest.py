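import numpy as np
import pytest

from phenorhythm.cloud import PointCloud
from phenorhythm.synth import LeafSpec, PlantSpec, random_plant_spec, sample_leaf, sample_plant


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def flat_leaf_spec():
    """Horizontal leaf, no droop: all surface z equals the attach height."""
    return LeafSpec(
        length=0.5, max_width=0.1, attach_height=1.0, inclination_deg=0.0,
        azimuth_deg=0.0, droop=0.0,
    )


@pytest.fixture(scope="session")
def plateau_plant_spec():
    rng = np.random.default_rng(7)
    return random_plant_spec(rng, n_leaves=8)


@pytest.fixture(scope="session")
def plateau_plant_cloud(plateau_plant_spec):
    return sample_plant(plateau_plant_spec, density=5e4, noise_sd=0.0, seed=3)


@pytest.fixture
def rectangle_leaf_cloud():
    """Dense flat rectangle 0.5 m x 0.1 m at z = 0, long side along +y."""
    rng = np.random.default_rng(0)
    n = 20000
    xyz = np.column_stack([
        rng.uniform(-0.05, 0.05, n), rng.uniform(0.0, 0.5, n), np.zeros(n),
    ])
    return PointCloud(xyz, labels=np.ones(n, dtype=np.int64))
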