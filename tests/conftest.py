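import numpy as np
import pytest

from stalkfield.pointcloud_io import PointCloud
from stalkfield.synth_field import FieldSpec, generate_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    """A labeled random cloud spanning a few meters."""
    n = 500
    xyz = rng.uniform([-2.0, -3.0, 0.0], [4.0, 2.0, 1.5], size=(n, 3))
    labels = rng.integers(0, 5, size=n)
    return PointCloud(xyz, labels)


@pytest.fixture(scope="session")
def tiny_field():
    """A small labeled field (8 plants) used by slicing/pipeline tests."""
    spec = FieldSpec(n_rows=2, n_cols=4, n_plants=8,
                     height_range=(0.3, 0.55), rng_seed=7)
    cloud, truths = generate_field(spec)
    return spec, cloud, truths
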