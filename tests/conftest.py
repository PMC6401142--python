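import numpy as np
import pytest

from neuralwaves.connectome import (
    SpatialNetwork,
    exponential_network,
    sample_bilateral_positions,
)


@pytest.fixture(scope="session")
def cloud_small():
    """200-node bilateral point cloud."""
    return sample_bilateral_positions(100, seed=11)


@pytest.fixture(scope="session")
def cloud_dense():
    """1000-node bilateral point cloud for velocity-accuracy checks."""
    return sample_bilateral_positions(500, seed=23)


@pytest.fixture(scope="session")
def expnet_small(cloud_small):
    return exponential_network(cloud_small, seed=5)


@pytest.fixture(scope="session")
def cloud_box():
    """800 nodes filling a box with no midline void (for flow geometry)."""
    rng = np.random.default_rng(31)
    return rng.uniform(-1.0, 1.0, (800, 3)) * np.array([70.0, 65.0, 45.0])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_net():
    """Hand-built 4-node network with simple weights."""
    pos = np.array([[-20.0, 0, 0], [-10.0, 5, 0], [10.0, -5, 0], [20.0, 0, 5]])
    w = np.array(
        [
            [0.0, 2.0, 1.0, 0.5],
            [2.0, 0.0, 1.5, 1.0],
            [1.0, 1.5, 0.0, 2.5],
            [0.5, 1.0, 2.5, 0.0],
        ]
    )
    return SpatialNetwork(pos, w)
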