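import numpy as np
import pytest

from drwpicp import PointCloud
from drwpicp.synthdata import random_rigid_transform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    return PointCloud(points=rng.uniform(-10, 10, size=(200, 3)))


def random_transform(seed, max_angle=np.pi, max_translation=10.0):
    return random_rigid_transform(np.random.default_rng(seed),
                                  max_angle, max_translation)


@pytest.fixture
def make_transform():
    return random_transform
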