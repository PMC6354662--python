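import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from airseg import Mask, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    data = rng.integers(-1200, 900, size=(12, 14, 10)).astype(np.int32)
    return Volume(data, spacing=(0.4, 0.5, 0.6), origin=(-3.0, 1.5, 2.0))


def make_shell_volume(
    cavity=(slice(4, 9), slice(4, 9), slice(4, 9)),
    shape=(13, 13, 13),
    wall_level=300,
    air_level=-1000,
    spacing=(1.0, 1.0, 1.0),
    pinhole=None,
):
    """Cubic air cavity enclosed in a one-voxel wall, floating in outer air.

    Wall spans the faces around the cavity slices; ``pinhole`` (index triple)
    punches a one-voxel air hole through the wall.
    """
    data = np.full(shape, air_level, dtype=np.int32)
    wall = tuple(slice(s.start - 1, s.stop + 1) for s in cavity)
    data[wall] = wall_level
    data[cavity] = air_level
    if pinhole is not None:
        data[pinhole] = air_level
    return Volume(data, spacing=spacing)


@pytest.fixture
def shell_volume():
    return make_shell_volume()


@pytest.fixture
def two_chamber_mask():
    """Two 3x3x3 air chambers joined by a 1-voxel-wide channel."""
    data = np.zeros((15, 7, 7), dtype=bool)
    data[2:5, 2:5, 2:5] = True
    data[10:13, 2:5, 2:5] = True
    data[5:10, 3, 3] = True  # channel along x at y=z=3
    return Mask(data, spacing=(1.0, 1.0, 1.0))
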