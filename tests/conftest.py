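import numpy as np
import pytest

from lidarhar.world import RoomMap, build_room


@pytest.fixture(scope="session")
def empty_room() -> RoomMap:
    return build_room(6.0, 6.0, 0.1, 0, seed=0)


@pytest.fixture(scope="session")
def obstacle_room() -> RoomMap:
    return build_room(6.0, 6.0, 0.1, 3, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
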