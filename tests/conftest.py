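import numpy as np
import pytest

from silpose.data import (PoseSamplingRanges, default_intrinsics, make_cube,
                          toy_instrument, _sample_one_pose)
from silpose.geometry import CameraIntrinsics, Pose, farthest_point_sampling


@pytest.fixture(scope="session")
def cube():
    return make_cube()


@pytest.fixture(scope="session")
def hook():
    return toy_instrument("hook")


@pytest.fixture(scope="session")
def small_camera():
    """160x120 camera: fast rasterization in unit tests."""
    return CameraIntrinsics(100.0, 100.0, 80.0, 60.0, 160, 120)


@pytest.fixture(scope="session")
def camera_640():
    return default_intrinsics()


@pytest.fixture(scope="session")
def cube_keypoints(cube):
    return farthest_point_sampling(cube, 8)


def random_pose(seed, depth=(3.0, 8.0)) -> Pose:
    rng = np.random.default_rng(seed)
    return _sample_one_pose(PoseSamplingRanges(depth=depth), rng)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
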