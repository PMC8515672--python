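import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import jawtrack as jt


def random_pose(rng: np.random.Generator, max_angle_deg: float = 180.0,
                max_shift_mm: float = 5.0) -> jt.RigidPose:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle_deg, max_angle_deg)
    R = Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
    return jt.RigidPose(R, rng.uniform(-max_shift_mm, max_shift_mm, 3))


@pytest.fixture(scope="session")
def default_truth():
    """Ground-truth chewing motion at the default study conditions."""
    return jt.simulate_jaw_motion(jt.MotionSpec())


@pytest.fixture(scope="session")
def short_truth():
    """Three-cycle motion for cheaper end-to-end checks."""
    return jt.simulate_jaw_motion(jt.MotionSpec(n_cycles=3))


@pytest.fixture(scope="session")
def dentition():
    """Toy dentition at a coarse tessellation (feature geometry is exact)."""
    return jt.synth_dentition(resolution=0.8)


@pytest.fixture(scope="session")
def model(dentition):
    mandible, maxilla, landmarks = dentition
    return jt.AnatomicalModel(mandible, maxilla, jt.DEFAULT_MARKERS,
                              landmarks)
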