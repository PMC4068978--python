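import numpy as np
import pytest

import casttrack as ct
from casttrack.synthetic import arch_frame_for_tooth


@pytest.fixture(scope="session")
def default_arch() -> ct.LabeledScan:
    return ct.generate_arch(ct.ArchSpec(seed=1))


@pytest.fixture(scope="session")
def small_arch() -> ct.LabeledScan:
    """Cheap arch for registration-heavy tests."""
    return ct.generate_arch(ct.ArchSpec(points_per_tooth=150, seed=2))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_rigid(rng, max_angle_deg=60.0, max_shift=10.0) -> ct.RigidTransform:
    """A random proper rigid motion with bounded rotation angle."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return ct.RigidTransform(R, rng.uniform(-max_shift, max_shift, 3))


def frame_for(scan, tooth_id, exclude=()):
    return arch_frame_for_tooth(scan, tooth_id, exclude=exclude)
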