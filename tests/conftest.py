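import numpy as np
import pytest

from planereg.geometry import PlaneTriplet, RigidTransform, StandardPlane
from planereg.phantom import canonical_triplet, sample_pose


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via random axis and angle."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, np.pi)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def random_plane(rng: np.random.Generator, name: str = "axial") -> StandardPlane:
    R = random_rotation(rng)
    center = rng.uniform(-50, 50, size=3)
    return StandardPlane(name=name, center=center, e_u=R[:, 0], e_v=R[:, 1])


def random_triplet(rng: np.random.Generator, region: str = "ankle") -> PlaneTriplet:
    """Canonical triplet under a random rigid pose (geometry stays consistent)."""
    pose = sample_pose(rng, max_angle_deg=180.0, max_translation_mm=40.0)
    from planereg.geometry import apply_rigid_to_triplet

    return apply_rigid_to_triplet(canonical_triplet(region), pose)


@pytest.fixture
def make_rotation(rng):
    return lambda: random_rotation(rng)


@pytest.fixture
def make_plane(rng):
    return lambda name="axial": random_plane(rng, name)


@pytest.fixture
def make_triplet(rng):
    return lambda region="ankle": random_triplet(rng, region)
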