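import numpy as np
import pytest

from rootalign.io_formats import Box3D
from rootalign.phantom import PhantomSpec, make_phantom


def random_invertible_affine(rng: np.random.Generator) -> np.ndarray:
    """Random well-conditioned affine; about half have negative determinant."""
    while True:
        linear = rng.uniform(-2.0, 2.0, size=(3, 3))
        det = np.linalg.det(linear)
        if abs(det) > 0.1:
            affine = np.eye(4)
            affine[:3, :3] = linear
            affine[:3, 3] = rng.uniform(-50.0, 50.0, size=3)
            return affine


def random_monomial_affine(rng: np.random.Generator) -> np.ndarray:
    """Random axis-aligned affine: per-axis scale, random flips and permutation.

    This is the NIfTI-realistic family (LPS/RAS flips, anisotropic spacing)
    under which axis-aligned boxes transform to axis-aligned boxes, so corner
    round trips are exact.
    """
    scales = rng.uniform(0.3, 3.0, size=3) * rng.choice([-1.0, 1.0], size=3)
    perm = rng.permutation(3)
    affine = np.zeros((4, 4))
    affine[3, 3] = 1.0
    for row, axis in enumerate(perm):
        affine[row, axis] = scales[row]
    affine[:3, 3] = rng.uniform(-50.0, 50.0, size=3)
    return affine


def random_int_box(rng: np.random.Generator, grid: int) -> Box3D:
    lo = rng.integers(0, grid - 1, size=3)
    hi = np.array([rng.integers(l + 1, grid + 1) for l in lo])
    return Box3D(lo=lo.astype(float), hi=hi.astype(float), space="voxel")


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small, fast phantom at 50 degrees with no noise."""
    spec = PhantomSpec(
        shape=(96, 96, 96),
        tube_angle_deg=50.0,
        tube_radius_mm=8.0,
        tube_length_mm=64.0,
        noise_sd_hu=0.0,
        seed=11,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(tube_angle_deg=45.0, noise_sd_hu=30.0, seed=5)
    return make_phantom(spec)
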