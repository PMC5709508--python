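import numpy as np
import pytest

from rhizohair import (GrowthConfig, PhaseVolume, cartesian_face,
                       extract_surface, generate_three_phase_soil,
                       uniform_volume)
from rhizohair.geometry import MINERAL, PORE, TEXTURAL


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def empty_volume():
    """All-pore cube, 800 µm edge, 8 µm voxels."""
    return uniform_volume(800, 8)


@pytest.fixture(scope="session")
def empty_face_surface(empty_volume):
    return extract_surface(empty_volume, cartesian_face(0, "low"))


@pytest.fixture(scope="session")
def three_phase_volume():
    """Small three-phase soil cube used across growth/morphometric tests."""
    return generate_three_phase_soil((0.35, 0.325, 0.325), 800, 8,
                                     correlation_length=100, rng_seed=7)


@pytest.fixture
def default_config():
    return GrowthConfig()


def brute_force_components(mask):
    """Independent 26-connectivity component scan (BFS, pure python)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
            for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            p = stack.pop()
            comp.append(p)
            for o in offs:
                q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
                if all(0 <= q[d] < mask.shape[d] for d in range(3)) \
                        and mask[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        comps.append(comp)
    return comps


def make_sphere_volume(diameter_um, voxel_size, pad_um=20.0, label=MINERAL):
    """A single voxelised sphere centred in a PORE cube."""
    edge = diameter_um + 2 * pad_um
    n = int(round(edge / voxel_size))
    ax = (np.arange(n) - (n - 1) / 2) * voxel_size
    d2 = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
          + ax[None, None, :] ** 2)
    labels = np.where(d2 <= (diameter_um / 2) ** 2, label, PORE).astype(np.uint8)
    return PhaseVolume(labels, voxel_size)
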