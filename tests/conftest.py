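import numpy as np
import pytest

from contoureval.grids import BinaryMask, Geometry


@pytest.fixture
def geom_iso():
    """Small isotropic 1 mm lattice."""
    return Geometry((12, 12, 12), (1.0, 1.0, 1.0))


@pytest.fixture
def geom_aniso():
    """Anisotropic lattice with 5 mm slices, as in pelvic planning CT."""
    return Geometry((16, 16, 8), (2.0, 2.0, 5.0))


def random_mask(geom: Geometry, rng: np.random.Generator, p: float = 0.25) -> BinaryMask:
    """A random non-empty blob-ish mask (random field smoothed by majority)."""
    vox = rng.random(geom.shape) < p
    if not vox.any():
        vox[tuple(d // 2 for d in geom.shape)] = True
    return BinaryMask(geom, vox)


def sphere_mask(geom: Geometry, center, radius_mm: float) -> BinaryMask:
    idx = np.indices(geom.shape).reshape(3, -1).T
    pts = geom.indices_to_physical(idx)
    inside = ((pts - np.asarray(center)) ** 2).sum(axis=1) <= radius_mm**2
    return BinaryMask(geom, inside.reshape(geom.shape))
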