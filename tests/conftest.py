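import numpy as np
import pytest

from vasquant.io import CalibratedImage
from vasquant.preprocess import BinaryMask
from vasquant.synthetic import generate_network


@pytest.fixture()
def plus_sign_mask():
    """Vertical and horizontal 9-px lines crossing at the shared center."""
    a = np.zeros((9, 9), dtype=bool)
    a[4, :] = True
    a[:, 4] = True
    return BinaryMask(a, 1.0)


@pytest.fixture()
def gradient_image():
    rng = np.random.default_rng(7)
    px = rng.integers(0, 256, size=(40, 40)).astype(np.uint8)
    return CalibratedImage(px, 0.65)


@pytest.fixture(scope="session")
def small_network():
    """One deterministic synthetic field reused by read-only tests."""
    return generate_network(42)


def random_point_mask(rng, shape=(80, 80), n_objects=10, pixel_size_um=1.0):
    """Mask of well-separated single-pixel objects; returns (mask, coords)."""
    pts = []
    while len(pts) < n_objects:
        r = int(rng.integers(1, shape[0] - 1))
        c = int(rng.integers(1, shape[1] - 1))
        if all(max(abs(r - a), abs(c - b)) > 1 for a, b in pts):
            pts.append((r, c))
    m = np.zeros(shape, dtype=bool)
    for r, c in pts:
        m[r, c] = True
    return BinaryMask(m, pixel_size_um), pts
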