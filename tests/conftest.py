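import numpy as np
import pytest

from nucleograde.regions import NucleusRegion, region_from_mask


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


def make_random_region(rng, size=16, p_mask=0.85, connected=True):
    """Random masked patch: random 8-bit intensities under a random but
    connected mask (a blob grown from the centre)."""
    from scipy import ndimage as ndi

    pixels = rng.integers(0, 256, size=(size, size)).astype(np.uint8)
    if connected:
        mask = rng.random((size, size)) < p_mask
        mask[size // 2, size // 2] = True
        labels, n = ndi.label(mask, structure=np.ones((3, 3), bool))
        centre_lab = labels[size // 2, size // 2]
        mask = labels == centre_lab
    else:
        mask = np.ones((size, size), bool)
    gray = np.where(mask, pixels, 0).astype(np.uint8)
    return region_from_mask(mask, gray)


@pytest.fixture
def random_region_factory(rng):
    return lambda **kw: make_random_region(rng, **kw)


def constant_region(value=100, size=12):
    mask = np.ones((size, size), bool)
    gray = np.full((size, size), value, np.uint8)
    return region_from_mask(mask, gray)


def full_region(pixels):
    """Region covering a full rectangular patch."""
    pixels = np.asarray(pixels, dtype=np.uint8)
    return region_from_mask(np.ones(pixels.shape, bool), pixels)


def disk_mask(radius, pad=3):
    n = 2 * (radius + pad) + 1
    rr, cc = np.mgrid[:n, :n]
    c = radius + pad
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius ** 2
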