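import numpy as np
import pytest

from echopanc import (PancreasMask, UltrasoundImage, default_spec,
                      generate_phantom)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic DM phantom (image, mask, label)."""
    return generate_phantom(default_spec("DM", seed=42))


@pytest.fixture(scope="session")
def speckle_image(rng):
    """Random speckle-like uint8 image with a centered elliptical mask."""
    img = (rng.random((96, 120)) * 255).astype(np.uint8)
    rr, cc = np.mgrid[:96, :120]
    mask = ((rr - 48) / 30.0) ** 2 + ((cc - 60) / 45.0) ** 2 <= 1.0
    return (UltrasoundImage(pixels=img, pixel_spacing_mm=0.3),
            PancreasMask(mask=mask))


def make_image(arr, spacing=1.0):
    return UltrasoundImage(pixels=np.asarray(arr, dtype=np.uint8),
                           pixel_spacing_mm=spacing)


def full_mask(shape):
    return PancreasMask(mask=np.ones(shape, dtype=bool))
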