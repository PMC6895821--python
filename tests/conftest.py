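from __future__ import annotations

import numpy as np
import pytest

from punctacoloc.detection import ChannelImage, DetectionParams, MaximaPoint, MaximaSet


def add_gaussian(img: np.ndarray, row: float, col: float, amp: float, sigma: float) -> None:
    """Add one isotropic Gaussian spot to a float image in place."""
    h, w = img.shape
    rr = np.arange(h)[:, None] - row
    cc = np.arange(w)[None, :] - col
    img += amp * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def random_quantized_image(rng: np.random.Generator, h: int = 64, w: int = 64) -> np.ndarray:
    """Integer-valued test image mixing spots, noise, ramps and flat patches.

    Quantization creates equal-intensity plateaus, exercising the plateau
    policy; flat patches and ramps exercise degenerate maxima.
    """
    img = np.full((h, w), 10.0)
    style = rng.integers(0, 4)
    if style >= 1:  # some spots
        for _ in range(int(rng.integers(1, 8))):
            add_gaussian(
                img,
                rng.uniform(2, h - 2),
                rng.uniform(2, w - 2),
                rng.uniform(4, 120),
                rng.uniform(0.8, 2.5),
            )
    if style in (0, 2):  # noise
        img += rng.normal(0, 3, img.shape)
    if style == 3:  # flat bright patch -> large plateau
        r, c = rng.integers(5, h - 12), rng.integers(5, w - 12)
        img[r : r + 5, c : c + 5] = rng.integers(30, 200)
    if rng.random() < 0.3:  # intensity ramp
        img += rng.uniform(0, 0.5) * np.arange(w)[None, :]
    return np.clip(np.round(img), 0, 255)


def make_set(points, shape=(64, 64), channel="A", params=None):
    """MaximaSet from bare (row, col) tuples, for matcher tests."""
    pts = tuple(MaximaPoint(int(r), int(c), 100.0, 10.0) for r, c in points)
    return MaximaSet(
        channel=channel,
        points=pts,
        params=params or DetectionParams(),
        image_shape=shape,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
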