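"""Punctate-maxima detection in single fluorescence channels.

A punctum is operationalized as a regional intensity maximum that rises at
least ``delta_threshold`` arbitrary units (AU, raw stored intensity) above
its *adjacent background*, estimated as a robust statistic over an annulus
centred on the candidate pixel.  Images are used unaltered: no flat-field,
illumination or bleaching correction is applied, so the criterion is purely
relative to the local surround.

Coordinate convention: 0-based ``(row, col)``, row increasing downward.
This convention is used everywhere coordinates are stored or written.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima as _regional_maxima

__all__ = [
    "ChannelImage",
    "DetectionParams",
    "MaximaPoint",
    "MaximaSet",
    "split_channels",
    "local_background",
    "detect_maxima",
]

_CHANNEL_LABELS = {"red", "green", "blue", "A", "B"}


@dataclass(frozen=True)
class ChannelImage:
    """One 2-D intensity plane with its channel label and bit depth.

    Intensities are raw stored values in AU; valid range is
    ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    channel: str
    bit_depth: int = 8
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError(
                f"ChannelImage requires a 2-D plane of at least 3x3 pixels, "
                f"got shape {px.shape}"
            )
        if self.channel not in _CHANNEL_LABELS:
            raise ValueError(
                f"channel must be one of {sorted(_CHANNEL_LABELS)}, got {self.channel!r}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        hi = 2**self.bit_depth - 1
        if px.min() < 0 or px.max() > hi:
            raise ValueError(
                f"intensities outside [0, {hi}] for a {self.bit_depth}-bit image"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the maxima criterion.

    delta_threshold
        Minimum excess of peak intensity over adjacent background, AU.
        Default 10 AU.
    background_annulus_inner, background_annulus_outer
        The adjacent background of a candidate at (r, c) is taken over
        pixels with ``inner < distance <= outer`` (Euclidean, pixel
        centres).  Defaults 3 and 7 px: the inner radius excludes the
        punctum core, the outer radius keeps the estimate local.
    background_statistic
        "median" (default, robust to nearby puncta) or "mean".
    edge_margin
        Candidates closer than this to any border are discarded rather
        than scored against a truncated annulus.  Defaults to the outer
        annulus radius.
    plateau_policy
        Quantized images produce flat-topped peaks.  "centroid" (default)
        collapses an equal-intensity plateau to its rounded centroid
        pixel; "first" takes the plateau pixel first in (row, col) order.
    """

    delta_threshold: float = 10.0
    background_annulus_inner: float = 3.0
    background_annulus_outer: float = 7.0
    background_statistic: str = "median"
    edge_margin: int | None = None
    plateau_policy: str = "centroid"

    def __post_init__(self) -> None:
        if self.delta_threshold <= 0:
            raise ValueError("delta_threshold must be > 0")
        if not self.background_annulus_inner < self.background_annulus_outer:
            raise ValueError("annulus inner radius must be < outer radius")
        if self.background_statistic not in ("median", "mean"):
            raise ValueError("background_statistic must be 'median' or 'mean'")
        if self.plateau_policy not in ("centroid", "first"):
            raise ValueError("plateau_policy must be 'centroid' or 'first'")
        if self.edge_margin is None:
            object.__setattr__(
                self, "edge_margin", int(np.ceil(self.background_annulus_outer))
            )
        if self.edge_margin < self.background_annulus_outer:
            raise ValueError("edge_margin must be >= background_annulus_outer")

    def annulus_offsets(self) -> np.ndarray:
        """(k, 2) integer offsets with inner < ||offset|| <= outer."""
        r = int(np.ceil(self.background_annulus_outer))
        dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
        d = np.hypot(dr, dc)
        keep = (d > self.background_annulus_inner) & (
            d <= self.background_annulus_outer
        )
        return np.stack([dr[keep], dc[keep]], axis=1)


class MaximaPoint(NamedTuple):
    row: int
    col: int
    intensity: float
    local_background: float


@dataclass(frozen=True)
class MaximaSet:
    """Detected puncta of one channel plus the parameters that produced them."""

    channel: str
    points: tuple[MaximaPoint, ...]
    params: DetectionParams
    image_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        """(n, 2) array of (row, col) coordinates; empty -> shape (0, 2)."""
        if not self.points:
            return np.empty((0, 2), dtype=float)
        return np.array([(p.row, p.col) for p in self.points], dtype=float)


def split_channels(image: np.ndarray, source_id: str = "", bit_depth: int = 8):
    """Split an RGB image into red/green/blue ChannelImage planes, unaltered.

    Accepts an (H, W, 3) array; anything else (grayscale, RGBA, ...) is
    rejected with the offending plane count in the message.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        n_planes = 1 if arr.ndim == 2 else (arr.shape[2] if arr.ndim == 3 else arr.ndim)
        raise ValueError(
            f"expected an image with exactly 3 colour planes, got {n_planes} "
            f"(shape {arr.shape})"
        )
    return tuple(
        ChannelImage(arr[:, :, i], channel=name, bit_depth=bit_depth, source_id=source_id)
        for i, name in enumerate(("red", "green", "blue"))
    )


def local_background(
    image: ChannelImage, row: int, col: int, params: DetectionParams
) -> float:
    """Adjacent-background estimate at (row, col): the configured statistic
    over the annulus ``inner < distance <= outer`` centred there.

    (row, col) must be at least ``edge_margin`` from every border so the
    annulus is complete.
    """
    offsets = params.annulus_offsets()
    if offsets.size == 0:
        raise ValueError(
            "empty background annulus: no pixel satisfies "
            f"{params.background_annulus_inner} < d <= {params.background_annulus_outer}"
        )
    h, w = image.shape
    m = params.edge_margin
    if not (m <= row < h - m and m <= col < w - m):
        raise ValueError(
            f"({row}, {col}) is within edge_margin={m} of the border of a "
            f"{h}x{w} image; the annulus would be truncated"
        )
    vals = image.pixels[row + offsets[:, 0], col + offsets[:, 1]].astype(float)
    if params.background_statistic == "median":
        return float(np.median(vals))
    return float(vals.mean())


def _plateau_representatives(
    img: np.ndarray, policy: str
) -> list[tuple[int, int, float]]:
    """Regional maxima as (row, col, plateau value) representative pixels.

    A regional maximum is an 8-connected equal-intensity plateau all of
    whose outside neighbours are strictly lower.  A single-pixel plateau is
    the strict 8-neighbourhood local maximum.  Representatives follow the
    plateau policy; the reported value is the plateau intensity (which for
    a non-convex plateau may differ from the image value at the rounded
    centroid pixel).
    """
    mask = _regional_maxima(img, connectivity=2, allow_borders=True)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    out = []
    if policy == "centroid":
        # floor(x + 0.5): deterministic half-up rounding of the centroid
        centroids = ndimage.center_of_mass(mask, labels, range(1, n + 1))
        for lab, (cr, cc) in enumerate(centroids, start=1):
            rr = int(np.floor(cr + 0.5))
            cc_ = int(np.floor(cc + 0.5))
            any_pix = np.argwhere(labels == lab)[0]
            out.append((rr, cc_, float(img[any_pix[0], any_pix[1]])))
    else:  # first in (row, col) order
        for lab in range(1, n + 1):
            pix = np.argwhere(labels == lab)
            i = np.lexsort((pix[:, 1], pix[:, 0]))[0]
            r, c = pix[i]
            out.append((int(r), int(c), float(img[r, c])))
    return out


def detect_maxima(image: ChannelImage, params: DetectionParams | None = None) -> MaximaSet:
    """Detect puncta: regional 8-neighbourhood maxima at least
    ``delta_threshold`` AU above their adjacent background.

    Candidates within ``edge_margin`` of a border are excluded.  Results are
    sorted by (row, col); if two plateau representatives round to the same
    pixel only the more intense survives, so points occupy distinct pixels.
    """
    if params is None:
        params = DetectionParams()
    h, w = image.shape
    m = params.edge_margin
    if h <= 2 * m or w <= 2 * m:
        raise ValueError(
            f"image of shape {h}x{w} is not larger than twice the edge "
            f"margin ({m}) in both dimensions"
        )
    img = image.pixels.astype(float)
    candidates = _plateau_representatives(img, params.plateau_policy)

    best: dict[tuple[int, int], MaximaPoint] = {}
    for r, c, val in candidates:
        if not (m <= r < h - m and m <= c < w - m):
            continue
        bg = local_background(image, r, c, params)
        if val - bg >= params.delta_threshold:
            key = (r, c)
            if key not in best or val > best[key].intensity:
                best[key] = MaximaPoint(r, c, val, bg)

    pts = tuple(sorted(best.values(), key=lambda p: (p.row, p.col)))
    return MaximaSet(channel=image.channel, points=pts, params=params, image_shape=(h, w))
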