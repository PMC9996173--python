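"""HSV colour segmentation of the vessel lumen.

Cross-sections of the reconstructed aorta are rendered with a red lumen.
Because hue isolates chroma, the lumen is extracted by thresholding in HSV
space rather than RGB.  Red straddles the hue origin, so two ranges are
needed: a low-hue band and a wrap-around band near the top of the hue
scale.  The union mask is cleaned by a morphological opening (erosion then
dilation, 3x3 structuring element) and smoothed with a 3x3 Gaussian filter
before re-binarisation.

Conventions
-----------
Hue is computed in degrees on [0, 360) from the piecewise max/min formula
and stored on the half-degree integer scale h in [0, 180]; saturation and
value are computed on [0, 1] and stored on [0, 255].  The default red
thresholds, inclusive on both ends, are

    [0, 43, 46] .. [10, 255, 255]   and   [156, 43, 46] .. [180, 255, 255]

on that storage scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .errors import NoLumenFound

__all__ = [
    "HsvColor",
    "HsvRange",
    "RED_RANGES",
    "rgb_to_hsv_degrees",
    "rgb_to_hsv",
    "rgb_image_to_hsv",
    "in_range",
    "segment_lumen",
    "SegmentationResult",
]

# 3x3 binomial kernel: the fixed Gaussian kernel for kernel size 3.
_GAUSS_1D = np.array([0.25, 0.5, 0.25])


class HsvColor(NamedTuple):
    """HSV triple on the integer storage scale (h in [0,180], s,v in [0,255])."""

    h: int
    s: int
    v: int


class HsvRange(NamedTuple):
    """Inclusive component-wise HSV bounds."""

    lower: HsvColor
    upper: HsvColor

    def validate(self) -> "HsvRange":
        lo, up = HsvColor(*self.lower), HsvColor(*self.upper)
        if not (0 <= lo.h <= 180 and 0 <= up.h <= 180):
            raise ValueError(f"hue bounds outside [0, 180]: {lo.h}, {up.h}")
        for name, a, b in (("s", lo.s, up.s), ("v", lo.v, up.v)):
            if not (0 <= a <= 255 and 0 <= b <= 255):
                raise ValueError(f"{name} bounds outside [0, 255]")
        if not (lo.h <= up.h and lo.s <= up.s and lo.v <= up.v):
            raise ValueError(f"lower bound exceeds upper bound: {lo} > {up}")
        return HsvRange(lo, up)


#: Default red thresholds: low-hue band and hue-wraparound band.
RED_RANGES: tuple[HsvRange, HsvRange] = (
    HsvRange(HsvColor(0, 43, 46), HsvColor(10, 255, 255)),
    HsvRange(HsvColor(156, 43, 46), HsvColor(180, 255, 255)),
)


def rgb_to_hsv_degrees(r, g, b):
    """Piecewise RGB -> HSV conversion on the continuous scale.

    Parameters are real channel values in [0, 1].  Returns ``(h, s, v)``
    with hue in degrees on [0, 360] (0 when max = min), and s, v in [0, 1]
    (s = 0 when max = 0).  Accepts scalars or broadcastable arrays.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, c in (("r", r), ("g", g), ("b", b)):
        if np.any((c < 0) | (c > 1)):
            raise ValueError(f"channel {name} outside [0, 1]")

    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    delta = mx - mn
    safe = np.where(delta == 0, 1.0, delta)

    h = np.select(
        [
            delta == 0,
            (mx == r) & (g >= b),
            (mx == r) & (g < b),
            mx == g,
        ],
        [
            0.0,
            60.0 * (g - b) / safe,
            60.0 * (g - b) / safe + 360.0,
            60.0 * (b - r) / safe + 120.0,
        ],
        default=60.0 * (r - g) / safe + 240.0,  # max == b
    )
    s = np.where(mx == 0, 0.0, delta / np.where(mx == 0, 1.0, mx))
    return h, s, mx


def rgb_to_hsv(r: float, g: float, b: float) -> HsvColor:
    """Convert one RGB colour (channels in [0, 1]) to stored HSV.

    Hue is halved and rounded to [0, 180]; s and v are scaled to [0, 255].
    """
    h, s, v = rgb_to_hsv_degrees(r, g, b)
    return HsvColor(int(np.round(h / 2.0)), int(np.round(s * 255.0)), int(np.round(v * 255.0)))


def rgb_image_to_hsv(img: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) uint8 RGB image to stored-scale HSV (uint8-ish ints).

    Returns an (H, W, 3) int array with channels (h, s, v) on the storage
    scale.  Vectorised version of :func:`rgb_to_hsv`.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) colour image")
    rgb = img.astype(float) / 255.0
    h, s, v = rgb_to_hsv_degrees(rgb[..., 0], rgb[..., 1], rgb[..., 2])
    out = np.empty(img.shape, dtype=np.int16)
    out[..., 0] = np.round(h / 2.0)
    out[..., 1] = np.round(s * 255.0)
    out[..., 2] = np.round(v * 255.0)
    return out


def in_range(hsv: np.ndarray, rng: HsvRange) -> np.ndarray:
    """Boolean mask of pixels whose stored HSV lies inside ``rng`` (inclusive)."""
    lo, up = HsvColor(*rng.lower), HsvColor(*rng.upper)
    return np.logical_and.reduce(
        [
            hsv[..., 0] >= lo.h,
            hsv[..., 0] <= up.h,
            hsv[..., 1] >= lo.s,
            hsv[..., 1] <= up.s,
            hsv[..., 2] >= lo.v,
            hsv[..., 2] <= up.v,
        ]
    )


@dataclass
class SegmentationResult:
    """Binary mask (0/1 uint8) and the source image zeroed outside it."""

    mask: np.ndarray
    masked_image: np.ndarray
    raw_in_range_count: int  # pixels inside the HSV ranges before cleanup


def segment_lumen(
    img: np.ndarray,
    ranges: Sequence[HsvRange] = RED_RANGES,
    *,
    opening_iterations: int = 1,
    gaussian: bool = True,
) -> SegmentationResult:
    """Extract the red lumen region of a colour cross-section image.

    Pixels falling in any of the HSV ``ranges`` form the raw mask; the mask
    is opened (one erosion then one dilation with a 3x3 rectangular
    element), blurred with the 3x3 Gaussian kernel and re-binarised at 0.5.
    The masked image keeps the original pixels where the mask is 1.

    Raises
    ------
    NoLumenFound
        If the cleaned mask is empty.
    """
    hsv = rgb_image_to_hsv(img)
    mask = np.zeros(hsv.shape[:2], dtype=bool)
    for rng in ranges:
        mask |= in_range(hsv, HsvRange(*rng).validate())
    raw_count = int(mask.sum())

    struct = np.ones((3, 3), dtype=bool)
    if opening_iterations > 0:
        mask = ndimage.binary_erosion(mask, structure=struct, iterations=opening_iterations)
        mask = ndimage.binary_dilation(mask, structure=struct, iterations=opening_iterations)
    if gaussian:
        soft = mask.astype(float)
        soft = ndimage.convolve1d(soft, _GAUSS_1D, axis=0, mode="nearest")
        soft = ndimage.convolve1d(soft, _GAUSS_1D, axis=1, mode="nearest")
        mask = soft >= 0.5

    if not mask.any():
        raise NoLumenFound("no pixel survived HSV thresholding and cleanup")

    mask8 = mask.astype(np.uint8)
    masked = img * mask8[..., None]
    return SegmentationResult(mask=mask8, masked_image=masked, raw_in_range_count=raw_count)
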