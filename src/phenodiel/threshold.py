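"""Colour-space range thresholding of VIS frames, and grayscale Otsu.

Rosettes are separated from the soil background by per-channel inclusion
ranges in a chosen colour space (RGB, HSV or CIELAB), or by the Otsu threshold
on luminance.  A pixel is foreground iff all three channel values fall inside
their inclusive ranges; the hue range may wrap around 360°.

Channel scales: RGB and grayscale in [0, 255]; H in [0, 360), S and V in
[0, 1]; L in [0, 100], a and b in [-128, 127] (D65 white point).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure, morphology

from .session import Frame, Modality

__all__ = [
    "ColorSpace",
    "ThresholdSpec",
    "convert_space",
    "threshold_ranges",
    "otsu_threshold",
    "clean_mask",
    "channel_histograms",
]

#: channel (low, high) bounds per colour space, in channel order
_SCALES = {
    "RGB": ((0, 255), (0, 255), (0, 255)),
    "HSV": ((0, 360), (0, 1), (0, 1)),
    "LAB": ((0, 100), (-128, 127), (-128, 127)),
}

DEFAULT_MIN_AREA_PX = 25


class ColorSpace(str, enum.Enum):
    RGB = "RGB"
    HSV = "HSV"
    LAB = "LAB"
    GRAY_OTSU = "GRAY_OTSU"


@dataclass(frozen=True)
class ThresholdSpec:
    """Foreground definition: colour space + three inclusive channel ranges."""

    space: ColorSpace
    ranges: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.space is ColorSpace.GRAY_OTSU:
            if self.ranges is not None:
                raise ValueError("GRAY_OTSU takes no ranges (threshold computed)")
            return
        if self.ranges is None or len(self.ranges) != 3:
            raise ValueError("three (low, high) channel ranges required")
        scales = _SCALES[self.space.value]
        for ch, ((lo, hi), (smin, smax)) in enumerate(zip(self.ranges, scales)):
            wrap_ok = self.space is ColorSpace.HSV and ch == 0
            if lo > hi and not wrap_ok:
                # permitted (it selects nothing) but must still be on-scale
                pass
            if not (smin <= lo <= smax and smin <= hi <= smax):
                if not (wrap_ok and smin <= lo < 360 and smin <= hi < 360):
                    raise ValueError(
                        f"channel {ch} range ({lo}, {hi}) outside scale "
                        f"[{smin}, {smax}]"
                    )


def convert_space(frame: Frame, space: ColorSpace | str) -> np.ndarray:
    """Convert an RGB frame to a 3-channel float raster on the declared scales.

    Standard sRGB→HSV and sRGB→Lab (D65) transforms.  NIR frames cannot be
    colour-converted and raise.
    """
    space = ColorSpace(space)
    if frame.modality is not Modality.VIS:
        raise ValueError("single-channel NIR frame cannot be colour-converted")
    rgb = frame.pixels
    if space is ColorSpace.RGB:
        return rgb.astype(np.float64)
    if space is ColorSpace.HSV:
        hsv = skcolor.rgb2hsv(rgb)
        hsv[..., 0] *= 360.0
        return hsv
    if space is ColorSpace.LAB:
        return skcolor.rgb2lab(rgb)
    raise ValueError("GRAY_OTSU is not a colour conversion; use otsu_threshold")


def threshold_ranges(frame: Frame, spec: ThresholdSpec) -> np.ndarray:
    """Boolean foreground mask: conjunction of the three channel ranges.

    Hue ranges with ``low > high`` wrap: [low, 360) ∪ [0, high].  In the other
    (linear) channels ``low > high`` selects nothing.
    """
    if spec.space is ColorSpace.GRAY_OTSU:
        raise ValueError("use otsu_threshold for GRAY_OTSU specs")
    chans = convert_space(frame, spec.space)
    mask = np.ones(frame.shape, dtype=bool)
    for ch, (lo, hi) in enumerate(spec.ranges):
        v = chans[..., ch]
        if spec.space is ColorSpace.HSV and ch == 0 and lo > hi:
            mask &= (v >= lo) | (v <= hi)
        else:
            mask &= (v >= lo) & (v <= hi)
    return mask


def otsu_threshold(gray: np.ndarray) -> tuple[int, np.ndarray]:
    """Otsu's threshold on the 256-bin histogram; foreground = pixels > t.

    The returned ``t`` maximizes the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2`` over all splits ``{<= t} / {> t}``; ties are
    broken by the smallest maximizing threshold.  A constant image has no
    valid split and raises ``ValueError("degenerate histogram")``.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("otsu_threshold expects a single-channel raster")
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256).astype(np.float64)
    n = hist.sum()
    csum = np.cumsum(hist)            # pixels with value <= t
    cmean = np.cumsum(hist * np.arange(256))
    w0 = csum[:-1]                    # candidate thresholds t = 0..254
    w1 = n - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise ValueError("degenerate histogram: constant image has no split")
    mu0 = np.where(w0 > 0, cmean[:-1] / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (cmean[-1] - cmean[:-1]) / np.maximum(w1, 1), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    t = int(np.argmax(sigma_b))       # argmax returns the first (smallest) tie
    return t, gray > t


def clean_mask(
    mask: np.ndarray,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    fill_holes: bool = False,
) -> np.ndarray:
    """Remove 8-connected components smaller than ``min_area_px``; optionally
    fill holes.  With ``fill_holes`` off the output is a subset of the input."""
    if min_area_px < 0:
        raise ValueError("min_area_px must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    if min_area_px > 1:
        # max_size removes components <= its value, so strictly-smaller-than
        # min_area_px means max_size = min_area_px - 1
        out = morphology.remove_small_objects(
            out, max_size=min_area_px - 1, connectivity=2
        )
    if fill_holes:
        out = ndimage.binary_fill_holes(out)
    return out


def channel_histograms(
    frame: Frame, space: ColorSpace | str, bins: int = 64
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-channel (counts, bin_edges) histograms to guide range tuning."""
    chans = convert_space(frame, space)
    scales = _SCALES[ColorSpace(space).value]
    return [
        np.histogram(chans[..., ch].ravel(), bins=bins, range=scales[ch])
        for ch in range(3)
    ]
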