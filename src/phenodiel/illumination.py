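"""Uneven-illumination estimation and correction for single-channel frames.

NIR frames lit by an LED array show a smooth spatial intensity field (typically
radial falloff from the array centre) superposed on the scene.  The correction
estimates that field with a heavy Gaussian blur and subtracts its deviation
from the global mean, pulling dark regions up and bright regions down without
disturbing scene-scale contrast.

The field estimate must reject two nuisance scales: bright rosettes (which a
plain low-pass map absorbs and then wrongly subtracts) and soil texture.  The
correction therefore uses a retrospective shading model: pixel values are
first pulled toward the global mean (damping foreground leverage), a sliding
median whose footprint exceeds the rosette diameter rejects the foreground
outright, and a least-squares quadratic surface fitted to the median image
gives the illumination field.  A quadratic captures linear gradients and the
radial (vignetting-style) falloff of an LED array exactly, with no edge
attenuation, and cannot chase scene texture — which also makes the correction
idempotent: once the field is removed, a second application is a near no-op.
Flattening by a fraction ``s`` scales the illumination field by ``1 - s``, so
the estimated deviation is rescaled by ``1 / (1 - s)`` before subtraction,
keeping the correction unbiased for any ``s < 1``.  Foreground rejection
fails only when plants cover more than half the median footprint (about a
quarter of the raster width by default); illumination structure beyond
second order is not modelled.

Correction applies only to single-channel (NIR or luminance) processing, never
to RGB VIS frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import rank
from skimage.morphology import disk

__all__ = [
    "IlluminationParams",
    "flatten_toward_mean",
    "intensity_map",
    "correct_illumination",
]


@dataclass(frozen=True)
class IlluminationParams:
    """blur_sigma: Gaussian std in px (default: raster width / 8 if None);
    flatten_strength: fraction in [0, 1] pulling values toward the mean."""

    blur_sigma: float | None = None
    flatten_strength: float = 0.5

    def __post_init__(self) -> None:
        if self.blur_sigma is not None and not self.blur_sigma > 0:
            raise ValueError("blur_sigma must be > 0")
        if not 0.0 <= self.flatten_strength <= 1.0:
            raise ValueError("flatten_strength must be in [0, 1]")

    def sigma_for(self, gray: np.ndarray) -> float:
        return self.blur_sigma if self.blur_sigma is not None else gray.shape[1] / 8.0


def flatten_toward_mean(gray: np.ndarray, strength: float) -> np.ndarray:
    """Pull every pixel toward the global mean: out = g + s * (mean - g).

    strength 0 is the identity; strength 1 yields a constant image at the
    mean.  Returns a float raster clipped to [0, 255].
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    g = _as_gray(gray)
    mean = g.mean()
    return np.clip(g + strength * (mean - g), 0.0, 255.0)


def intensity_map(gray: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian low-pass estimate of the illumination field (reflect boundary)."""
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    g = _as_gray(gray)
    return ndimage.gaussian_filter(g, sigma=sigma, mode="reflect")


def correct_illumination(
    gray: np.ndarray, params: IlluminationParams | None = None
) -> np.ndarray:
    """Subtract the estimated illumination field's deviation from the mean.

    ``out = gray - (field - mean(field)) / (1 - s)`` where ``field`` is a
    quadratic surface fitted to the sliding median of the flattened image
    (``s = flatten_strength``; at ``s = 1`` the field is estimated from the
    unflattened image instead).  Output is clipped to [0, 255] and returned
    in the input dtype (rounded for 8-bit input); the global mean is
    preserved up to clipping.
    """
    params = params or IlluminationParams()
    g = _as_gray(gray)
    s = params.flatten_strength if params.flatten_strength < 1.0 else 0.0
    sigma = params.sigma_for(g)
    flat = flatten_toward_mean(g, s)
    # footprint must comfortably exceed the rosette diameter, or the median
    # picks up the foreground tail
    radius = max(int(round(1.5 * sigma)), 3)
    base = rank.median(
        np.round(flat).astype(np.uint8), footprint=disk(radius)
    ).astype(np.float64)
    # the rank median truncates its footprint at the borders, biasing the
    # estimate there; fit on the unbiased interior and extrapolate
    field = _quadratic_surface(base, border=radius)
    dev = (field - field.mean()) / (1.0 - s)
    out = np.clip(g - dev, 0.0, 255.0)
    if np.asarray(gray).dtype == np.uint8:
        return np.round(out).astype(np.uint8)
    return out


def _quadratic_surface(field: np.ndarray, border: int = 0) -> np.ndarray:
    """Least-squares fit of a + bx + cy + dx^2 + exy + fy^2 to a raster,
    optionally fitting only the interior (excluding ``border`` px per side)
    and extrapolating the surface to the full grid."""
    h, w = field.shape
    yy, xx = np.indices((h, w))
    x = (xx.ravel() - (w - 1) / 2.0) / max(w, 1)
    y = (yy.ravel() - (h - 1) / 2.0) / max(h, 1)
    basis = np.stack([np.ones_like(x), x, y, x * x, x * y, y * y], axis=-1)
    b = min(border, (h - 4) // 2, (w - 4) // 2)
    if b > 0:
        interior = (
            (xx.ravel() >= b) & (xx.ravel() < w - b)
            & (yy.ravel() >= b) & (yy.ravel() < h - b)
        )
    else:
        interior = slice(None)
    coef, *_ = np.linalg.lstsq(
        basis[interior], field.ravel()[interior], rcond=None
    )
    return (basis @ coef).reshape(h, w)


def _as_gray(gray: np.ndarray) -> np.ndarray:
    g = np.asarray(gray, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError("illumination correction expects a single-channel raster")
    return g
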