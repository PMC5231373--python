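"""Micrograph enhancement: median denoising and global histogram equalization.

Enhancement precedes segmentation: the median filter suppresses impulse
and shot noise without blurring droplet edges, and global histogram
equalization spreads the intensity histogram toward uniform via the
monotone mapping v -> round(255 * cdf(v)), improving contrast between
droplets and the lighter background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["GrayImage", "median_filter", "equalize_histogram", "enhance"]


@dataclass(frozen=True)
class GrayImage:
    """8-bit grayscale micrograph with spatial calibration.

    ``pixels`` is a 2-D uint8 array; ``um_per_px`` the pixel size in
    micrometers; ``time_s`` the acquisition time (NaN when unknown).
    """

    pixels: np.ndarray
    um_per_px: float = 1.0
    time_s: float = float("nan")

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            object.__setattr__(self, "pixels", px.astype(np.uint8))
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")


def median_filter(img: GrayImage, radius_px: int = 1) -> GrayImage:
    """Median-filter with a (2r+1) x (2r+1) window, edge-replicated borders."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if 2 * radius_px + 1 > min(img.pixels.shape):
        raise ValueError("median window larger than the image")
    out = ndimage.median_filter(img.pixels, size=2 * radius_px + 1, mode="nearest")
    return GrayImage(out, img.um_per_px, img.time_s)


def equalize_histogram(img: GrayImage) -> GrayImage:
    """Global histogram equalization: v -> round(255 * cdf(v)).

    The mapping is monotone non-decreasing, so the relative intensity
    order of any two pixels is preserved; a constant image maps to 255
    (its single level carries the full cumulative mass).
    """
    counts = np.bincount(img.pixels.ravel(), minlength=256)
    cdf = np.cumsum(counts) / img.pixels.size
    lut = np.rint(255.0 * cdf).astype(np.uint8)
    return GrayImage(lut[img.pixels], img.um_per_px, img.time_s)


def enhance(img: GrayImage, median_radius: int = 1, equalize: bool = True) -> GrayImage:
    """Default enhancement chain: median filter, then equalization."""
    out = median_filter(img, median_radius) if median_radius else img
    return equalize_histogram(out) if equalize else out
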