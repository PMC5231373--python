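"""Droplet segmentation by two-component Gaussian-mixture thresholding.

The intensity histogram of an enhanced micrograph is bimodal: a dark
droplet class and a lighter background class.  A two-component Gaussian
mixture is fitted to the binned histogram by expectation–maximization and
the binarization threshold is placed at the intersection of the two
weighted component densities, i.e. the gray level t in (mu1, mu2) where

    w1 * N(t; mu1, sigma1) = w2 * N(t; mu2, sigma2)

which is the minimum-error decision boundary between the classes.  The
binary mask is then cleaned morphologically (closing to seal edge gaps,
hole filling, removal of border-touching and sub-minimum components).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk, remove_small_objects
from skimage.segmentation import clear_border

from .enhancement import GrayImage

logger = logging.getLogger(__name__)

_SIGMA_FLOOR = 0.5  # gray levels; below this a component has collapsed

__all__ = [
    "Gaussian2Mix",
    "BinaryMask",
    "intensity_histogram",
    "fit_gmm2",
    "gmm_threshold",
    "binarize",
    "refine_mask",
    "segment_frame",
]


@dataclass(frozen=True)
class Gaussian2Mix:
    """Two-component intensity mixture, components ordered mu1 < mu2."""

    w1: float
    w2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool
    sigma_floored: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.w1 < 1 and 0 < self.w2 < 1):
            raise ValueError("weights must lie in (0, 1)")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigmas must be positive")
        if not self.mu1 < self.mu2:
            raise ValueError("components must be ordered mu1 < mu2")


@dataclass(frozen=True)
class BinaryMask:
    """Binary droplet mask, same shape as its source image."""

    pixels: np.ndarray
    um_per_px: float = 1.0
    time_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixels.dtype != bool:
            object.__setattr__(self, "pixels", self.pixels.astype(bool))


def intensity_histogram(img: GrayImage) -> np.ndarray:
    """256-bin intensity histogram of an 8-bit image."""
    return np.bincount(img.pixels.ravel(), minlength=256)


def _log_norm_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2 * math.pi)


def _em_binned(
    levels: np.ndarray,
    counts: np.ndarray,
    init: tuple[float, float, float, float, float],
    tol: float,
    max_iter: int,
    trace: list[float] | None = None,
) -> tuple[np.ndarray, float, int, bool, bool]:
    """EM for a 2-Gaussian mixture on binned data (levels weighted by counts)."""
    w1, mu1, mu2, s1, s2 = init
    n = counts.sum()
    prev_ll = -np.inf
    floored = False
    ll = prev_ll
    it = 0
    for it in range(1, max_iter + 1):
        log_p1 = math.log(w1) + _log_norm_pdf(levels, mu1, s1)
        log_p2 = math.log(1 - w1) + _log_norm_pdf(levels, mu2, s2)
        m = np.maximum(log_p1, log_p2)
        log_tot = m + np.log(np.exp(log_p1 - m) + np.exp(log_p2 - m))
        ll = float(np.sum(counts * log_tot))
        if trace is not None:
            trace.append(ll)
        r1 = np.exp(log_p1 - log_tot)
        c1 = counts * r1
        c2 = counts * (1.0 - r1)
        n1, n2 = c1.sum(), c2.sum()
        if n1 <= 0 or n2 <= 0:
            break
        w1 = n1 / n
        mu1 = float(np.sum(c1 * levels) / n1)
        mu2 = float(np.sum(c2 * levels) / n2)
        s1 = math.sqrt(max(float(np.sum(c1 * (levels - mu1) ** 2) / n1), 0.0))
        s2 = math.sqrt(max(float(np.sum(c2 * (levels - mu2) ** 2) / n2), 0.0))
        if s1 < _SIGMA_FLOOR:
            s1, floored = _SIGMA_FLOOR, True
        if s2 < _SIGMA_FLOOR:
            s2, floored = _SIGMA_FLOOR, True
        if ll - prev_ll < tol and it > 1:
            return np.array([w1, mu1, mu2, s1, s2]), ll, it, True, floored
        prev_ll = ll
    return np.array([w1, mu1, mu2, s1, s2]), ll, it, False, floored


def fit_gmm2(
    hist: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    n_restarts: int = 3,
) -> Gaussian2Mix:
    """Fit a two-component Gaussian mixture to a 256-bin histogram by EM.

    Each gray level is weighted by its count.  Initialization splits the
    histogram at its median level (component means set to the two
    half-means, weights to the half-masses); ``n_restarts`` additional
    seeded jittered starts are run and the highest-likelihood solution is
    kept.  Component standard deviations are floored at 0.5 gray level
    (flagged) to prevent collapse on quasi-degenerate histograms.
    """
    counts = np.asarray(hist, dtype=float)
    if counts.ndim != 1 or counts.size != 256 or np.any(counts < 0):
        raise ValueError("hist must be a 256-bin non-negative histogram")
    occupied = np.nonzero(counts)[0]
    if occupied.size < 2:
        raise ValueError("unimodal/degenerate input: fewer than 2 occupied levels")
    levels = np.arange(256, dtype=float)
    total = counts.sum()

    # median-split initialization
    cdf = np.cumsum(counts) / total
    split = int(np.searchsorted(cdf, 0.5))
    lo = counts[: split + 1]
    hi = counts[split + 1 :]
    if hi.sum() == 0 or lo.sum() == 0:  # all median mass on one side: use extremes
        split = int(occupied[0])
        lo = counts[: split + 1]
        hi = counts[split + 1 :]
    mu1_0 = float(np.sum(levels[: split + 1] * lo) / lo.sum())
    mu2_0 = float(np.sum(levels[split + 1 :] * hi) / hi.sum())
    w1_0 = float(lo.sum() / total)
    spread = max((mu2_0 - mu1_0) / 2.0, _SIGMA_FLOOR)
    base = (w1_0, mu1_0, mu2_0, spread, spread)

    rng = np.random.default_rng(seed)
    inits = [base]
    for _ in range(n_restarts):
        jit = rng.normal(0.0, 0.15 * (mu2_0 - mu1_0), size=2)
        w_j = float(np.clip(w1_0 + rng.normal(0, 0.05), 0.05, 0.95))
        inits.append((w_j, mu1_0 + jit[0], mu2_0 + jit[1], spread, spread))

    best = None
    for init in inits:
        params, ll, it, conv, floored = _em_binned(levels, counts, init, tol, max_iter)
        if best is None or ll > best[1]:
            best = (params, ll, it, conv, floored)
    params, ll, it, conv, floored = best
    w1, mu1, mu2, s1, s2 = params
    if mu1 > mu2:
        w1, mu1, mu2, s1, s2 = 1 - w1, mu2, mu1, s2, s1
    w1 = float(np.clip(w1, 1e-9, 1 - 1e-9))
    return Gaussian2Mix(
        w1=w1, w2=1.0 - w1, mu1=float(mu1), mu2=float(mu2),
        sigma1=float(s1), sigma2=float(s2),
        loglik=float(ll), n_iter=int(it), converged=bool(conv),
        sigma_floored=bool(floored),
    )


def gmm_threshold(mix: Gaussian2Mix) -> float:
    """Threshold at the intersection of the two weighted Gaussian densities.

    Solves w1*phi(t; mu1, s1) = w2*phi(t; mu2, s2) for t in (mu1, mu2).
    With unequal sigmas this is a quadratic; the in-interval root is
    selected.  If no root falls inside (mu1, mu2) — possible for extreme
    weight ratios — the weighted midpoint w2*mu1 + w1*mu2 is returned and
    a warning logged.
    """
    w1, w2 = mix.w1, mix.w2
    mu1, mu2, s1, s2 = mix.mu1, mix.mu2, mix.sigma1, mix.sigma2
    # log w1 - log s1 - (t-mu1)^2/(2 s1^2) = log w2 - log s2 - (t-mu2)^2/(2 s2^2)
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = mu1 / s1**2 - mu2 / s2**2
    c = mu2**2 / (2 * s2**2) - mu1**2 / (2 * s1**2) + math.log((w1 * s2) / (w2 * s1))
    if abs(a) < 1e-12:
        roots = [-c / b] if b != 0 else []
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    in_interval = [t for t in roots if mu1 < t < mu2]
    if in_interval:
        return float(in_interval[0] if len(in_interval) == 1 else min(in_interval))
    logger.warning(
        "no density intersection in (mu1, mu2); falling back to weighted midpoint"
    )
    return float(w2 * mu1 + w1 * mu2)


def binarize(img: GrayImage, threshold: float, object_is_dark: bool = True) -> BinaryMask:
    """Threshold an image; object pixels are below (dark) or above the cut."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    if object_is_dark:
        mask = img.pixels < threshold
    else:
        mask = img.pixels > threshold
    return BinaryMask(mask, img.um_per_px, img.time_s)


def refine_mask(
    mask: BinaryMask,
    dilation_radius: int = 1,
    min_area_px: int = 25,
    drop_border: bool = True,
) -> BinaryMask:
    """Morphological cleanup of a thresholded mask.

    Closing (dilation then erosion) with a disk of the given radius seals
    small boundary gaps, interior holes are filled, and connected
    components smaller than ``min_area_px`` or touching the image border
    are removed (border droplets are partially observed and excluded from
    analysis).
    """
    px = mask.pixels
    if dilation_radius > 0:
        pad = dilation_radius + 1  # pad so closing cannot interact with the frame edge
        padded = np.pad(px, pad, mode="constant")
        padded = closing(padded, disk(dilation_radius))
        px = padded[pad:-pad, pad:-pad]
    px = ndimage.binary_fill_holes(px)
    if drop_border:
        px = clear_border(px)
    if min_area_px > 1:
        # max_size removes components of size <= max_size
        px = remove_small_objects(px, connectivity=2, max_size=min_area_px - 1)
    return BinaryMask(px, mask.um_per_px, mask.time_s)


def segment_frame(
    img: GrayImage,
    object_is_dark: bool = True,
    dilation_radius: int = 1,
    min_area_px: int = 25,
    seed: int = 0,
    threshold: float | None = None,
) -> tuple[BinaryMask, Gaussian2Mix | None, float]:
    """GMM-threshold one frame and clean the mask.

    The threshold is estimated per frame unless a fixed ``threshold`` is
    given (reproducibility studies).  Returns (mask, mixture, threshold).
    """
    mix = None
    if threshold is None:
        mix = fit_gmm2(intensity_histogram(img), seed=seed)
        threshold = gmm_threshold(mix)
    mask = binarize(img, threshold, object_is_dark=object_is_dark)
    mask = refine_mask(mask, dilation_radius=dilation_radius, min_area_px=min_area_px)
    return mask, mix, float(threshold)
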