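"""Geometric feature extraction from binary droplet masks.

Each segmented droplet is summarized by the three magnitudes used in the
downstream analysis: the major diameter of the moment-equivalent ellipse
(um), the pixel-count area (um^2) and the aspect ratio AR = major/minor.
The ellipse is the one sharing the component's second central moments, so
for a pixel set with coordinate covariance matrix C the axis lengths are
``4 * sqrt(eig(C))`` (in pixels) and the orientation is the principal
eigenvector direction.

Droplets are followed through time by nearest-centroid matching with a
displacement gate, producing one :class:`RelaxationCurve` per droplet and
magnitude ready for stretched-exponential fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.segmentation import clear_border

from .segmentation import BinaryMask

logger = logging.getLogger(__name__)

MAGNITUDES = ("area", "ar", "major")

__all__ = [
    "ComponentFeatures",
    "RelaxationCurve",
    "MAGNITUDES",
    "label_components",
    "ellipse_features",
    "track_droplets",
]


@dataclass(frozen=True)
class ComponentFeatures:
    """Per-droplet, per-frame geometry. Lengths in um, area in um^2."""

    droplet_id: str
    time_s: float
    area_um2: float
    major_um: float
    minor_um: float
    ar: float
    centroid_px: tuple[float, float]  # (row, col)
    orientation_rad: float


@dataclass
class RelaxationCurve:
    """One droplet x one magnitude x one process, values versus time."""

    droplet_id: str
    magnitude: str  # "area" | "ar" | "major"
    process: str  # "elongation" | "recovery"
    times_s: list[float] = field(default_factory=list)
    values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.magnitude not in MAGNITUDES:
            raise ValueError(f"magnitude must be one of {MAGNITUDES}")
        if len(self.times_s) != len(self.values):
            raise ValueError("times_s and values must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")


def label_components(mask: BinaryMask) -> list[np.ndarray]:
    """Extract 8-connected components, excluding border-touching ones.

    Returns a list of (n, 2) integer arrays of (row, col) pixel
    coordinates, ordered deterministically by each component's top-most,
    then left-most pixel.
    """
    interior = clear_border(mask.pixels.astype(bool))
    labels = measure.label(interior, connectivity=2)
    comps = []
    for lab in range(1, labels.max() + 1):
        coords = np.argwhere(labels == lab)
        if coords.size:
            comps.append(coords)
    comps.sort(key=lambda c: (int(c[0, 0]), int(c[0, 1])))
    return comps


def ellipse_features(
    component: np.ndarray,
    um_per_px: float,
    time_s: float = float("nan"),
    droplet_id: str = "",
) -> ComponentFeatures:
    """Moment-equivalent-ellipse geometry of one pixel set.

    The component's coordinate covariance C (population moments, no
    discretization correction) defines the ellipse with identical second
    moments: axis lengths 4*sqrt(eigenvalues), orientation along the
    principal eigenvector.  Orientation is the angle of the major axis
    from the column (x) axis, in (-pi/2, pi/2].
    """
    coords = np.asarray(component, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 3:
        raise ValueError("component must be an (n>=3, 2) coordinate array")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / coords.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    if eigvals[0] <= 1e-12:
        raise ValueError("degenerate geometry: collinear component")
    minor_px = 4.0 * math.sqrt(eigvals[0])
    major_px = 4.0 * math.sqrt(eigvals[1])
    v = eigvecs[:, 1]
    if v[1] < 0 or (v[1] == 0 and v[0] < 0):
        v = -v
    orientation = math.atan2(v[0], v[1])
    if orientation <= -math.pi / 2:
        orientation += math.pi
    elif orientation > math.pi / 2:
        orientation -= math.pi
    return ComponentFeatures(
        droplet_id=droplet_id,
        time_s=time_s,
        area_um2=coords.shape[0] * um_per_px**2,
        major_um=major_px * um_per_px,
        minor_um=minor_px * um_per_px,
        ar=major_px / minor_px,
        centroid_px=(float(centroid[0]), float(centroid[1])),
        orientation_rad=orientation,
    )


class _Track:
    def __init__(self, track_id: str, first: ComponentFeatures):
        self.track_id = track_id
        self.points: list[ComponentFeatures] = [first]
        self.n_missing = 0

    @property
    def last(self) -> ComponentFeatures:
        return self.points[-1]


def track_droplets(
    frames: list[tuple[float, list[ComponentFeatures]]],
    um_per_px: float = 1.0,
    gate_factor: float = 0.5,
    max_missing_frac: float = 0.2,
    process: str = "elongation",
    ids_from: list[tuple[str, tuple[float, float]]] | None = None,
) -> list[RelaxationCurve]:
    """Link per-frame components into per-droplet relaxation curves.

    Matching is nearest-centroid with a displacement gate of
    ``gate_factor`` times the droplet's current major diameter per frame
    step; when two candidates fall inside the gate the one with the
    smaller area change wins (logged).  Tracks missing from more than
    ``max_missing_frac`` of the frames are dropped.  ``ids_from`` may give
    (droplet_id, (row, col)) anchors — e.g. from a synthetic-scene
    manifest — to name the tracks by nearest initial centroid; otherwise
    tracks are named d1, d2, ... in first-frame component order.
    """
    if len(frames) < 2:
        raise ValueError("cannot track droplets across fewer than 2 frames")
    t0, comps0 = frames[0]
    tracks = [_Track(f"d{i + 1}", c) for i, c in enumerate(comps0)]
    for time_s, comps in frames[1:]:
        unused = list(range(len(comps)))
        for track in tracks:
            gate_px = gate_factor * track.last.major_um / um_per_px
            cands = []
            for j in unused:
                d = math.dist(comps[j].centroid_px, track.last.centroid_px)
                if d <= gate_px:
                    cands.append((d, j))
            if not cands:
                track.n_missing += 1
                continue
            if len(cands) > 1:
                cands.sort(key=lambda dj: abs(comps[dj[1]].area_um2 - track.last.area_um2))
                logger.warning(
                    "ambiguous match for %s at t=%.3g s: %d candidates, "
                    "resolved by minimum area change",
                    track.track_id, time_s, len(cands),
                )
            j = cands[0][1]
            unused.remove(j)
            track.points.append(comps[j])
    n_frames = len(frames)
    kept: list[_Track] = []
    for track in tracks:
        if track.n_missing > max_missing_frac * n_frames:
            logger.warning(
                "dropping %s: missing in %d of %d frames",
                track.track_id, track.n_missing, n_frames,
            )
        else:
            kept.append(track)
    if ids_from is not None:
        for track in kept:
            anchor = min(
                ids_from,
                key=lambda ic: math.dist(ic[1], track.points[0].centroid_px),
            )
            track.track_id = anchor[0]

    times_by_track = {
        t.track_id: [p.time_s for p in t.points] for t in kept
    }
    curves: list[RelaxationCurve] = []
    for track in kept:
        times = times_by_track[track.track_id]
        for magnitude, attr in (("area", "area_um2"), ("ar", "ar"), ("major", "major_um")):
            curves.append(
                RelaxationCurve(
                    droplet_id=track.track_id,
                    magnitude=magnitude,
                    process=process,
                    times_s=list(times),
                    values=[getattr(p, attr) for p in track.points],
                )
            )
    return curves
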