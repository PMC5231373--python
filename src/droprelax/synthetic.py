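"""Synthetic time-lapse droplet scenes with known ground truth.

The original micrographs behind the analysis — elliptical ferrofluid
droplets in an alginate solution, deforming under a weak uniform magnetic
field and relaxing back when it is switched off — were never deposited.
This module emulates their measurable content: a handful of
non-interacting elliptical droplets, darker than the background, whose
aspect ratio and major diameter evolve in time by the stretched-
exponential (KWW) law, rendered as 8-bit grayscale frames with Gaussian
class noise and optional salt-and-pepper impulses.  The magnetic field
itself is not modeled; only its geometric effect is.

Every scene is fully determined by a :class:`SceneConfig` (including the
seed), so frames are bit-reproducible, and the generating KWW parameters
are written alongside the images as machine-readable ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enhancement import GrayImage
from .features import RelaxationCurve
from .kww import KWWParams, kww_value

__all__ = [
    "DropletSpec",
    "SceneConfig",
    "generate_curves",
    "render_frame",
    "write_scene",
    "scene_from_manifest",
    "default_scene",
]

#: frame times (s) mirroring the published sampling of the two processes
ELONGATION_TIMES = (0.0, 2.0, 6.0, 10.0, 15.0, 18.0, 23.0, 26.0)
RECOVERY_TIMES = (0.0, 6.0, 15.0, 26.0, 54.0, 74.0, 92.0, 111.0, 125.0)


@dataclass(frozen=True)
class DropletSpec:
    """One synthetic droplet: position, orientation and KWW ground truth.

    ``kww_ar`` drives the aspect ratio AR(t) (must stay >= 1) and
    ``kww_major_um`` the major diameter in micrometers; the minor diameter
    and area follow from the ellipse identities minor = major/AR and
    area = pi * major * minor / 4.
    """

    droplet_id: str
    center_px: tuple[float, float]  # (row, col)
    orientation_rad: float
    kww_ar: KWWParams
    kww_major_um: KWWParams


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic time-lapse scene.

    Default intensities put the droplet class at 60 and the background at
    190 gray levels with sd 8 each — a cleanly bimodal histogram (mode
    separation 130 > 3 sd) matching what Gaussian-mixture thresholding
    assumes.  ``impulse_noise_fraction`` adds salt-and-pepper pixels to
    exercise the median filter.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    um_per_px: float = 0.5
    frame_times_s: tuple[float, ...] = ELONGATION_TIMES
    droplets: tuple[DropletSpec, ...] = ()
    background_mean: float = 190.0
    background_sd: float = 8.0
    droplet_mean: float = 60.0
    droplet_sd: float = 8.0
    impulse_noise_fraction: float = 0.002
    seed: int = 0
    droplet_darker: bool = True

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        times = np.asarray(self.frame_times_s, dtype=float)
        if times.size == 0 or np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError("frame_times_s must be non-negative and strictly increasing")
        if not 0 <= self.impulse_noise_fraction < 1:
            raise ValueError("impulse_noise_fraction must lie in [0, 1)")
        for v in (self.background_mean, self.droplet_mean):
            if not 0 <= v <= 255:
                raise ValueError("class means must lie in [0, 255]")
        self._check_geometry()

    def _max_radius_px(self, spec: DropletSpec) -> float:
        """Largest semi-major axis (px) the droplet reaches over the scene."""
        times = np.asarray(self.frame_times_s, dtype=float)
        major = np.asarray(kww_value(times, spec.kww_major_um), dtype=float)
        return float(major.max()) / (2.0 * self.um_per_px)

    def _check_geometry(self) -> None:
        radii = [self._max_radius_px(s) for s in self.droplets]
        for spec, r in zip(self.droplets, radii):
            row, col = spec.center_px
            if (row - r < 1 or col - r < 1
                    or row + r > self.image_height_px - 2
                    or col + r > self.image_width_px - 2):
                raise ValueError(
                    f"droplet {spec.droplet_id} extends beyond the image bounds"
                )
        for i in range(len(self.droplets)):
            for j in range(i + 1, len(self.droplets)):
                d = math.dist(self.droplets[i].center_px, self.droplets[j].center_px)
                if d <= radii[i] + radii[j] + 2:
                    raise ValueError(
                        f"droplets {self.droplets[i].droplet_id} and "
                        f"{self.droplets[j].droplet_id} overlap or touch"
                    )


def _shape_at(spec: DropletSpec, t: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ar = np.asarray(kww_value(t, spec.kww_ar), dtype=float)
    major = np.asarray(kww_value(t, spec.kww_major_um), dtype=float)
    if np.any(ar < 1.0 - 1e-12):
        raise ValueError(f"droplet {spec.droplet_id}: AR drops below 1")
    return ar, major


def generate_curves(
    spec: DropletSpec, times: list[float] | np.ndarray
) -> dict[str, RelaxationCurve]:
    """Ground-truth AR, major-diameter and area curves for one droplet.

    The area curve is derived from major and AR through the ellipse
    identity area = pi * major * minor / 4 with minor = major / AR.  The
    process label is inferred from the sign of the AR amplitude
    (b >= 0: elongation; b < 0: recovery).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    ar, major = _shape_at(spec, t)
    minor = major / ar
    area = math.pi * major * minor / 4.0
    process = "elongation" if spec.kww_ar.b >= 0 else "recovery"
    times_list = t.tolist()
    return {
        "ar": RelaxationCurve(spec.droplet_id, "ar", process, times_list, ar.tolist()),
        "major": RelaxationCurve(spec.droplet_id, "major", process, times_list, major.tolist()),
        "area": RelaxationCurve(spec.droplet_id, "area", process, times_list, area.tolist()),
    }


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_major_px: float,
    semi_minor_px: float,
    orientation_rad: float,
) -> np.ndarray:
    """Pixels whose centers satisfy the rotated ellipse inequality."""
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    dr = rows - center[0]
    dc = cols - center[1]
    cos_t, sin_t = math.cos(orientation_rad), math.sin(orientation_rad)
    u = dc * cos_t + dr * sin_t  # along major axis
    v = -dc * sin_t + dr * cos_t
    return (u / semi_major_px) ** 2 + (v / semi_minor_px) ** 2 <= 1.0


def render_frame(config: SceneConfig, frame_index: int) -> GrayImage:
    """Render one frame of the scene as an 8-bit grayscale image.

    Droplets are filled ellipses at ``droplet_mean`` on a
    ``background_mean`` field (inverted when ``droplet_darker`` is
    False), with per-class Gaussian noise and optional impulse noise; the
    frame is a deterministic function of (config, frame_index).
    """
    if not 0 <= frame_index < len(config.frame_times_s):
        raise IndexError(f"frame_index {frame_index} outside frame_times_s")
    t = config.frame_times_s[frame_index]
    shape = (config.image_height_px, config.image_width_px)
    if config.droplet_darker:
        bg_mean, drop_mean = config.background_mean, config.droplet_mean
    else:
        bg_mean, drop_mean = config.droplet_mean, config.background_mean
    img = np.full(shape, bg_mean, dtype=float)
    inside = np.zeros(shape, dtype=bool)
    for spec in config.droplets:
        ar, major = _shape_at(spec, t)
        semi_major = float(major) / (2.0 * config.um_per_px)
        semi_minor = semi_major / float(ar)
        m = _ellipse_mask(shape, spec.center_px, semi_major, semi_minor,
                          spec.orientation_rad)
        img[m] = drop_mean
        inside |= m
    rng = np.random.default_rng([config.seed, frame_index])
    if config.background_sd > 0 or config.droplet_sd > 0:
        sd = np.where(inside, config.droplet_sd, config.background_sd)
        img = img + rng.normal(size=shape) * sd
    if config.impulse_noise_fraction > 0:
        n_imp = int(round(config.impulse_noise_fraction * img.size))
        if n_imp:
            flat_idx = rng.choice(img.size, size=n_imp, replace=False)
            salt = rng.integers(0, 2, size=n_imp).astype(bool)
            img.ravel()[flat_idx] = np.where(salt, 255.0, 0.0)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrayImage(pixels, config.um_per_px, time_s=float(t))


def ground_truth_table(config: SceneConfig) -> pd.DataFrame:
    """Per-droplet, per-frame true geometry plus generating KWW parameters."""
    rows = []
    for spec in config.droplets:
        ar, major = _shape_at(spec, np.asarray(config.frame_times_s))
        minor = major / ar
        area = math.pi * major * minor / 4.0
        for k, t in enumerate(config.frame_times_s):
            rows.append({
                "droplet_id": spec.droplet_id,
                "time_s": t,
                "ar": ar[k],
                "major_um": major[k],
                "area_um2": area[k],
                "center_row": spec.center_px[0],
                "center_col": spec.center_px[1],
                "ar_a": spec.kww_ar.a, "ar_b": spec.kww_ar.b,
                "ar_lambda_c": spec.kww_ar.lambda_c, "ar_beta": spec.kww_ar.beta,
                "major_a": spec.kww_major_um.a, "major_b": spec.kww_major_um.b,
                "major_lambda_c": spec.kww_major_um.lambda_c,
                "major_beta": spec.kww_major_um.beta,
            })
    return pd.DataFrame(rows)


def _config_to_dict(config: SceneConfig) -> dict:
    d = dataclasses.asdict(config)
    d["droplets"] = [
        {
            "droplet_id": s.droplet_id,
            "center_px": list(s.center_px),
            "orientation_rad": s.orientation_rad,
            "kww_ar": dataclasses.asdict(s.kww_ar),
            "kww_major_um": dataclasses.asdict(s.kww_major_um),
        }
        for s in config.droplets
    ]
    d["frame_times_s"] = list(config.frame_times_s)
    return d


def scene_from_manifest(path: str | Path) -> SceneConfig:
    """Rebuild a SceneConfig from a scene manifest written by write_scene."""
    with open(path) as fh:
        d = json.load(fh)["config"]
    droplets = tuple(
        DropletSpec(
            droplet_id=s["droplet_id"],
            center_px=tuple(s["center_px"]),
            orientation_rad=s["orientation_rad"],
            kww_ar=KWWParams(**s["kww_ar"]),
            kww_major_um=KWWParams(**s["kww_major_um"]),
        )
        for s in d["droplets"]
    )
    d = {**d, "droplets": droplets, "frame_times_s": tuple(d["frame_times_s"])}
    return SceneConfig(**d)


def write_scene(
    config: SceneConfig, out_dir: str | Path, image_format: str = "tiff"
) -> dict:
    """Write the scene to disk: frames, ground-truth CSV and JSON manifest.

    One 8-bit grayscale image per frame (TIFF by default, PNG
    alternatively), ``ground_truth.csv`` with per-frame true geometry and
    generating parameters, and ``manifest.json`` holding the calibration,
    frame times, seed and full config (sufficient to re-render the frames
    bit-identically).  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if image_format not in ("tiff", "png"):
        raise ValueError("image_format must be 'tiff' or 'png'")
    ext = "tif" if image_format == "tiff" else "png"
    frame_files = []
    for k in range(len(config.frame_times_s)):
        frame = render_frame(config, k)
        name = f"frame_{k:03d}.{ext}"
        path = out / name
        try:
            if image_format == "tiff":
                import tifffile

                tifffile.imwrite(path, frame.pixels)
            else:
                import imageio.v3 as iio

                iio.imwrite(path, frame.pixels)
        except OSError as exc:
            raise OSError(f"failed to write frame to {path}: {exc}") from exc
        frame_files.append(name)
    gt = ground_truth_table(config)
    gt.to_csv(out / "ground_truth.csv", index=False)
    manifest = {
        "um_per_px": config.um_per_px,
        "frame_times_s": list(config.frame_times_s),
        "seed": config.seed,
        "image_format": image_format,
        "frames": frame_files,
        "ground_truth": "ground_truth.csv",
        "config": _config_to_dict(config),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def default_scene(
    process: str = "elongation",
    seed: int = 0,
    frame_times_s: tuple[float, ...] | None = None,
    noise: bool = True,
) -> SceneConfig:
    """The canonical five-droplet study scene.

    The droplets reuse the published per-droplet stretched-exponential
    parameters for AR and major diameter (elongation or recovery rows),
    so the scene reproduces the size range (initial majors ~12-67 um) and
    kinetics (lambda_c ~ 5-22 s) of the experiment at 1 um/px on a
    512 x 512 field.  ``noise=False`` renders noise-free two-level frames
    for exact-recovery tests.
    """
    from .fixtures import load_table1

    if process not in ("elongation", "recovery"):
        raise ValueError("process must be 'elongation' or 'recovery'")
    t1 = load_table1()
    centers = [(80.0, 120.0), (120.0, 380.0), (300.0, 60.0),
               (330.0, 230.0), (400.0, 430.0)]
    droplets = []
    for d, center in zip(range(1, 6), centers):
        row_ar = t1[(t1.magnitude == "ar") & (t1.droplet == d) & (t1.process == process)].iloc[0]
        row_mj = t1[(t1.magnitude == "major") & (t1.droplet == d) & (t1.process == process)].iloc[0]
        # A recovering droplet relaxes toward a sphere (AR -> 1); floor the
        # AR plateau at 1 where the tabulated amplitude would undershoot it.
        b_ar = max(row_ar.b, 1.0 - row_ar.a) if row_ar.b < 0 else row_ar.b
        droplets.append(
            DropletSpec(
                droplet_id=f"d{d}",
                center_px=center,
                orientation_rad=0.35,
                kww_ar=KWWParams(row_ar.a, b_ar, row_ar.lambda_c, row_ar.beta),
                kww_major_um=KWWParams(row_mj.a, row_mj.b, row_mj.lambda_c, row_mj.beta),
            )
        )
    if frame_times_s is None:
        frame_times_s = ELONGATION_TIMES if process == "elongation" else RECOVERY_TIMES
    kwargs = {} if noise else {
        "background_sd": 0.0, "droplet_sd": 0.0, "impulse_noise_fraction": 0.0,
    }
    return SceneConfig(
        frame_times_s=tuple(frame_times_s),
        droplets=tuple(droplets),
        seed=seed,
        **kwargs,
    )
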