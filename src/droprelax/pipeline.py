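"""End-to-end orchestration: images -> masks -> features -> fits -> statistics.

The pipeline mirrors the analysis workflow: enhance each time-stamped
micrograph, segment it by Gaussian-mixture thresholding, extract
per-droplet ellipse features, track droplets through time, fit the
stretched-exponential law to every (droplet, magnitude) curve, and run
the design-of-experiments statistics on the resulting parameter table.
Every stage can also be entered directly from its input artifact
(feature CSV, fit CSV, or the packaged reference fit table), and a full
run writes every intermediate plus a manifest with checksums so that the
same config and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import segmentation, synthetic
from .enhancement import GrayImage, enhance
from .features import RelaxationCurve, ellipse_features, label_components, track_droplets
from .fixtures import load_table1
from .kww import DEConfig, KWWFit, fit_kww
from . import stats as st

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_table1", "fit_feature_table", "features_from_scene_dir"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_frames(scene_dir: str | Path) -> tuple[list[GrayImage], dict]:
    """Load the frames of a written scene directory via its manifest."""
    scene_dir = Path(scene_dir)
    with open(scene_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    frames = []
    for name, t in zip(manifest["frames"], manifest["frame_times_s"]):
        path = scene_dir / name
        if path.suffix in (".tif", ".tiff"):
            import tifffile

            px = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            px = iio.imread(path)
        frames.append(GrayImage(np.asarray(px), manifest["um_per_px"], time_s=float(t)))
    return frames, manifest


def features_from_scene_dir(
    scene_dir: str | Path,
    median_radius: int = 1,
    equalize: bool = False,
    min_area_px: int = 25,
    dilation_radius: int = 1,
    seed: int = 0,
    process: str = "elongation",
) -> tuple[list[RelaxationCurve], pd.DataFrame]:
    """Run enhance -> segment -> features -> track on a scene directory.

    By default the mixture threshold is fitted on the median-filtered
    intensities without histogram equalization: equalization is a
    monotone remap that helps display contrast but reshapes both classes
    away from Gaussian, degrading the intersection threshold, so it is
    opt-in here.  Droplet identities are anchored to the scene manifest's
    true centers when available.  Returns the tracked curves and a
    per-frame feature table.
    """
    frames, manifest = read_frames(scene_dir)
    ids_from = None
    cfg = manifest.get("config")
    if cfg:
        ids_from = [
            (d["droplet_id"], tuple(d["center_px"])) for d in cfg["droplets"]
        ]
    per_frame = []
    rows = []
    for k, frame in enumerate(frames):
        enhanced = enhance(frame, median_radius=median_radius, equalize=equalize)
        mask, _, thr = segmentation.segment_frame(
            enhanced, min_area_px=min_area_px, dilation_radius=dilation_radius,
            seed=seed,
        )
        comps = [
            ellipse_features(c, frame.um_per_px, time_s=frame.time_s)
            for c in label_components(mask)
        ]
        per_frame.append((frame.time_s, comps))
        for c in comps:
            rows.append({
                "time_s": c.time_s, "frame": k, "threshold": thr,
                "area_um2": c.area_um2, "major_um": c.major_um,
                "minor_um": c.minor_um, "ar": c.ar,
                "row": c.centroid_px[0], "col": c.centroid_px[1],
                "orientation_rad": c.orientation_rad,
            })
    curves = track_droplets(
        per_frame, um_per_px=frames[0].um_per_px, process=process, ids_from=ids_from
    )
    return curves, pd.DataFrame(rows)


def fit_feature_table(
    curves: list[RelaxationCurve], seed: int = 0, de: DEConfig | None = None
) -> pd.DataFrame:
    """Fit every relaxation curve; returns the fit table (one row each)."""
    rows = []
    for curve in curves:
        fit = fit_kww(curve, de or DEConfig(seed=seed))
        if not fit.converged:
            logger.warning(
                "fit did not converge for %s/%s/%s",
                curve.droplet_id, curve.magnitude, curve.process,
            )
        rows.append(_fit_row(fit))
    return pd.DataFrame(rows)


def _fit_row(fit: KWWFit) -> dict:
    return {
        "droplet_id": fit.droplet_id, "magnitude": fit.magnitude,
        "process": fit.process, "a": fit.params.a, "b": fit.params.b,
        "lambda_c": fit.params.lambda_c, "beta": fit.params.beta,
        "r2": fit.r2, "n_points": fit.n_points, "seed": fit.seed,
    }


def _stats_stage(table: pd.DataFrame, out: Path, seed: int, n_resamples: int) -> dict:
    aov = st.anova_additive(table, "lambda_c")
    man = st.manova_pillai(table)
    tuk = st.tukey_hsd(table, "lambda_c", "droplet")
    beta_ci, beta_outliers = st.beta_interval(table, n_resamples=n_resamples, seed=seed)
    lam_cis = st.relaxation_time_intervals(table, n_resamples=n_resamples, seed=seed)
    major_el = table[(table.magnitude == "major") & (table.process == "elongation")]
    major_re = table[(table.magnitude == "major") & (table.process == "recovery")]
    merged = major_el.merge(major_re, on="droplet", suffixes=("_el", "_re"))
    reg = st.origin_regression(merged["a_el"], merged["lambda_c_re"])

    aov.to_csv(out / "anova.csv")
    man.to_csv(out / "manova.csv")
    tuk.to_csv(out / "tukey.csv")
    boot = {
        "beta": dataclasses.asdict(beta_ci),
        "beta_outliers": sorted(float(v) for v in beta_outliers),
        "lambda_c": {k: dataclasses.asdict(v) for k, v in lam_cis.items()},
        "reversible_overlap": lam_cis["elongation"].overlaps(lam_cis["recovery"]),
    }
    with open(out / "bootstrap.json", "w") as fh:
        json.dump(boot, fh, indent=1)
    with open(out / "regression.json", "w") as fh:
        json.dump(dataclasses.asdict(reg), fh, indent=1)
    _write_report(out, aov, man, tuk, boot, reg)
    return boot


def _write_report(out, aov, man, tuk, boot, reg) -> None:
    lines = ["# Droplet relaxation statistics", ""]
    lines += ["## Additive ANOVA (response lambda_c)", "", aov.to_markdown(), ""]
    lines += ["## MANOVA, Pillai trace (response (a, b, lambda_c, beta))", "",
              man.to_markdown(), ""]
    lines += ["## Tukey HSD between droplets (lambda_c)", "", tuk.to_markdown(), ""]
    b = boot["beta"]
    lines += ["## Bootstrap 95% confidence intervals", "",
              f"- mean beta (outliers {boot['beta_outliers']} removed): "
              f"({b['lower']:.3f}, {b['upper']:.3f})"]
    for proc, ci in boot["lambda_c"].items():
        lines.append(f"- mean lambda_c, {proc}: ({ci['lower']:.3f}, {ci['upper']:.3f}) s")
    lines += [f"- intervals overlap (reversibility): {boot['reversible_overlap']}", ""]
    if reg.intercept is None:
        lines += ["## lambda_c vs major diameter (through origin)", "",
                  f"lambda_c = {reg.slope:.3f} * major, R^2 = {reg.r2:.3f}"]
    else:
        lines += ["## lambda_c vs major diameter", "",
                  f"lambda_c = {reg.intercept:.3f} + {reg.slope:.3f} * major, "
                  f"R^2 = {reg.r2:.3f}"]
    (out / "report.md").write_text("\n".join(lines) + "\n")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the pipeline from the stage named by ``config['mode']``.

    Modes: ``fixture:table1`` (statistics on the packaged fit table),
    ``fits`` (statistics on a fit CSV), ``features`` (fit + statistics on
    a feature CSV of curves), ``images`` (full chain on a scene
    directory), ``synthetic`` (generate a scene first, then full chain).
    Returns a run manifest with parameters and artifact checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode = config.get("mode", "fixture:table1")
    seed = int(config.get("seed", 0))
    n_resamples = int(config.get("bootstrap", {}).get("n_resamples", 1000))

    table = None
    if mode == "synthetic":
        synth_cfg = config.get("synthetic", {})
        scene = synthetic.default_scene(
            process=synth_cfg.get("process", "elongation"),
            seed=seed,
            frame_times_s=tuple(synth_cfg["frame_times_s"])
            if "frame_times_s" in synth_cfg else None,
            noise=synth_cfg.get("noise", True),
        )
        scene_dir = out / "scene"
        synthetic.write_scene(scene, scene_dir)
        config = {**config, "mode": "images", "input": str(scene_dir)}
        mode = "images"

    if mode == "images":
        seg_cfg = config.get("segment", {})
        enh_cfg = config.get("enhance", {})
        curves, feats = features_from_scene_dir(
            config["input"],
            median_radius=int(enh_cfg.get("median_radius", 1)),
            equalize=bool(enh_cfg.get("equalize", True)),
            min_area_px=int(seg_cfg.get("min_area_px", 25)),
            dilation_radius=int(seg_cfg.get("dilation_radius", 1)),
            seed=seed,
            process=config.get("process", "elongation"),
        )
        feats.to_csv(out / "features.csv", index=False)
        fits = fit_feature_table(curves, seed=seed)
        fits.to_csv(out / "fits.csv", index=False)
        table = _fits_as_factor_table(fits)
    elif mode == "features":
        curves = _curves_from_csv(pd.read_csv(config["input"]))
        fits = fit_feature_table(curves, seed=seed)
        fits.to_csv(out / "fits.csv", index=False)
        table = _fits_as_factor_table(fits)
    elif mode == "fits":
        table = pd.read_csv(config["input"])
    elif mode == "fixture:table1":
        table = load_table1()
        table.to_csv(out / "fits.csv", index=False)
    else:
        raise ValueError(f"unknown pipeline mode {mode!r}")

    if table is not None and _is_full_design(table):
        _stats_stage(table, out, seed, n_resamples)
    else:
        logger.info("skipping DOE statistics: table is not the full 5x3x2 design")

    artifacts = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "run_manifest.json")
    manifest = {
        "mode": mode,
        "seed": seed,
        "parameters": {k: v for k, v in config.items() if k != "mode"},
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _fits_as_factor_table(fits: pd.DataFrame) -> pd.DataFrame:
    table = fits.rename(columns={"droplet_id": "droplet"}).copy()
    table["droplet"] = table["droplet"].astype(str).str.lstrip("d")
    return table


def _is_full_design(table: pd.DataFrame) -> bool:
    try:
        st.validate_factor_table(table)
        return True
    except ValueError:
        return False


def _curves_from_csv(df: pd.DataFrame) -> list[RelaxationCurve]:
    """Rebuild curves from a long-format feature CSV.

    Expected columns: droplet_id, time_s, process and the three magnitude
    columns area_um2, ar, major_um.
    """
    curves = []
    for (droplet_id, process), g in df.groupby(["droplet_id", "process"]):
        g = g.sort_values("time_s")
        for magnitude, col in (("area", "area_um2"), ("ar", "ar"), ("major", "major_um")):
            curves.append(RelaxationCurve(
                droplet_id=str(droplet_id), magnitude=magnitude, process=str(process),
                times_s=g["time_s"].tolist(), values=g[col].tolist(),
            ))
    return curves
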