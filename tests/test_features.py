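"""Component labeling, moment-ellipse features, and droplet tracking."""

import math
from collections import deque

import numpy as np
import pytest

from droprelax.features import (
    ComponentFeatures,
    RelaxationCurve,
    ellipse_features,
    label_components,
    track_droplets,
)
from droprelax.segmentation import BinaryMask


def flood_fill_partition(px):
    """Independent BFS flood-fill oracle (8-connectivity, border included)."""
    seen = np.zeros_like(px, dtype=bool)
    comps = []
    for r in range(px.shape[0]):
        for c in range(px.shape[1]):
            if px[r, c] and not seen[r, c]:
                comp = []
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    rr, cc = queue.popleft()
                    comp.append((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (0 <= nr < px.shape[0] and 0 <= nc < px.shape[1]
                                    and px[nr, nc] and not seen[nr, nc]):
                                seen[nr, nc] = True
                                queue.append((nr, nc))
                comps.append(frozenset(comp))
    return set(comps)


def disc_mask(shape, center, radius):
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    return rows**2 + cols**2 <= radius**2


class TestLabelComponents:
    def test_two_discs_found_with_correct_sizes(self):
        px = disc_mask((64, 64), (20, 20), 8) | disc_mask((64, 64), (45, 45), 5)
        comps = label_components(BinaryMask(px))
        assert len(comps) == 2
        assert {len(c) for c in comps} == {
            int(disc_mask((64, 64), (20, 20), 8).sum()),
            int(disc_mask((64, 64), (45, 45), 5).sum()),
        }

    def test_diagonal_pixels_are_one_component(self):
        px = np.zeros((8, 8), dtype=bool)
        px[3, 3] = px[4, 4] = True
        assert len(label_components(BinaryMask(px))) == 1

    def test_matches_flood_fill_oracle(self, rng):
        px = rng.random((16, 16)) < 0.35
        px[0, :] = px[-1, :] = px[:, 0] = px[:, -1] = False  # keep off border
        got = {frozenset(map(tuple, c)) for c in label_components(BinaryMask(px))}
        assert got == flood_fill_partition(px)

    def test_border_touching_excluded_and_order_deterministic(self):
        px = np.zeros((32, 32), dtype=bool)
        px[0:5, 10:15] = True          # touches border: excluded
        px[20:24, 3:8] = True          # lower-left
        px[10:14, 20:25] = True        # upper-right
        comps = label_components(BinaryMask(px))
        assert len(comps) == 2
        assert tuple(comps[0][0]) < tuple(comps[1][0])  # topmost first

    def test_empty_mask_gives_empty_list(self):
        assert label_components(BinaryMask(np.zeros((8, 8), dtype=bool))) == []


def rendered_ellipse(a_px, b_px, theta=0.0, shape=(160, 160)):
    center = (shape[0] / 2, shape[1] / 2)
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    u = cols * math.cos(theta) + rows * math.sin(theta)
    v = -cols * math.sin(theta) + rows * math.cos(theta)
    return np.argwhere((u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0)


class TestEllipseFeatures:
    def test_disc_moments_match_brute_force(self):
        comp = rendered_ellipse(30, 30)
        f = ellipse_features(comp, um_per_px=1.0)
        assert 1.0 <= f.ar <= 1.02
        assert f.major_um == pytest.approx(60, abs=1.0)
        assert f.area_um2 == comp.shape[0]

    def test_axis_aligned_ellipse_axes_within_two_percent(self):
        f = ellipse_features(rendered_ellipse(40, 20), um_per_px=1.0)
        assert f.major_um == pytest.approx(80, rel=0.02)
        assert f.minor_um == pytest.approx(40, rel=0.02)
        assert f.ar == pytest.approx(2.0, rel=0.02)

    def test_rotation_invariance_of_axes_and_orientation_recovery(self):
        base = ellipse_features(rendered_ellipse(40, 20), um_per_px=1.0)
        rot = ellipse_features(rendered_ellipse(40, 20, theta=math.pi / 6), um_per_px=1.0)
        assert rot.major_um == pytest.approx(base.major_um, rel=0.02)
        assert rot.minor_um == pytest.approx(base.minor_um, rel=0.02)
        assert rot.ar == pytest.approx(base.ar, rel=0.02)
        assert rot.orientation_rad == pytest.approx(math.pi / 6, abs=math.radians(2))

    def test_calibration_scales_lengths_and_area(self):
        comp = rendered_ellipse(30, 30)
        f = ellipse_features(comp, um_per_px=0.5)
        assert f.major_um == pytest.approx(30, abs=0.5)
        assert f.area_um2 == pytest.approx(comp.shape[0] * 0.25)

    def test_collinear_component_rejected(self):
        line = np.array([[5, c] for c in range(10)])
        with pytest.raises(ValueError, match="degenerate"):
            ellipse_features(line, um_per_px=1.0)


def stationary_feature(center, t, area=900.0, droplet_id=""):
    return ComponentFeatures(
        droplet_id=droplet_id, time_s=t, area_um2=area, major_um=2 * math.sqrt(area / math.pi),
        minor_um=2 * math.sqrt(area / math.pi), ar=1.0, centroid_px=center,
        orientation_rad=0.0,
    )


class TestTrackDroplets:
    def make_frames(self, n_frames=9, centers=None):
        centers = centers or [(20.0, 20.0), (20.0, 80.0), (60.0, 40.0),
                              (80.0, 90.0), (90.0, 15.0)]
        return [
            (float(t), [stationary_feature(c, float(t), area=600 + 100 * i)
                        for i, c in enumerate(centers)])
            for t in range(n_frames)
        ]

    def test_five_stationary_droplets_give_five_full_tracks(self):
        curves = track_droplets(self.make_frames())
        assert len(curves) == 15  # 5 droplets x 3 magnitudes
        assert all(len(c.times_s) == 9 for c in curves)
        ids = sorted({c.droplet_id for c in curves})
        assert ids == ["d1", "d2", "d3", "d4", "d5"]

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            track_droplets(self.make_frames(n_frames=1))

    def test_one_missing_frame_keeps_the_track(self):
        frames = self.make_frames()
        t, comps = frames[4]
        frames[4] = (t, comps[1:])  # first droplet absent in 1 of 9 frames
        curves = track_droplets(frames)
        by_id = {c.droplet_id for c in curves}
        assert by_id == {"d1", "d2", "d3", "d4", "d5"}
        d1 = [c for c in curves if c.droplet_id == "d1"][0]
        assert len(d1.times_s) == 8

    def test_mostly_missing_track_is_dropped(self):
        frames = self.make_frames()
        frames = [(t, comps if k < 3 else comps[1:]) for k, (t, comps) in enumerate(frames)]
        curves = track_droplets(frames)
        assert {c.droplet_id for c in curves} == {"d2", "d3", "d4", "d5"}

    def test_ids_anchored_to_manifest_centers(self):
        anchors = [("alpha", (20.0, 20.0)), ("beta", (20.0, 80.0)),
                   ("gamma", (60.0, 40.0)), ("delta", (80.0, 90.0)),
                   ("epsilon", (90.0, 15.0))]
        curves = track_droplets(self.make_frames(), ids_from=anchors)
        assert {c.droplet_id for c in curves} == {a[0] for a in anchors}

    def test_ambiguous_match_resolved_by_area(self):
        f0 = [stationary_feature((50.0, 50.0), 0.0, area=900.0)]
        f1 = [stationary_feature((50.0, 54.0), 1.0, area=2000.0),
              stationary_feature((50.0, 55.0), 1.0, area=905.0)]
        curves = track_droplets([(0.0, f0), (1.0, f1)])
        area_curve = [c for c in curves if c.magnitude == "area"][0]
        assert area_curve.values[1] == 905.0


def test_relaxation_curve_validation():
    with pytest.raises(ValueError):
        RelaxationCurve("d1", "volume", "elongation", [0.0], [1.0])
    with pytest.raises(ValueError):
        RelaxationCurve("d1", "ar", "elongation", [0.0, 0.0], [1.0, 1.0])
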