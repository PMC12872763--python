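import math

import numpy as np
import pytest

from stipemorph.centerline import (
    CenterlineKeypoints,
    canonical_keypoints,
    centerline_length,
    keypoints_to_pose,
)
from stipemorph.geometry import bounding_rect
from stipemorph.synthetic import make_curved_band


@pytest.fixture(scope="module")
def spec_rectangle():
    m = np.zeros((500, 1000), bool)
    m[100:201, 100:501] = True
    return m


class TestCanonicalKeypoints:
    def test_rectangle_midline_points(self, spec_rectangle):
        kps = canonical_keypoints(spec_rectangle)
        assert kps.points == (
            (100, 150),
            (200, 150),
            (300, 150),
            (400, 150),
            (500, 150),
        )

    def test_band_points_lie_on_generating_arc(self, band_fixture):
        mask, _ = band_fixture
        R, t, theta = 300.0, 50.0, math.pi / 3
        kps = canonical_keypoints(mask)
        h, w = mask.shape
        cx = (w - 1) / 2.0
        cy = 8 - (R - t) * math.cos(theta / 2)
        for x, y in kps.points:
            radial = math.hypot(x - cx, y - cy)
            assert radial == pytest.approx(R, abs=2.0)

    def test_too_short_mask_rejected(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:4] = True  # only 3 px along the length axis
        with pytest.raises(ValueError, match=">= 5 px"):
            canonical_keypoints(m)

    def test_mirror_symmetry_reverses_order(self, band_fixture):
        mask, _ = band_fixture
        kps = canonical_keypoints(mask)
        flipped = canonical_keypoints(mask[:, ::-1])
        w = mask.shape[1]
        mirrored = [(w - 1 - x, y) for x, y in reversed(kps.points)]
        for (mx, my), (fx, fy) in zip(mirrored, flipped.points):
            assert fx == pytest.approx(mx, abs=1.0)
            assert fy == pytest.approx(my, abs=1.0)

    def test_translation_equivariance(self, band_fixture):
        mask, _ = band_fixture
        big = np.zeros((mask.shape[0] + 13, mask.shape[1] + 29), bool)
        big[13:, 29:] = mask
        kps = canonical_keypoints(mask)
        shifted = canonical_keypoints(big)
        for (x, y), (sx, sy) in zip(kps.points, shifted.points):
            assert (sx - x, sy - y) == pytest.approx((29, 13), abs=1e-9)


class TestCenterlineLength:
    def test_collinear_points(self):
        kps = CenterlineKeypoints(
            points=tuple((100.0 * i, 5.0) for i in range(5)), length_axis=0
        )
        assert centerline_length(kps) == 400.0

    def test_arc_polyline_close_to_arc_length(self):
        R, theta = 300.0, math.pi / 3
        pts = tuple(
            (
                R * math.sin(-theta / 2 + f * theta),
                R * math.cos(-theta / 2 + f * theta),
            )
            for f in (0, 0.25, 0.5, 0.75, 1.0)
        )
        kps = CenterlineKeypoints(points=pts, length_axis=0)
        assert centerline_length(kps) == pytest.approx(R * theta, rel=0.01)

    def test_rectangle_polyline(self, spec_rectangle):
        assert centerline_length(canonical_keypoints(spec_rectangle)) == 400.0

    def test_band_length_recovers_arc(self, band_fixture):
        mask, truth = band_fixture
        length = centerline_length(canonical_keypoints(mask))
        assert length == pytest.approx(truth.centerline_px, rel=0.02)

    def test_length_at_least_endpoint_span(self, band_fixture):
        mask, _ = band_fixture
        kps = canonical_keypoints(mask)
        span = abs(kps.points[-1][0] - kps.points[0][0])
        assert centerline_length(kps) >= span


class TestPoseEmission:
    def test_normalization_of_spec_rectangle(self, spec_rectangle):
        kps = canonical_keypoints(spec_rectangle)
        pose = keypoints_to_pose(kps, bounding_rect(spec_rectangle), 1000, 500)
        assert pose.box_center_x == pytest.approx(0.3005)
        assert pose.box_center_y == pytest.approx(0.301)
        assert pose.box_w == pytest.approx(0.401)
        assert pose.box_h == pytest.approx(0.202)
        assert pose.keypoints[0] == (0.1, 0.3, 2)
        assert all(v == 2 for _, _, v in pose.keypoints)
        assert pose.class_id == 0

    def test_corner_keypoint_accepted(self):
        kps = CenterlineKeypoints(
            points=((0, 0), (25, 5), (50, 5), (75, 5), (101, 11)), length_axis=0
        )
        box = bounding_rect(np.ones((11, 101), bool))
        pose = keypoints_to_pose(kps, box, 101, 11)
        assert pose.keypoints[0][:2] == (0.0, 0.0)
        assert pose.keypoints[-1][:2] == (1.0, 1.0)

    def test_keypoint_outside_image_rejected(self):
        kps = CenterlineKeypoints(
            points=((0, 0), (25, 5), (50, 5), (75, 5), (102, 11)), length_axis=0
        )
        box = bounding_rect(np.ones((11, 101), bool))
        with pytest.raises(ValueError, match="outside"):
            keypoints_to_pose(kps, box, 101, 11)
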