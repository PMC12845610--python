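"""Scalp-target geometry: arc angles, roll correction, target equations."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coilpilot.exceptions import DegenerateGeometryError
from coilpilot.head_geometry import (HeadLandmarks, approach_offset,
                                     c3_arc_angle, ear_axis_angle,
                                     estimate_head_pose, estimate_vertex,
                                     localize_c3, target_xy)


def make_landmarks(left, right, nasion=(0.0, 0.0, 90.0)):
    return HeadLandmarks(nasion=nasion, left_preauricular=left,
                         right_preauricular=right)


class TestArcAngle:
    @pytest.mark.parametrize("fraction, span, expected", [
        (0.20, 180.0, 36.0),   # the C3 rule: 20% of the transverse arc
        (0.50, 180.0, 90.0),
        (0.10, 180.0, 18.0),
    ])
    def test_linear_in_fraction(self, fraction, span, expected):
        assert c3_arc_angle(fraction, span) == pytest.approx(expected)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_rejects_out_of_range_fraction(self, fraction):
        with pytest.raises(ValueError):
            c3_arc_angle(fraction, 180.0)


class TestEarAxisAngle:
    @pytest.mark.parametrize("left, right, expected", [
        ((-75, 0, 0), (75, 0, 0), 0.0),
        ((-50, -50, 0), (50, 50, 0), 45.0),
        ((-80, -10, 0), (80, 10, 0), math.degrees(math.atan(20 / 160))),
    ])
    def test_known_angles(self, left, right, expected):
        lm = make_landmarks(left, right)
        assert ear_axis_angle(lm) == pytest.approx(expected, abs=1e-9)

    def test_third_example_is_about_seven_degrees(self):
        lm = make_landmarks((-80, -10, 0), (80, 10, 0))
        assert ear_axis_angle(lm) == pytest.approx(7.125, abs=1e-3)

    def test_degenerate_when_ears_have_no_x_separation(self):
        lm = make_landmarks((0, -50, 0), (0, 50, 0))
        with pytest.raises(DegenerateGeometryError):
            ear_axis_angle(lm)

    def test_quadrant_aware_variant_handles_flipped_axis(self):
        # subject facing away: right ear on image left
        lm = make_landmarks((75, 0, 0), (-75, 0, 0))
        assert ear_axis_angle(lm, quadrant_aware=True) == pytest.approx(180.0)
        assert ear_axis_angle(lm) == pytest.approx(0.0)


class TestApproachOffset:
    @pytest.mark.parametrize("theta, expected", [
        (0.0, 100.0),                       # level head: full 100 mm reach
        (60.0, 50.0),
        (7.125, 100.0 * math.cos(math.radians(7.125))),
    ])
    def test_cosine_foreshortening(self, theta, expected):
        assert approach_offset(theta) == pytest.approx(expected, abs=1e-9)

    def test_third_example_value(self):
        assert approach_offset(7.125) == pytest.approx(99.23, abs=5e-3)

    @given(st.floats(min_value=0.5, max_value=89.0))
    def test_monotone_decreasing_in_abs_theta(self, theta):
        eps = 0.25
        assert approach_offset(theta) > approach_offset(theta + eps)
        assert approach_offset(-theta) > approach_offset(-theta - eps)

    def test_rejects_angles_outside_open_interval(self):
        with pytest.raises(ValueError):
            approach_offset(90.0)


class TestTargetXY:
    def test_level_head_at_origin(self):
        tx, ty = target_xy((0.0, 0.0), 0.0)
        assert tx == pytest.approx(-100.0 * math.tan(math.radians(36.0)))
        assert tx == pytest.approx(-72.654, abs=5e-4)
        assert ty == pytest.approx(100.0)

    def test_nine_degree_roll_gives_unit_tangent(self):
        # 36 + 9 = 45 degrees: tan = 1, so |target_x - MP_x| = alpha
        tx, ty = target_xy((0.0, 0.0), 9.0)
        alpha = 100.0 * math.cos(math.radians(9.0))
        assert tx == pytest.approx(-alpha)
        assert ty == pytest.approx(alpha)
        assert (tx, ty) == pytest.approx((-98.769, 98.769), abs=5e-4)

    def test_translation_equivariance(self):
        tx0, ty0 = target_xy((0.0, 0.0), 0.0)
        tx, ty = target_xy((10.0, 20.0), 0.0)
        assert (tx, ty) == pytest.approx((tx0 + 10.0, ty0 + 20.0))
        assert (tx, ty) == pytest.approx((-62.654, 120.0), abs=5e-4)

    def test_tangent_blowup_guard(self):
        with pytest.raises(DegenerateGeometryError):
            target_xy((0.0, 0.0), 53.8)  # 36 + 53.8 = 89.8, within guard

    @given(st.floats(-30, 30), st.floats(-200, 200), st.floats(-200, 200))
    def test_matches_direct_formula(self, theta, mpx, mpy):
        tx, ty = target_xy((mpx, mpy), theta)
        alpha = 100.0 * math.cos(math.radians(theta))
        assert tx == pytest.approx(
            mpx - alpha * math.tan(math.radians(36.0 + theta)), rel=1e-12)
        assert ty == pytest.approx(mpy + alpha, rel=1e-12)


class TestHeadPose:
    def test_symmetric_head_has_zero_pose(self, symmetric_landmarks):
        pose = estimate_head_pose(symmetric_landmarks)
        assert pose.roll == pytest.approx(0.0)
        assert pose.pitch == pytest.approx(0.0)

    def test_roll_from_raised_right_ear(self):
        lm = make_landmarks((-80, -5, 0), (80, 5, 0))
        pose = estimate_head_pose(lm)
        assert pose.roll == pytest.approx(math.degrees(math.atan(10 / 160)))
        assert pose.roll == pytest.approx(3.576, abs=1e-3)

    def test_pitch_from_raised_nasion(self):
        lm = make_landmarks((-75, 0, 0), (75, 0, 0), nasion=(0, 20, 90))
        pose = estimate_head_pose(lm)
        assert pose.pitch == pytest.approx(math.degrees(math.atan(20 / 90)))
        assert pose.pitch == pytest.approx(12.529, abs=1e-3)

    def test_degenerate_triangle_rejected(self):
        lm = make_landmarks((-75, 0, 0), (75, 0, 0), nasion=(0, 40, 0))
        with pytest.raises(DegenerateGeometryError):
            estimate_head_pose(lm)


class TestVertexEstimate:
    def test_symmetric_head_vertex_centred(self, symmetric_landmarks):
        v = estimate_vertex(symmetric_landmarks)
        assert v[0] == pytest.approx(0.0, abs=1e-12)
        assert v[2] == pytest.approx(0.0, abs=1e-12)
        assert v[1] > 0  # lifted toward the vertex

    def test_translation_equivariance(self, symmetric_landmarks):
        v0 = estimate_vertex(symmetric_landmarks)
        v1 = estimate_vertex(symmetric_landmarks.translated((10.0, 0.0, 0.0)))
        assert v1 == pytest.approx(v0 + np.array([10.0, 0.0, 0.0]))

    def test_vertex_tilts_with_rolled_ear_axis(self):
        lm = make_landmarks((-80, -5, 0), (80, 5, 0))
        v = estimate_vertex(lm, lift=80.0)
        mp = lm.preauricular_midpoint
        up = (v - mp) / np.linalg.norm(v - mp)
        tilt = math.degrees(math.acos(np.clip(up[1], -1, 1)))
        assert tilt == pytest.approx(math.degrees(math.atan(10 / 160)),
                                     abs=1e-9)

    def test_centroid_mode_uses_all_three_points(self, symmetric_landmarks):
        v = estimate_vertex(symmetric_landmarks, mode="centroid")
        assert v[2] == pytest.approx(90.0 / 3.0)


class TestLocalizeC3:
    def test_symmetric_head_composition(self, symmetric_landmarks):
        t = localize_c3(symmetric_landmarks)
        assert t.ear_axis_angle_theta == pytest.approx(0.0)
        assert t.offset_alpha == pytest.approx(100.0)
        assert t.c3_arc_angle == pytest.approx(36.0)
        assert (t.target_x, t.target_y) == pytest.approx((-72.654, 100.0),
                                                         abs=5e-4)
        assert t.target_z == pytest.approx(0.0)  # depth passes through

    def test_coincident_ears_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            make_landmarks((10.0, 0, 0), (10.0, 0, 0))

    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_translation_equivariance(self, dx, dy):
        lm = make_landmarks((-80, -10, 5), (80, 10, 5), nasion=(2, 5, 95))
        t0 = localize_c3(lm)
        t1 = localize_c3(lm.translated((dx, dy, 0.0)))
        assert t1.target_x == pytest.approx(t0.target_x + dx, abs=1e-9)
        assert t1.target_y == pytest.approx(t0.target_y + dy, abs=1e-9)

    def test_matches_independent_evaluation_on_random_heads(self):
        """Pipeline output equals a from-scratch evaluation of the target
        equations on 1,000 random landmark configurations."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            left = np.array([-80, 0, 0]) + rng.uniform(-20, 20, 3)
            right = np.array([80, 0, 0]) + rng.uniform(-20, 20, 3)
            nasion = np.array([0, 0, 95]) + rng.uniform(-20, 20, 3)
            if abs(right[0] - left[0]) < 1.0:
                continue
            ear = right - left
            theta = math.degrees(math.atan(ear[1] / ear[0]))
            if abs(36.0 + theta - 90.0) < 0.5:
                continue
            alpha = 100.0 * math.cos(math.radians(theta))
            mp = 0.5 * (left + right)
            ex = mp[0] - alpha * math.tan(math.radians(36.0 + theta))
            ey = mp[1] + alpha
            t = localize_c3(HeadLandmarks(nasion, left, right))
            assert t.target_x == pytest.approx(ex, rel=1e-9, abs=1e-9)
            assert t.target_y == pytest.approx(ey, rel=1e-9, abs=1e-9)

    def test_pitch_correction_is_identity_for_level_head(
            self, symmetric_landmarks):
        t0 = localize_c3(symmetric_landmarks)
        t1 = localize_c3(symmetric_landmarks, pose_correct=True)
        assert t1.target_x == pytest.approx(t0.target_x, abs=1e-9)
        assert t1.target_y == pytest.approx(t0.target_y, abs=1e-9)

    def test_pitch_correction_changes_pitched_head_result(self):
        lm = make_landmarks((-75, 0, 0), (75, 0, 0), nasion=(0, 30, 85))
        t0 = localize_c3(lm)
        t1 = localize_c3(lm, pose_correct=True)
        assert t0.target_x == pytest.approx(t1.target_x)  # pitch is about x
        assert t1.target_y != pytest.approx(t0.target_y, abs=1e-6)
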