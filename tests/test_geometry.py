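"""Ellipse fitting, vertical extent, rotation angle, and calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mouthkit.geometry import (
    CalibrationError,
    EllipseFit,
    EllipseFitError,
    LandmarkFrame,
    align_to_eye_line,
    ellipse_points,
    fit_ellipse_points,
    fit_mouth_ellipse,
    interocular_scale,
    measure_frame,
    rotation_angle,
    vertical_extent,
)

from conftest import make_frame


def geometric_fit_oracle(pts):
    """Brute-force geometric (radial-residual) ellipse fit with multi-start."""
    from scipy.optimize import least_squares

    def resid(params):
        cx, cy, a, b, phi = params
        c, s = np.cos(phi), np.sin(phi)
        u = (pts - [cx, cy]) @ np.array([[c, s], [-s, c]]).T
        rp = np.hypot(u[:, 0], u[:, 1])
        psi = np.arctan2(u[:, 1], u[:, 0])
        re = a * b / np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)
        return rp - re

    span = pts.max(axis=0) - pts.min(axis=0)
    best = None
    for phi0 in np.linspace(-np.pi / 2, np.pi / 2, 7):
        x0 = [pts[:, 0].mean(), pts[:, 1].mean(), span.max() / 2, span.min() / 2, phi0]
        r = least_squares(resid, x0, method="lm")
        if best is None or r.cost < best.cost:
            best = r
    cx, cy, a, b, phi = best.x
    a, b = abs(a), abs(b)
    phi = math.degrees(phi)
    if a < b:
        a, b = b, a
        phi += 90.0
    phi = (phi + 90.0) % 180.0 - 90.0
    if phi <= -90.0:
        phi += 180.0
    return cx, cy, a, b, phi


class TestFit:
    def test_exact_recovery_axis_aligned(self):
        pts = ellipse_points((10, 20), 30, 12, 0, 20)
        f = fit_ellipse_points(pts)
        assert f.center == pytest.approx((10, 20), abs=1e-6)
        assert f.a == pytest.approx(30, abs=1e-6)
        assert f.b == pytest.approx(12, abs=1e-6)
        assert f.phi_deg == pytest.approx(0, abs=1e-6)
        assert f.rms_residual < 1e-9

    def test_rotation_equivariance(self):
        f = fit_ellipse_points(ellipse_points((10, 20), 30, 12, 25, 20))
        assert f.phi_deg == pytest.approx(25, abs=1e-6)
        assert (f.a, f.b) == pytest.approx((30, 12), abs=1e-6)

    def test_jittered_fit_matches_geometric_oracle(self, rng):
        pts = ellipse_points((10, 20), 30, 12, 10, 20) + rng.normal(0, 0.5, (20, 2))
        f = fit_ellipse_points(pts)
        cx, cy, a, b, phi = geometric_fit_oracle(pts)
        assert f.center == pytest.approx((cx, cy), abs=0.5)
        assert f.a == pytest.approx(a, abs=0.5)
        assert f.b == pytest.approx(b, abs=0.5)
        assert f.phi_deg == pytest.approx(phi, abs=1.0)

    def test_agrees_with_independent_library_fit(self, rng):
        skimage = pytest.importorskip("skimage.measure")
        pts = ellipse_points((5, -3), 22, 9, -35, 20) + rng.normal(0, 0.3, (20, 2))
        f = fit_ellipse_points(pts)
        m = skimage.EllipseModel.from_estimate(pts)
        assert m
        (cx, cy), (a, b), phi = m.center, m.axis_lengths, m.theta
        if a < b:
            a, b = b, a
            phi += np.pi / 2
        phi = math.degrees(phi)
        phi = (phi + 90.0) % 180.0 - 90.0
        assert f.center == pytest.approx((cx, cy), abs=0.3)
        assert (f.a, f.b) == pytest.approx((a, b), abs=0.3)

    def test_fit_idempotence(self, rng):
        for _ in range(20):
            a = rng.uniform(5, 50)
            b = rng.uniform(1, a)
            phi = rng.uniform(-89, 90)
            f0 = fit_ellipse_points(ellipse_points(rng.uniform(-100, 100, 2), a, b, phi, 20))
            f1 = fit_ellipse_points(ellipse_points(f0.center, f0.a, f0.b, f0.phi_deg, 20))
            assert f1.a == pytest.approx(f0.a, abs=1e-6)
            assert f1.b == pytest.approx(f0.b, abs=1e-6)

    @pytest.mark.parametrize(
        "pts,match",
        [
            (np.array([[0, 0], [1, 1], [2, 2], [3, 3]]), "5"),
            (np.column_stack([np.arange(8.0), 2 * np.arange(8.0)]), "collinear"),
            (np.zeros((6, 2)), "coincident|collinear"),
        ],
    )
    def test_degenerate_inputs_raise(self, pts, match):
        with pytest.raises(EllipseFitError, match=match):
            fit_ellipse_points(pts)

    def test_frame_error_names_frame(self):
        frame = make_frame()
        pts = frame.points.copy()
        pts[48:68, 1] = 100.0  # collapse mouth to a line
        bad = LandmarkFrame(frame_id=7, timestamp=0.0, points=pts)
        with pytest.raises(EllipseFitError, match="frame 7"):
            fit_mouth_ellipse(bad)


class TestVerticalExtent:
    @pytest.mark.parametrize(
        "a,b,phi,expected",
        [
            (30, 12, 0, 24.0),
            (30, 12, 90, 60.0),
            (30, 12, 30, 2 * math.sqrt(900 * 0.25 + 144 * 0.75)),
        ],
    )
    def test_closed_form(self, a, b, phi, expected):
        assert vertical_extent(EllipseFit((0, 0), a, b, phi, 0.0)) == pytest.approx(expected, rel=1e-12)

    def test_matches_dense_boundary_maximizer(self, rng):
        t = np.linspace(0, 2 * np.pi, 10_000)
        for _ in range(200):
            a = rng.uniform(1, 100)
            b = rng.uniform(0.1, a)
            phi = rng.uniform(-89.999, 90)
            f = EllipseFit((0, 0), a, b, phi, 0.0)
            y = ellipse_points((0, 0), a, b, phi, 10_000)[:, 1]
            dense = y.max() - y.min()
            assert vertical_extent(f) == pytest.approx(dense, rel=1e-6)


class TestRotationAngle:
    def test_zero_inclination(self):
        assert rotation_angle(EllipseFit((0, 0), 30, 12, 0, 0.0)) == 0.0

    def test_circle_reduces_to_phi(self):
        assert rotation_angle(EllipseFit((0, 0), 10, 10, 37, 0.0)) == pytest.approx(37.0)

    def test_worked_value(self):
        assert rotation_angle(EllipseFit((0, 0), 24, 12, 45, 0.0)) == pytest.approx(
            math.degrees(math.atan(0.5)), rel=1e-12
        )

    @given(st.floats(-89.9, 89.9), st.floats(1.01, 50.0), st.floats(0.1, 1.0))
    @settings(max_examples=100, derandomize=True)
    def test_odd_and_bounded(self, phi, a, ratio):
        b = a * ratio
        theta = rotation_angle(EllipseFit((0, 0), a, b, phi, 0.0))
        theta_neg = rotation_angle(EllipseFit((0, 0), a, b, -phi, 0.0))
        assert theta == pytest.approx(-theta_neg, abs=1e-9)
        assert abs(theta) <= abs(phi) + 1e-9


class TestCalibration:
    def test_listed_formula(self):
        frame = make_frame(eye_distance_px=70.0)
        assert interocular_scale(frame, 3.5) == pytest.approx(0.05)

    def test_homogeneity(self):
        frame = make_frame()
        k = 3.7
        scaled = LandmarkFrame(0, 0.0, frame.points * k, frame.index_map)
        assert interocular_scale(scaled) == pytest.approx(interocular_scale(frame) / k)

    def test_coincident_eyes_error(self):
        frame = make_frame()
        pts = frame.points.copy()
        pts[42] = pts[39]
        bad = LandmarkFrame(0, 0.0, pts)
        with pytest.raises(CalibrationError):
            interocular_scale(bad)


class TestMeasureFrame:
    def test_forward_inversion(self):
        m = measure_frame(make_frame(opening_mm=38.0, eye_distance_px=70.0))
        assert m.opening_px == pytest.approx(76.0, rel=1e-9)
        assert m.opening_mm == pytest.approx(38.0, rel=1e-9)

    def test_scale_invariance(self, rng):
        frame = make_frame(opening_mm=27.0, phi_deg=6.0)
        m0 = measure_frame(frame)
        for k in (0.1, 2.0, 40.0):
            mk = measure_frame(LandmarkFrame(0, 0.0, frame.points * k, frame.index_map))
            assert mk.opening_mm == pytest.approx(m0.opening_mm, rel=1e-9)
            assert mk.theta_deg == pytest.approx(m0.theta_deg, rel=1e-9)

    def test_eye_line_alignment_removes_roll(self):
        frame = make_frame(opening_mm=30.0, phi_deg=5.0)
        m0 = measure_frame(frame)
        ang = math.radians(20.0)
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        rolled = LandmarkFrame(0, 0.0, frame.points @ rot.T, frame.index_map)
        m1 = measure_frame(rolled)
        assert m1.opening_mm == pytest.approx(m0.opening_mm, rel=1e-9)
        assert m1.theta_deg == pytest.approx(m0.theta_deg, abs=1e-9)
        aligned = align_to_eye_line(rolled)
        left, right = aligned.eye_points
        assert left[1] == pytest.approx(right[1], abs=1e-9)

    def test_too_few_mouth_points_rejected(self):
        frame = make_frame()
        with pytest.raises(ValueError, match=">= 5"):
            LandmarkFrame(0, 0.0, frame.points, {"left_eye_inner": 39, "right_eye_inner": 42, "mouth_contour": [48, 49, 50, 51]})
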