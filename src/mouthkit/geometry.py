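"""Calibrated oral-region geometry from 2D facial landmarks.

Pipeline: fit an ellipse to the mouth contour, take its exact vertical
extent as the mouth opening, derive the symmetry rotation angle
``theta = arctan(b sin(phi) / (a cos(phi)))`` from the ellipse inclination,
and convert pixels to physical units via the interocular distance
(anthropometric inner-eye-corner reference, 3.5 cm by default).

All measurements are taken in a face-aligned frame: landmarks are rotated
so the interocular line is horizontal before fitting, which makes opening
(mm) and theta (deg) exactly invariant to in-plane head roll and to uniform
rescaling of the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LandmarkFrame",
    "EllipseFit",
    "CalibratedMeasure",
    "EllipseFitError",
    "CalibrationError",
    "DEFAULT_INDEX_MAP",
    "fit_mouth_ellipse",
    "vertical_extent",
    "rotation_angle",
    "interocular_scale",
    "align_to_eye_line",
    "measure_frame",
    "ellipse_points",
]

#: 68-point landmark convention: inner eye corners at 39/42 (0-based),
#: mouth contour at 48..67. Overridable per frame via ``index_map``.
DEFAULT_INDEX_MAP: dict = {
    "left_eye_inner": 39,
    "right_eye_inner": 42,
    "mouth_contour": list(range(48, 68)),
}


class EllipseFitError(ValueError):
    """Raised when the mouth contour cannot be fit by an ellipse."""


class CalibrationError(ValueError):
    """Raised when interocular calibration is impossible."""


@dataclass(frozen=True)
class LandmarkFrame:
    """One timestamped set of 2D facial landmarks in pixel coordinates."""

    frame_id: int
    timestamp: float
    points: np.ndarray  # (n_landmarks, 2) float array
    index_map: Mapping = field(default_factory=lambda: DEFAULT_INDEX_MAP)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        if self.timestamp < 0:
            raise ValueError("timestamp must be non-negative")
        n = pts.shape[0]
        for role in ("left_eye_inner", "right_eye_inner"):
            idx = self.index_map[role]
            if not 0 <= idx < n:
                raise ValueError(f"index_map[{role!r}]={idx} out of range for {n} landmarks")
        contour = list(self.index_map["mouth_contour"])
        if len(contour) < 5:
            raise ValueError("mouth_contour needs >= 5 landmark ids")
        if any(not 0 <= i < n for i in contour):
            raise ValueError("mouth_contour indices out of range")

    @property
    def mouth_points(self) -> np.ndarray:
        return self.points[list(self.index_map["mouth_contour"])]

    @property
    def eye_points(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.points[self.index_map["left_eye_inner"]],
            self.points[self.index_map["right_eye_inner"]],
        )


@dataclass(frozen=True)
class EllipseFit:
    """Fitted ellipse: center, semi-axes a >= b, inclination in (-90, 90]."""

    center: tuple[float, float]
    a: float
    b: float
    phi_deg: float
    rms_residual: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if not (-90.0 < self.phi_deg <= 90.0):
            raise ValueError("inclination must lie in (-90, 90] degrees")
        if self.rms_residual < 0:
            raise ValueError("residual must be non-negative")

    def to_dict(self) -> dict:
        return {
            "center": [self.center[0], self.center[1]],
            "a": self.a,
            "b": self.b,
            "phi_deg": self.phi_deg,
            "rms_residual": self.rms_residual,
        }


@dataclass(frozen=True)
class CalibratedMeasure:
    """Per-frame calibrated measurement: opening in mm and symmetry angle."""

    opening_px: float
    scale: float  # cm per pixel
    opening_mm: float
    theta_deg: float
    frame_id: int | None = None
    timestamp: float | None = None
    fit: EllipseFit | None = None

    def to_dict(self) -> dict:
        d = {
            "opening_px": self.opening_px,
            "scale": self.scale,
            "opening_mm": self.opening_mm,
            "theta_deg": self.theta_deg,
        }
        if self.frame_id is not None:
            d["frame_id"] = self.frame_id
        if self.timestamp is not None:
            d["timestamp"] = self.timestamp
        if self.fit is not None:
            d["fit"] = self.fit.to_dict()
        return d


def ellipse_points(
    center: Sequence[float],
    a: float,
    b: float,
    phi_deg: float,
    n: int = 20,
) -> np.ndarray:
    """Sample ``n`` evenly spaced points on an ellipse boundary."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    phi = math.radians(phi_deg)
    c, s = math.cos(phi), math.sin(phi)
    x = center[0] + a * np.cos(t) * c - b * np.sin(t) * s
    y = center[1] + a * np.cos(t) * s + b * np.sin(t) * c
    return np.column_stack([x, y])


def _fit_conic_halir_flusser(pts: np.ndarray) -> np.ndarray:
    """Stable direct least-squares conic fit constrained to ellipses.

    Returns conic coefficients (A, B, C, D, E, F) for
    A x^2 + B x y + C y^2 + D x + E y + F = 0 with B^2 - 4AC < 0.
    """
    x, y = pts[:, 0], pts[:, 1]
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError(f"degenerate mouth contour (singular moment matrix): {exc}") from exc
    m = s1 + s2 @ t
    # inverse-constraint scatter: C^-1 M with C = [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.where(np.isreal(eigval) & (cond > 0))[0]
    if len(ok) == 0:
        raise EllipseFitError("least-squares conic is not an ellipse")
    a1 = np.real(eigvec[:, ok[0]])
    coeffs = np.concatenate([a1, t @ a1])
    return coeffs


def _conic_to_ellipse(coeffs: np.ndarray) -> tuple[float, float, float, float, float]:
    """Convert conic coefficients to (x0, y0, a, b, phi_deg), canonicalized."""
    A, B, C, D, E, F = coeffs
    disc = B * B - 4.0 * A * C
    if disc >= 0:
        raise EllipseFitError("conic discriminant is non-negative (not an ellipse)")
    x0 = (2.0 * C * D - B * E) / disc
    y0 = (2.0 * A * E - B * D) / disc
    # conic value at the center
    fc = A * x0 * x0 + B * x0 * y0 + C * y0 * y0 + D * x0 + E * y0 + F
    q = np.array([[A, B / 2.0], [B / 2.0, C]])
    eigval, eigvec = np.linalg.eigh(q)
    with np.errstate(invalid="ignore", divide="ignore"):
        axes_sq = -fc / eigval
    if np.any(axes_sq <= 0) or not np.all(np.isfinite(axes_sq)):
        raise EllipseFitError("conic has no real ellipse axes (degenerate fit)")
    axes = np.sqrt(axes_sq)
    # major axis = eigenvector of the smaller |eigenvalue|
    major = int(np.argmax(axes))
    a, b = float(axes[major]), float(axes[1 - major])
    vx, vy = eigvec[:, major]
    phi = math.degrees(math.atan2(vy, vx))
    # canonicalize inclination into (-90, 90]
    if phi <= -90.0:
        phi += 180.0
    elif phi > 90.0:
        phi -= 180.0
    return float(x0), float(y0), a, b, phi


def _sampson_rms(coeffs: np.ndarray, pts: np.ndarray) -> float:
    """RMS orthogonal-approximation (Sampson) residual of a conic fit."""
    A, B, C, D, E, F = coeffs
    x, y = pts[:, 0], pts[:, 1]
    val = A * x * x + B * x * y + C * y * y + D * x + E * y + F
    gx = 2.0 * A * x + B * y + D
    gy = B * x + 2.0 * C * y + E
    grad = np.hypot(gx, gy)
    grad = np.where(grad == 0, np.finfo(float).tiny, grad)
    return float(np.sqrt(np.mean((val / grad) ** 2)))


def fit_ellipse_points(pts: np.ndarray) -> EllipseFit:
    """Fit an ellipse to an (n, 2) point array by direct least squares."""
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise EllipseFitError("expected an (n, 2) point array")
    if pts.shape[0] < 5:
        raise EllipseFitError(f"need >= 5 contour points, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise EllipseFitError("contour contains non-finite coordinates")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(pts).max())) < 2:
        raise EllipseFitError("contour points are collinear")
    # isotropic normalization for conditioning; undone below
    mean = pts.mean(axis=0)
    scale = float(np.mean(np.abs(centered)))
    if scale == 0:
        raise EllipseFitError("contour points are coincident")
    norm = centered / scale
    coeffs_n = _fit_conic_halir_flusser(norm)
    x0n, y0n, a_n, b_n, phi = _conic_to_ellipse(coeffs_n)
    x0 = x0n * scale + mean[0]
    y0 = y0n * scale + mean[1]
    a, b = a_n * scale, b_n * scale
    # residual in original pixel units: denormalize the conic
    A, B, C, D, E, F = coeffs_n
    mx, my = mean
    coeffs = np.array(
        [
            A,
            B,
            C,
            scale * D - 2 * A * mx - B * my,
            scale * E - B * mx - 2 * C * my,
            scale * scale * F + A * mx * mx + B * mx * my + C * my * my - scale * (D * mx + E * my),
        ]
    )
    rms = _sampson_rms(coeffs, pts)
    return EllipseFit(center=(x0, y0), a=a, b=b, phi_deg=phi, rms_residual=rms)


def fit_mouth_ellipse(frame: LandmarkFrame) -> EllipseFit:
    """Least-squares ellipse through the frame's mouth contour."""
    try:
        return fit_ellipse_points(frame.mouth_points)
    except EllipseFitError as exc:
        raise EllipseFitError(f"frame {frame.frame_id}: {exc}") from exc


def vertical_extent(fit: EllipseFit) -> float:
    """Exact vertical extent of the rotated ellipse.

    The highest and lowest boundary points of an ellipse with semi-axes
    (a, b) and inclination phi are separated by
    ``2 * sqrt(a^2 sin^2(phi) + b^2 cos^2(phi))``.
    """
    phi = math.radians(fit.phi_deg)
    return 2.0 * math.hypot(fit.a * math.sin(phi), fit.b * math.cos(phi))


def rotation_angle(fit: EllipseFit) -> float:
    """Symmetry rotation angle theta = arctan(b sin(phi) / (a cos(phi))), degrees.

    Signed; grading uses the magnitude. Computed with the two-argument
    arctangent so phi = 90 deg is well defined. Reduces to theta = phi for
    a circle (a == b), and |theta| <= |phi| whenever b <= a.
    """
    phi = math.radians(fit.phi_deg)
    return math.degrees(math.atan2(fit.b * math.sin(phi), fit.a * math.cos(phi)))


def interocular_scale(frame: LandmarkFrame, reference_cm: float = 3.5) -> float:
    """cm-per-pixel scale from the inner-eye-corner distance.

    ``scale = reference_cm / ||p_left - p_right||``; the 3.5 cm default is
    the anthropometric mean inner-canthal distance.
    """
    if reference_cm <= 0:
        raise CalibrationError("reference_cm must be positive")
    left, right = frame.eye_points
    dist = float(np.hypot(*(left - right)))
    if dist == 0:
        raise CalibrationError(f"frame {frame.frame_id}: coincident eye landmarks, cannot calibrate")
    return reference_cm / dist


def align_to_eye_line(frame: LandmarkFrame) -> LandmarkFrame:
    """Rotate landmarks about the eye midpoint so the eye line is horizontal.

    Removes in-plane head roll so vertical extent and theta are measured
    relative to the face axis, not the camera axis.
    """
    left, right = frame.eye_points
    delta = right - left
    if float(np.hypot(*delta)) == 0:
        raise CalibrationError(f"frame {frame.frame_id}: coincident eye landmarks, cannot align")
    ang = math.atan2(delta[1], delta[0])
    c, s = math.cos(-ang), math.sin(-ang)
    rot = np.array([[c, -s], [s, c]])
    mid = (left + right) / 2.0
    pts = (frame.points - mid) @ rot.T + mid
    return LandmarkFrame(
        frame_id=frame.frame_id,
        timestamp=frame.timestamp,
        points=pts,
        index_map=frame.index_map,
    )


def measure_frame(frame: LandmarkFrame, config=None) -> CalibratedMeasure:
    """Calibrated opening (mm) and symmetry angle (deg) for one frame.

    Aligns the frame to the interocular line, fits the mouth ellipse,
    computes the exact vertical extent and theta, and converts to mm with
    the interocular scale: ``opening_mm = extent_px * scale_cm_per_px * 10``.
    All intermediates are retained on the returned measure for audit.
    """
    reference_cm = 3.5 if config is None else config.reference_cm
    aligned = align_to_eye_line(frame)
    fit = fit_mouth_ellipse(aligned)
    scale = interocular_scale(aligned, reference_cm)
    opening_px = vertical_extent(fit)
    return CalibratedMeasure(
        opening_px=opening_px,
        scale=scale,
        opening_mm=opening_px * scale * 10.0,
        theta_deg=rotation_angle(fit),
        frame_id=frame.frame_id,
        timestamp=frame.timestamp,
        fit=fit,
    )
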