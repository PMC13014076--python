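"""Synthetic mouth-opening exercise sequences with exact ground truth.

A parametric 3D face template (inner eye corners 3.5 cm apart, mouth
contour of 20 points on an ellipse) performs an open-hold-release exercise:
the ellipse's vertical extent follows a piecewise-linear ramp/plateau/release
profile of the true opening in mm. Frames are produced by rotating the
template (pitch/yaw/roll), projecting orthographically, scaling to pixels,
and adding seeded Gaussian landmark jitter. Every frame carries exact truth
(opening mm, inclination, symmetry angle theta, grade), so the measurement
and grading pipeline can be validated in closed loop.

The orthographic projection makes pose biases analytic: yaw shrinks the
interocular distance by cos(yaw), inflating recovered openings by
1/cos(yaw); pitch shrinks vertical extents by cos(pitch); roll is an
in-plane isometry and leaves recovered openings unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .geometry import DEFAULT_INDEX_MAP, EllipseFit, LandmarkFrame, rotation_angle
from .grading import grade_opening
from .splitting import SampleRecord

__all__ = [
    "SyntheticFaceConfig",
    "CohortSpec",
    "GroundTruth",
    "SimulatedSequence",
    "GRADE_PEAK_INTERVALS_MM",
    "simulate_sequence",
    "apply_pose_perturbation",
    "generate_cohort",
    "opening_profile",
]

#: Peak-opening sampling intervals per grade (mm). The F1 floor of 5 mm is
#: a realistic severe-restriction minimum (the grade itself is open below).
GRADE_PEAK_INTERVALS_MM: dict = {
    "F1": (5.0, 15.0),
    "F2": (15.0, 25.0),
    "F3": (25.0, 35.0),
    "F4": (35.0, 50.0),
}

_MIN_SEMI_VERTICAL_CM = 0.05  # floors the profile away from a degenerate sliver
_MOUTH_CENTER_CM = np.array([0.0, -5.0, 0.0])
_IMAGE_CENTER_PX = np.array([320.0, 240.0])


@dataclass(frozen=True)
class SyntheticFaceConfig:
    """Generative parameters of one synthetic exercise sequence."""

    peak_mm: float = 38.0
    rest_mm: float = 2.0
    ramp_s: float = 1.5
    hold_s: float = 3.0
    release_s: float = 1.5
    interocular_cm: float = 3.5
    mouth_width_cm: float = 6.0
    phi_deg: float = 0.0  # ellipse inclination (asymmetry), face-relative
    px_per_cm: float = 20.0
    distance_multiplier: float = 1.0
    pitch_deg: float = 0.0
    yaw_deg: float = 0.0
    roll_deg: float = 0.0
    jitter_sigma_px: float = 0.0
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_mm < 0:
            raise ValueError("peak_mm must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.interocular_cm <= 0 or self.mouth_width_cm <= 0:
            raise ValueError("face dimensions must be positive")
        if self.px_per_cm <= 0 or self.distance_multiplier <= 0:
            raise ValueError("camera parameters must be positive")
        for ang in (self.pitch_deg, self.yaw_deg, self.roll_deg):
            if abs(ang) > 90:
                raise ValueError("pose angles must satisfy |angle| <= 90 deg")
        if abs(self.phi_deg) > 45:
            raise ValueError("inclination must satisfy |phi| <= 45 deg")
        if self.jitter_sigma_px < 0:
            raise ValueError("jitter sigma must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame and session-level truth for a simulated sequence."""

    opening_mm: np.ndarray  # exact vertical extent in face plane, per frame
    phi_deg: np.ndarray
    theta_deg: np.ndarray
    grades: tuple[str, ...]
    session_max_opening_mm: float
    session_grade: str
    session_theta_deg: float


@dataclass(frozen=True)
class SimulatedSequence:
    frames: tuple[LandmarkFrame, ...]
    truth: GroundTruth
    config: SyntheticFaceConfig


def opening_profile(config: SyntheticFaceConfig, t: np.ndarray) -> np.ndarray:
    """Piecewise-linear open-hold-release profile of true opening (mm)."""
    peak, rest = config.peak_mm, config.rest_mm
    r, h, rel = config.ramp_s, config.hold_s, config.release_s
    out = np.full_like(t, float(rest))
    if r > 0:
        ramp = t < r
        out[ramp] = rest + (peak - rest) * t[ramp] / r
    hold = (t >= r) & (t < r + h)
    out[hold] = peak
    if rel > 0:
        down = t >= r + h
        out[down] = np.maximum(rest, peak - (peak - rest) * (t[down] - r - h) / rel)
    else:
        out[t >= r + h] = peak
    return out


def _rotation_matrix(pitch_deg: float, yaw_deg: float, roll_deg: float) -> np.ndarray:
    """Rz(roll) @ Ry(yaw) @ Rx(pitch), angles in degrees."""
    p, y, r = (math.radians(a) for a in (pitch_deg, yaw_deg, roll_deg))
    rx = np.array([[1, 0, 0], [0, math.cos(p), -math.sin(p)], [0, math.sin(p), math.cos(p)]])
    ry = np.array([[math.cos(y), 0, math.sin(y)], [0, 1, 0], [-math.sin(y), 0, math.cos(y)]])
    rz = np.array([[math.cos(r), -math.sin(r), 0], [math.sin(r), math.cos(r), 0], [0, 0, 1]])
    return rz @ ry @ rx


def _static_template_cm(interocular_cm: float) -> np.ndarray:
    """68-point 3D template (cm, y up, z = 0 plane); mouth points are zeroed
    placeholders filled per frame."""
    pts = np.zeros((68, 3))
    half = interocular_cm / 2.0
    # jawline 0-16 on a face oval
    ang = np.linspace(math.pi, 2 * math.pi, 17)
    pts[0:17, 0] = 7.0 * np.cos(ang)
    pts[0:17, 1] = -2.0 + 9.0 * np.sin(ang)
    # brows 17-26
    pts[17:22, 0] = np.linspace(-4.0, -1.0, 5)
    pts[17:22, 1] = 1.5
    pts[22:27, 0] = np.linspace(1.0, 4.0, 5)
    pts[22:27, 1] = 1.5
    # nose bridge 27-30 and base 31-35
    pts[27:31, 0] = 0.0
    pts[27:31, 1] = np.linspace(0.5, -2.0, 4)
    pts[31:36, 0] = np.linspace(-1.0, 1.0, 5)
    pts[31:36, 1] = -2.8
    # left eye 36-41 (39 = inner corner), right eye 42-47 (42 = inner corner)
    eye_dx = np.array([-1.2, -0.8, -0.4, 0.0, -0.4, -0.8])
    eye_dy = np.array([0.0, 0.25, 0.25, 0.0, -0.25, -0.25])
    pts[36:42, 0] = -half + eye_dx
    pts[36:42, 1] = eye_dy
    pts[42:48, 0] = half + np.array([0.0, 0.4, 0.8, 1.2, 0.8, 0.4])
    pts[42:48, 1] = eye_dy
    return pts


def _semi_vertical_cm(extent_mm: float, half_width_cm: float, phi_deg: float) -> float:
    """Invert the vertical-extent formula for the vertical semi-axis."""
    phi = math.radians(phi_deg)
    half_extent = extent_mm / 10.0 / 2.0
    inside = half_extent**2 - (half_width_cm * math.sin(phi)) ** 2
    return math.sqrt(max(inside, 0.0)) / math.cos(phi)


def _min_extent_mm(half_width_cm: float, phi_deg: float) -> float:
    phi = math.radians(phi_deg)
    return 20.0 * math.hypot(half_width_cm * math.sin(phi), _MIN_SEMI_VERTICAL_CM * math.cos(phi))


def _truth_fit(half_width_cm: float, semi_vert_cm: float, phi_deg: float) -> EllipseFit:
    """Canonical EllipseFit of the generated (face-plane) mouth ellipse."""
    if half_width_cm >= semi_vert_cm:
        a, b, phi = half_width_cm, semi_vert_cm, phi_deg
    else:
        a, b, phi = semi_vert_cm, half_width_cm, phi_deg + 90.0
    if phi > 90.0:
        phi -= 180.0
    elif phi <= -90.0:
        phi += 180.0
    return EllipseFit(center=(0.0, 0.0), a=a, b=b, phi_deg=phi, rms_residual=0.0)


def simulate_sequence(
    config: SyntheticFaceConfig,
    extra_rotation: Optional[np.ndarray] = None,
) -> SimulatedSequence:
    """Simulate one exercise sequence with full ground truth.

    The profile drives the *true opening* (vertical extent of the mouth
    ellipse in the face plane, mm); the ellipse's vertical semi-axis is
    solved from it given the mouth width and inclination. The profile is
    floored at the smallest feasible extent for the configured geometry,
    so ground-truth grades are exactly the clinical grades of the
    generated openings.
    """
    a_cm = config.mouth_width_cm / 2.0
    floor_mm = _min_extent_mm(a_cm, config.phi_deg)
    duration = config.ramp_s + config.hold_s + config.release_s
    n_frames = int(round(duration * config.fps)) + 1
    t = np.arange(n_frames) / config.fps
    extents = np.maximum(opening_profile(config, t), floor_mm)

    r_base = _rotation_matrix(config.pitch_deg, config.yaw_deg, config.roll_deg)
    r_total = r_base if extra_rotation is None else extra_rotation @ r_base
    template = _static_template_cm(config.interocular_cm)
    ppx = config.px_per_cm / config.distance_multiplier
    rng = np.random.default_rng(config.seed)

    phi = math.radians(config.phi_deg)
    c_phi, s_phi = math.cos(phi), math.sin(phi)
    t_mouth = np.linspace(0.0, 2.0 * math.pi, 20, endpoint=False)
    cos_t, sin_t = np.cos(t_mouth), np.sin(t_mouth)

    frames = []
    openings = np.empty(n_frames)
    thetas = np.empty(n_frames)
    phis = np.empty(n_frames)
    grades = []
    for k in range(n_frames):
        b_cm = _semi_vertical_cm(extents[k], a_cm, config.phi_deg)
        pts3 = template.copy()
        mx = a_cm * cos_t * c_phi - b_cm * sin_t * s_phi
        my = a_cm * cos_t * s_phi + b_cm * sin_t * c_phi
        pts3[48:68, 0] = _MOUTH_CENTER_CM[0] + mx
        pts3[48:68, 1] = _MOUTH_CENTER_CM[1] + my
        pts3[48:68, 2] = _MOUTH_CENTER_CM[2]
        rotated = pts3 @ r_total.T
        px = np.empty((68, 2))
        px[:, 0] = _IMAGE_CENTER_PX[0] + rotated[:, 0] * ppx
        px[:, 1] = _IMAGE_CENTER_PX[1] - rotated[:, 1] * ppx  # image y is down
        if config.jitter_sigma_px > 0:
            px = px + rng.normal(0.0, config.jitter_sigma_px, size=px.shape)
        frames.append(
            LandmarkFrame(frame_id=k, timestamp=float(t[k]), points=px, index_map=DEFAULT_INDEX_MAP)
        )
        truth_fit = _truth_fit(a_cm, b_cm, config.phi_deg)
        openings[k] = extents[k]
        phis[k] = truth_fit.phi_deg
        thetas[k] = rotation_angle(truth_fit)
        grades.append(grade_opening(extents[k]).grade)

    peak_true = float(np.max(extents))
    peak_idx = int(np.argmax(extents))
    truth = GroundTruth(
        opening_mm=openings,
        phi_deg=phis,
        theta_deg=thetas,
        grades=tuple(grades),
        session_max_opening_mm=peak_true,
        session_grade=grade_opening(peak_true).grade,
        session_theta_deg=abs(float(thetas[peak_idx])),
    )
    return SimulatedSequence(frames=tuple(frames), truth=truth, config=config)


def apply_pose_perturbation(
    sim: SimulatedSequence,
    pitch_deg: float = 0.0,
    yaw_deg: float = 0.0,
    roll_deg: float = 0.0,
) -> SimulatedSequence:
    """Re-project the underlying 3D template under a composed rotation.

    The perturbation rotation is composed with the sequence's own pose;
    jitter is re-drawn from the sequence seed, so a zero perturbation
    reproduces the original frames bit for bit.
    """
    for ang in (pitch_deg, yaw_deg, roll_deg):
        if abs(ang) > 90:
            raise ValueError("perturbation angles must satisfy |angle| <= 90 deg")
    extra = _rotation_matrix(pitch_deg, yaw_deg, roll_deg)
    return simulate_sequence(sim.config, extra_rotation=extra)


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a grade-mixed synthetic cohort."""

    grade_mix: dict = field(default_factory=lambda: {"F1": 0.25, "F2": 0.25, "F3": 0.25, "F4": 0.25})
    n_patients: int = 40
    sessions_each: int = 1
    phi_range_deg: tuple[float, float] = (-3.0, 3.0)
    pitch_range_deg: tuple[float, float] = (0.0, 0.0)
    yaw_range_deg: tuple[float, float] = (0.0, 0.0)
    roll_range_deg: tuple[float, float] = (0.0, 0.0)
    jitter_sigma_px: float = 0.0
    boundary_margin_mm: float = 0.0
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grade_mix:
            raise ValueError("grade_mix must not be empty")
        if abs(sum(self.grade_mix.values()) - 1.0) > 1e-9:
            raise ValueError("grade_mix must sum to 1")
        if any(g not in GRADE_PEAK_INTERVALS_MM for g in self.grade_mix):
            raise ValueError("grade_mix keys must be F1..F4")
        if self.n_patients < 1 or self.sessions_each < 1:
            raise ValueError("need at least one patient and one session")


def _apportion(mix: dict, n: int) -> dict:
    """Largest-remainder apportionment of n patients to grades."""
    grades = sorted(mix)
    raw = {g: mix[g] * n for g in grades}
    counts = {g: int(math.floor(raw[g])) for g in grades}
    short = n - sum(counts.values())
    for g in sorted(grades, key=lambda g: (-(raw[g] - counts[g]), g))[:short]:
        counts[g] += 1
    return counts


def generate_cohort(spec: CohortSpec) -> tuple[list[SampleRecord], dict]:
    """Generate a grade-mixed cohort of patients with simulated sessions.

    Per-patient peak openings are drawn uniformly within the grade's mm
    interval (optionally shrunk by ``boundary_margin_mm`` at each end);
    inclination and pose are drawn per patient from the configured ranges.
    Returns records consumable by the splitting/metric modules and a
    mapping sample_id -> SimulatedSequence.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _apportion(spec.grade_mix, spec.n_patients)
    records: list[SampleRecord] = []
    sequences: dict = {}
    pid_n = 0
    for grade in sorted(counts):
        lo, hi = GRADE_PEAK_INTERVALS_MM[grade]
        lo += spec.boundary_margin_mm
        hi -= spec.boundary_margin_mm
        if lo >= hi:
            raise ValueError(f"boundary margin leaves no room in grade {grade}")
        for _ in range(counts[grade]):
            pid = f"P{pid_n:04d}"
            pid_n += 1
            peak = float(rng.uniform(lo, hi))
            phi = float(rng.uniform(*spec.phi_range_deg))
            pitch = float(rng.uniform(*spec.pitch_range_deg))
            yaw = float(rng.uniform(*spec.yaw_range_deg))
            roll = float(rng.uniform(*spec.roll_range_deg))
            for s in range(spec.sessions_each):
                cfg = SyntheticFaceConfig(
                    peak_mm=peak,
                    phi_deg=phi,
                    pitch_deg=pitch,
                    yaw_deg=yaw,
                    roll_deg=roll,
                    jitter_sigma_px=spec.jitter_sigma_px,
                    fps=spec.fps,
                    seed=int(rng.integers(2**31)),
                )
                sim = simulate_sequence(cfg)
                sid = f"{pid}_s{s:02d}"
                records.append(
                    SampleRecord(
                        sample_id=sid,
                        patient_id=pid,
                        grade=sim.truth.session_grade,
                        features=(peak, phi),
                    )
                )
                sequences[sid] = sim
    return records, sequences
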