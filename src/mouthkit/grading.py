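"""F1-F4 clinical grading of mouth opening and symmetry, session aggregation.

Opening grades (maximum mouth opening, mm): F1 severe restriction (<15),
F2 moderate (15-25), F3 mild (25-35), F4 normal (35-50). Symmetry grades
(ellipse rotation angle |theta|, deg): F4 good (<5), F3 mild asymmetry
(5-10), F2 moderate (10-15), F1 severe (>=15). Printed intervals share
endpoints; the implementation uses half-open intervals closed on the left,
so every finite input receives exactly one grade.

A session is aggregated with the maximum-aperture protocol: the subject
holds maximal opening for ~3 s; five samples are taken at evenly spaced
time points within the middle 1 s of the detected hold plateau, and their
mean is the session's maximum mouth opening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import CalibratedMeasure

__all__ = [
    "OpeningGrade",
    "SymmetryGrade",
    "SessionReport",
    "AdherenceLog",
    "ProtocolConfig",
    "OPENING_THRESHOLDS_MM",
    "SYMMETRY_THRESHOLDS_DEG",
    "OPENING_UPPER_NORMAL_MM",
    "grade_opening",
    "grade_symmetry",
    "aggregate_session",
    "weekly_counts",
]

#: Left edges of F2, F3, F4 opening intervals (mm); below the first is F1.
OPENING_THRESHOLDS_MM: tuple[float, float, float] = (15.0, 25.0, 35.0)
#: Left edges of F3, F2, F1 symmetry intervals (deg); below the first is F4.
SYMMETRY_THRESHOLDS_DEG: tuple[float, float, float] = (5.0, 10.0, 15.0)
#: Upper bound of the printed normal range; beyond it F4 is flagged.
OPENING_UPPER_NORMAL_MM: float = 50.0


@dataclass(frozen=True)
class OpeningGrade:
    grade: str
    opening_mm: float
    out_of_range_flag: bool

    def to_dict(self) -> dict:
        return {
            "grade": self.grade,
            "opening_mm": self.opening_mm,
            "out_of_range_flag": self.out_of_range_flag,
        }


@dataclass(frozen=True)
class SymmetryGrade:
    grade: str
    theta_deg: float  # absolute value

    def to_dict(self) -> dict:
        return {"grade": self.grade, "theta_deg": self.theta_deg}


@dataclass(frozen=True)
class ProtocolConfig:
    """Maximum-aperture measurement protocol parameters."""

    hold_seconds: float = 3.0
    window_seconds: float = 1.0
    n_samples: int = 5
    plateau_fraction: float = 0.95


@dataclass(frozen=True)
class SessionReport:
    session_id: str
    max_opening_mm: float
    opening_grade: OpeningGrade
    symmetry_theta_deg: float
    symmetry_grade: SymmetryGrade
    n_frames: int
    hold_window: tuple[float, float]
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "max_opening_mm": self.max_opening_mm,
            "opening_grade": self.opening_grade.to_dict(),
            "symmetry_theta_deg": self.symmetry_theta_deg,
            "symmetry_grade": self.symmetry_grade.to_dict(),
            "n_frames": self.n_frames,
            "hold_window": list(self.hold_window),
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class AdherenceLog:
    """Timestamps of completed training sessions."""

    session_times: tuple

    def __post_init__(self) -> None:
        times = tuple(pd.Timestamp(t) for t in self.session_times)
        object.__setattr__(self, "session_times", times)


def grade_opening(opening_mm: float) -> OpeningGrade:
    """Grade a maximum mouth opening in millimetres.

    F1 < 15 <= F2 < 25 <= F3 < 35 <= F4; openings above 50 mm stay F4
    with ``out_of_range_flag`` set (a measurement is never rejected for
    supranormal values).
    """
    if not math.isfinite(opening_mm) or opening_mm < 0:
        raise ValueError(f"opening_mm must be finite and non-negative, got {opening_mm}")
    t1, t2, t3 = OPENING_THRESHOLDS_MM
    if opening_mm < t1:
        grade = "F1"
    elif opening_mm < t2:
        grade = "F2"
    elif opening_mm < t3:
        grade = "F3"
    else:
        grade = "F4"
    return OpeningGrade(grade=grade, opening_mm=opening_mm, out_of_range_flag=opening_mm > OPENING_UPPER_NORMAL_MM)


def grade_symmetry(theta_deg: float) -> SymmetryGrade:
    """Grade mouth symmetry from the ellipse rotation angle (sign ignored).

    F4 |theta| < 5, F3 in [5, 10), F2 in [10, 15), F1 >= 15 degrees.
    """
    if not math.isfinite(theta_deg):
        raise ValueError(f"theta_deg must be finite, got {theta_deg}")
    t = abs(theta_deg)
    s1, s2, s3 = SYMMETRY_THRESHOLDS_DEG
    if t < s1:
        grade = "F4"
    elif t < s2:
        grade = "F3"
    elif t < s3:
        grade = "F2"
    else:
        grade = "F1"
    return SymmetryGrade(grade=grade, theta_deg=t)


def _longest_plateau(times: np.ndarray, openings: np.ndarray, fraction: float) -> tuple[int, int]:
    """Indices [i, j] (inclusive) of the longest run with opening >= fraction*max."""
    mask = openings >= fraction * openings.max()
    best = (0, 0)
    best_len = -1.0
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            run_len = times[j] - times[i]
            if run_len > best_len:
                best_len = run_len
                best = (i, j)
            i = j + 1
        else:
            i += 1
    return best


def aggregate_session(
    measures: Sequence[CalibratedMeasure],
    protocol: ProtocolConfig | None = None,
    session_id: str = "session",
) -> SessionReport:
    """Aggregate time-ordered per-frame measures into a session report.

    Detects the hold plateau (longest contiguous run at >= plateau_fraction
    of the sequence maximum), samples ``n_samples`` evenly spaced time
    points within the middle ``window_seconds`` of the plateau (nearest
    frame), and reports the mean opening and mean |theta| over those
    samples, with grades.
    """
    protocol = protocol or ProtocolConfig()
    if len(measures) == 0:
        raise ValueError("aggregate_session requires at least one measure")
    times = np.array([m.timestamp for m in measures], dtype=float)
    if np.any(~np.isfinite(times)):
        raise ValueError("all measures need finite timestamps")
    if np.any(np.diff(times) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    openings = np.array([m.opening_mm for m in measures], dtype=float)
    thetas = np.array([abs(m.theta_deg) for m in measures], dtype=float)

    warns: list[str] = []
    i0, i1 = _longest_plateau(times, openings, protocol.plateau_fraction)
    t_start, t_end = float(times[i0]), float(times[i1])
    window = times[i0 : i1 + 1]
    duration = t_end - t_start

    if duration < protocol.window_seconds:
        warns.append(
            f"hold window {duration:.3f}s shorter than {protocol.window_seconds}s; "
            "using all frames of the window"
        )
        sel = np.arange(i0, i1 + 1)
    else:
        mid = (t_start + t_end) / 2.0
        half = protocol.window_seconds / 2.0
        sample_times = np.linspace(mid - half, mid + half, protocol.n_samples)
        # nearest frame within the plateau for each sample time
        sel = i0 + np.argmin(np.abs(window[None, :] - sample_times[:, None]), axis=1)
        if len(set(sel.tolist())) < protocol.n_samples:
            warns.append("frame rate too low for distinct protocol samples; duplicates used")

    max_opening = float(np.mean(openings[sel]))
    theta = float(np.mean(thetas[sel]))
    return SessionReport(
        session_id=session_id,
        max_opening_mm=max_opening,
        opening_grade=grade_opening(max_opening),
        symmetry_theta_deg=theta,
        symmetry_grade=grade_symmetry(theta),
        n_frames=len(measures),
        hold_window=(t_start, t_end),
        warnings=tuple(warns),
    )


def weekly_counts(log: AdherenceLog) -> dict:
    """Sessions per ISO week plus the mean across observed weeks.

    Returns ``{"weeks": {"YYYY-Www": count, ...}, "total": n,
    "mean_per_week": float}``; total is conserved.
    """
    if len(log.session_times) == 0:
        return {"weeks": {}, "total": 0, "mean_per_week": 0.0}
    keys = []
    for t in log.session_times:
        iso = t.isocalendar()
        keys.append(f"{iso.year}-W{iso.week:02d}")
    counts: dict[str, int] = {}
    for k in sorted(keys):
        counts[k] = counts.get(k, 0) + 1
    total = len(keys)
    return {
        "weeks": counts,
        "total": total,
        "mean_per_week": total / len(counts),
    }
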