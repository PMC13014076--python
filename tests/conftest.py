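import numpy as np
import pytest

from mouthkit.geometry import DEFAULT_INDEX_MAP, LandmarkFrame, ellipse_points


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_frame(
    opening_mm: float = 38.0,
    eye_distance_px: float = 70.0,
    phi_deg: float = 0.0,
    frame_id: int = 0,
    timestamp: float = 0.0,
    mouth_width_px: float = 120.0,
    jitter=None,
) -> LandmarkFrame:
    """Minimal synthetic 68-point frame with a known mouth ellipse.

    The pixel scale is eye_distance_px / 3.5 cm, so opening_mm maps to a
    vertical extent of opening_mm/10 * eye_distance_px/3.5 pixels.
    """
    px_per_cm = eye_distance_px / 3.5
    extent_px = opening_mm / 10.0 * px_per_cm
    phi = np.radians(phi_deg)
    a = mouth_width_px / 2.0
    half = extent_px / 2.0
    inside = half**2 - (a * np.sin(phi)) ** 2
    if inside < 0:
        raise ValueError("opening too small for this width/inclination")
    b = np.sqrt(inside) / np.cos(phi)
    pts = np.zeros((68, 2))
    pts[:, 0] = np.linspace(0, 67, 68)  # distinct placeholders
    pts[:, 1] = -50.0
    pts[39] = (-eye_distance_px / 2.0, 0.0)
    pts[42] = (eye_distance_px / 2.0, 0.0)
    pts[48:68] = ellipse_points((0.0, 100.0), a, b, phi_deg, 20)
    if jitter is not None:
        pts = pts + jitter
    return LandmarkFrame(frame_id=frame_id, timestamp=timestamp, points=pts, index_map=DEFAULT_INDEX_MAP)
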