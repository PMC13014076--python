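"""Tool configuration: every numeric constant of the assessment pipeline.

Defaults mirror the clinical protocol: a 3.5 cm interocular reference for
pixel-to-cm calibration, the F1-F4 opening (mm) and symmetry (deg) grade
thresholds, and the 3-second-hold / middle-1-second / 5-sample aggregation
protocol. Landmark roles default to the 68-point convention (inner eye
corners 39/42, mouth contour 48-67, 0-based).
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .grading import (
    OPENING_THRESHOLDS_MM,
    OPENING_UPPER_NORMAL_MM,
    SYMMETRY_THRESHOLDS_DEG,
    ProtocolConfig,
)
from .geometry import DEFAULT_INDEX_MAP

__all__ = ["ToolConfig", "load_config", "config_hash", "CONSTANTS_MANIFEST"]

#: Every default constant with its origin, checked by the test suite.
CONSTANTS_MANIFEST: dict = {
    "reference_cm": (3.5, "anthropometric mean inner-canthal distance used for calibration"),
    "opening_thresholds_mm": ((15.0, 25.0, 35.0), "F1/F2/F3/F4 opening grade boundaries"),
    "opening_upper_normal_mm": (50.0, "upper bound of the normal opening range"),
    "symmetry_thresholds_deg": ((5.0, 10.0, 15.0), "F4/F3/F2/F1 symmetry grade boundaries"),
    "hold_seconds": (3.0, "stabilization hold duration of the aperture protocol"),
    "window_seconds": (1.0, "middle sampling interval of the hold"),
    "n_samples": (5, "data points averaged within the sampling interval"),
    "plateau_fraction": (0.95, "plateau detection level, design choice"),
    "left_eye_inner": (39, "0-based 68-point landmark id of the left inner eye corner"),
    "right_eye_inner": (42, "0-based 68-point landmark id of the right inner eye corner"),
    "failure_threshold_nme": (0.08, "face-alignment failure threshold, field convention"),
    "focal_alpha_t": (0.25, "canonical focal-loss class-balance factor"),
    "focal_gamma": (2.0, "canonical focal-loss focusing exponent"),
}


class IndexMapConfig(BaseModel):
    left_eye_inner: int = DEFAULT_INDEX_MAP["left_eye_inner"]
    right_eye_inner: int = DEFAULT_INDEX_MAP["right_eye_inner"]
    mouth_contour: list[int] = Field(default_factory=lambda: list(DEFAULT_INDEX_MAP["mouth_contour"]))

    def as_dict(self) -> dict:
        return {
            "left_eye_inner": self.left_eye_inner,
            "right_eye_inner": self.right_eye_inner,
            "mouth_contour": list(self.mouth_contour),
        }


class ToolConfig(BaseModel):
    """Full pipeline configuration with protocol defaults."""

    reference_cm: float = CONSTANTS_MANIFEST["reference_cm"][0]
    index_map: IndexMapConfig = Field(default_factory=IndexMapConfig)
    opening_thresholds_mm: tuple[float, float, float] = OPENING_THRESHOLDS_MM
    opening_upper_normal_mm: float = OPENING_UPPER_NORMAL_MM
    symmetry_thresholds_deg: tuple[float, float, float] = SYMMETRY_THRESHOLDS_DEG
    hold_seconds: float = CONSTANTS_MANIFEST["hold_seconds"][0]
    window_seconds: float = CONSTANTS_MANIFEST["window_seconds"][0]
    n_samples: int = CONSTANTS_MANIFEST["n_samples"][0]
    plateau_fraction: float = CONSTANTS_MANIFEST["plateau_fraction"][0]
    failure_threshold_nme: float = CONSTANTS_MANIFEST["failure_threshold_nme"][0]
    focal_alpha_t: float = CONSTANTS_MANIFEST["focal_alpha_t"][0]
    focal_gamma: float = CONSTANTS_MANIFEST["focal_gamma"][0]
    loss_lambdas: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    @field_validator("opening_thresholds_mm", "symmetry_thresholds_deg")
    @classmethod
    def _strictly_increasing(cls, v):
        if not all(a < b for a, b in zip(v, v[1:])):
            raise ValueError("thresholds must be strictly increasing")
        return v

    @field_validator("reference_cm")
    @classmethod
    def _positive_reference(cls, v):
        if v <= 0:
            raise ValueError("reference_cm must be positive")
        return v

    def protocol(self) -> ProtocolConfig:
        return ProtocolConfig(
            hold_seconds=self.hold_seconds,
            window_seconds=self.window_seconds,
            n_samples=self.n_samples,
            plateau_fraction=self.plateau_fraction,
        )


def load_config(path: Optional[str] = None) -> ToolConfig:
    """Load a YAML config file; missing path yields the defaults."""
    if path is None:
        return ToolConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ToolConfig(**data)


def config_hash(config: ToolConfig) -> str:
    """Stable hash of a configuration (canonical JSON, sha256)."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
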