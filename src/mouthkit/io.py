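"""Readers and writers for landmark sequences, manifests, and reports.

Formats are deliberately plain: landmarks travel as CSV
(``frame_id,timestamp,landmark_id,x,y``) or JSON (array of frames with a
``points`` array), predictions and manifests as CSV, reports as JSON with
deterministic key order and fixed float precision so identical inputs and
configuration produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import ToolConfig, config_hash
from .geometry import LandmarkFrame

__all__ = [
    "ReportEnvelope",
    "read_landmarks",
    "write_landmarks",
    "write_report",
    "read_manifest",
    "read_predictions",
]

LANDMARK_COLUMNS = ["frame_id", "timestamp", "landmark_id", "x", "y"]


@dataclass(frozen=True)
class ReportEnvelope:
    """Audit wrapper for any report payload.

    ``timestamps`` records the input data's own time range (not wall-clock
    time), keeping identical runs byte-identical.
    """

    payload: dict
    config: ToolConfig
    input_digest: str = ""
    timestamps: Optional[tuple[float, float]] = None
    tool_version: str = field(default="")

    def to_dict(self) -> dict:
        return {
            "tool_version": self.tool_version or __version__,
            "config_hash": config_hash(self.config),
            "input_digest": self.input_digest,
            "timestamps": list(self.timestamps) if self.timestamps else None,
            "payload": self.payload,
        }


def _landmark_frame(fid: int, group: pd.DataFrame, index_map: dict) -> LandmarkFrame:
    ids = group["landmark_id"].to_numpy()
    expected = np.arange(len(ids))
    order = np.argsort(ids)
    if not np.array_equal(ids[order], expected):
        raise ValueError(f"frame {fid}: landmark ids must be contiguous 0..n-1")
    pts = group[["x", "y"]].to_numpy(dtype=float)[order]
    ts = group["timestamp"].to_numpy(dtype=float)
    if not np.all(ts == ts[0]):
        raise ValueError(f"frame {fid}: inconsistent timestamps within the frame")
    return LandmarkFrame(frame_id=int(fid), timestamp=float(ts[0]), points=pts, index_map=index_map)


def read_landmarks(path, fmt: Optional[str] = None, index_map: Optional[dict] = None) -> list[LandmarkFrame]:
    """Read a landmark sequence from CSV or JSON, sorted by timestamp.

    Validation is strict: missing columns, non-numeric coordinates, and
    duplicate (frame_id, landmark_id) pairs raise errors naming the
    offending row or frame.
    """
    from .geometry import DEFAULT_INDEX_MAP

    index_map = index_map or DEFAULT_INDEX_MAP
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        with open(path) as fh:
            data = json.load(fh)
        frames = [
            LandmarkFrame(
                frame_id=int(item["frame_id"]),
                timestamp=float(item["timestamp"]),
                points=np.asarray(item["points"], dtype=float),
                index_map=index_map,
            )
            for item in data
        ]
        return sorted(frames, key=lambda f: f.timestamp)

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("timestamp", "x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(df.index[bad | df[col].isna()][0]) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric {col} at row {row}")
        df[col] = pd.to_numeric(df[col])
    dup = df.duplicated(subset=["frame_id", "landmark_id"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}: duplicate (frame_id, landmark_id) at row {row}")
    frames = [_landmark_frame(fid, g, index_map) for fid, g in df.groupby("frame_id", sort=True)]
    return sorted(frames, key=lambda f: f.timestamp)


def write_landmarks(frames: Sequence[LandmarkFrame], path, fmt: Optional[str] = None) -> None:
    """Write a landmark sequence as CSV or JSON (lossless round trip)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        data = [
            {
                "frame_id": f.frame_id,
                "timestamp": f.timestamp,
                "points": f.points.tolist(),
            }
            for f in frames
        ]
        with open(path, "w") as fh:
            json.dump(data, fh)
        return
    rows = []
    for f in frames:
        for lid, (x, y) in enumerate(f.points):
            rows.append((f.frame_id, f.timestamp, lid, x, y))
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.6g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_round_floats(v, ndigits) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.6g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(envelope: ReportEnvelope, path) -> None:
    """Serialize a report with deterministic key order and float precision."""
    data = _round_floats(envelope.to_dict())
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> pd.DataFrame:
    """Cohort manifest CSV: sample_id, patient_id, grade[, path, features...]."""
    df = pd.read_csv(path)
    for col in ("sample_id", "patient_id", "grade"):
        if col not in df.columns:
            raise ValueError(f"{path}: manifest missing column {col}")
    return df


def read_predictions(path) -> pd.DataFrame:
    """Predictions CSV: item_id, true_grade, pred_grade[, pred_mm, true_mm, score]."""
    df = pd.read_csv(path)
    for col in ("item_id", "true_grade", "pred_grade"):
        if col not in df.columns:
            raise ValueError(f"{path}: predictions missing column {col}")
    return df
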