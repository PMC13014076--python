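"""Detector training losses: focal classification, GIoU box, keypoint MSE.

Pure scalar/array functions forming the joint objective

    L = lambda1 * focal(p_t) + lambda2 * (1 - GIoU(B_p, B_g)) + lambda3 * MSE(P, G)

where ``focal(p_t) = -alpha_t (1 - p_t)^gamma log(p_t)`` is the
class-balanced hard-example-weighted classification loss, GIoU is the
generalized intersection over union of the predicted and ground-truth
boxes (the enclosing region is the smallest axis-aligned box, the
universal convention for detection boxes), and MSE is the mean squared
Euclidean keypoint deviation. No autodiff, no layers — just the math.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoundingBox",
    "LossParams",
    "focal_loss",
    "giou",
    "iou",
    "giou_loss",
    "keypoint_mse",
    "joint_loss",
]

_EPS = 1e-12


@dataclass(frozen=True)
class BoundingBox:
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass(frozen=True)
class LossParams:
    """Joint-loss hyperparameters (canonical focal-loss defaults)."""

    alpha_t: float = 0.25
    gamma: float = 2.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha_t <= 1):
            raise ValueError("alpha_t must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        lams = (self.lambda1, self.lambda2, self.lambda3)
        if any(l < 0 for l in lams):
            raise ValueError("task weights must be non-negative")
        if all(l == 0 for l in lams):
            raise ValueError("task weights must not all be zero")


def focal_loss(p_t, params: LossParams | None = None) -> float:
    """-alpha_t (1 - p_t)^gamma log(p_t); arrays are averaged per sample."""
    params = params or LossParams()
    p = np.asarray(p_t, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p_t must lie in [0, 1]")
    p = np.clip(p, _EPS, 1.0)
    loss = -params.alpha_t * (1.0 - p) ** params.gamma * np.log(p)
    return float(np.mean(loss))


def iou(b_p: BoundingBox, b_g: BoundingBox) -> float:
    """Intersection over union of two axis-aligned boxes."""
    ix = max(0.0, min(b_p.x_max, b_g.x_max) - max(b_p.x_min, b_g.x_min))
    iy = max(0.0, min(b_p.y_max, b_g.y_max) - max(b_p.y_min, b_g.y_min))
    inter = ix * iy
    union = b_p.area + b_g.area - inter
    return inter / union


def giou(b_p: BoundingBox, b_g: BoundingBox) -> float:
    """Generalized IoU: IoU - |C \\ (B_p U B_g)| / |C|, in [-1, 1].

    C is the smallest enclosing axis-aligned box; GIoU stays informative
    for disjoint boxes, tending to -1 as they separate.
    """
    ix = max(0.0, min(b_p.x_max, b_g.x_max) - max(b_p.x_min, b_g.x_min))
    iy = max(0.0, min(b_p.y_max, b_g.y_max) - max(b_p.y_min, b_g.y_min))
    inter = ix * iy
    union = b_p.area + b_g.area - inter
    cx = max(b_p.x_max, b_g.x_max) - min(b_p.x_min, b_g.x_min)
    cy = max(b_p.y_max, b_g.y_max) - min(b_p.y_min, b_g.y_min)
    enclosing = cx * cy
    return inter / union - (enclosing - union) / enclosing


def giou_loss(b_p: BoundingBox, b_g: BoundingBox) -> float:
    """1 - GIoU(B_p, B_g), the box localization loss; range [0, 2]."""
    return 1.0 - giou(b_p, b_g)


def keypoint_mse(pred, truth) -> float:
    """(1/N) sum_i ||P_i - G_i||^2 over N paired 2D keypoints."""
    p = np.asarray(pred, dtype=float)
    g = np.asarray(truth, dtype=float)
    if p.shape != g.shape:
        raise ValueError(f"keypoint sets differ in shape: {p.shape} vs {g.shape}")
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] == 0:
        raise ValueError("keypoints must be a non-empty (N, 2) array")
    return float(np.mean(np.sum((p - g) ** 2, axis=1)))


def joint_loss(
    p_t,
    b_p: BoundingBox,
    b_g: BoundingBox,
    pred_kps,
    true_kps,
    params: LossParams | None = None,
) -> dict:
    """Weighted sum of the three task losses, with a per-component breakdown."""
    params = params or LossParams()
    components = {
        "focal": focal_loss(p_t, params),
        "giou_loss": giou_loss(b_p, b_g),
        "keypoint_mse": keypoint_mse(pred_kps, true_kps),
    }
    total = (
        params.lambda1 * components["focal"]
        + params.lambda2 * components["giou_loss"]
        + params.lambda3 * components["keypoint_mse"]
    )
    return {"total": float(total), **components}
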