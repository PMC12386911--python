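"""Axis-aligned box arithmetic and the size-adaptive SDIoU similarity.

Boxes live in pixel coordinates as (center x, center y, width, height),
origin top-left, x rightward, y downward.  SDIoU extends the familiar
IoU-with-center-distance family with two adaptive coefficients:

* ``v``/``alpha`` — an aspect-ratio mismatch penalty (the CIoU shape term),
* ``beta`` — a size-aware coefficient, beta = delta * (1 - log(1 + area) /
  log(1 + s_max)), which strengthens supervision for targets much smaller
  than the reference area ``s_max`` and fades to zero as the target
  approaches it.

The full similarity is

    SDIoU = (delta - beta) + (1 - delta + beta) * IoU - alpha * v
            - (1 + delta - beta) * rho^2 / c^2

with rho^2 the squared center distance and c^2 the squared diagonal of the
smallest enclosing box.  SDIoU(b, b) = 1 exactly; the training loss is
1 - SDIoU.

Numerical conventions (also covered by tests):

* natural logarithm in ``beta`` (the ratio makes the base immaterial);
* ``beta`` clamped to [0, delta] so targets larger than ``s_max`` are not
  rewarded;
* ``alpha * v`` defined as 0 whenever v = 0, guarding the 0/0 at a perfect
  match;
* zero or negative widths/heights are rejected, not epsilon-patched —
  training-side callers clamp predictions to a small positive floor first.

All formula functions accept floats, numpy arrays, or autodiff tensors for
the *predicted* box fields; ``alpha`` and ``beta`` are treated as
non-differentiable coefficients (evaluated on raw values), matching the
convention used for the analogous CIoU term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor

__all__ = ["AxisBox", "SDIoUParams", "InvalidBoxError", "iou",
           "shape_penalty_v", "alpha", "beta", "sdiou", "sdiou_loss",
           "sdiou_terms"]


class InvalidBoxError(ValueError):
    """Raised for boxes with non-positive width or height."""


@dataclass(frozen=True)
class AxisBox:
    """Axis-aligned box: center (cx, cy) and size (w, h) in pixels."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"box size must be positive, got w={self.w}, h={self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def corners(self) -> tuple:
        """(x1, y1, x2, y2) with x1 < x2, y1 < y2."""
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "AxisBox":
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


@dataclass(frozen=True)
class SDIoUParams:
    """delta: fixed balance coefficient; s_max: reference area in px^2.

    Defaults follow the study conditions: delta = 0.5 and s_max = 90 * 90,
    the largest labelled target in nadir (orthophoto) imagery at the
    640 x 640 network input resolution.
    """

    delta: float = 0.5
    s_max: float = 8100.0

    def __post_init__(self):
        if not (0 < self.delta < 1):
            raise ValueError("delta must lie in (0, 1)")
        if not self.s_max > 0:
            raise ValueError("s_max must be positive")


# -- generic math helpers (float / ndarray / Tensor) -------------------------

def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _maximum(a, b):
    if _is_tensor(a):
        return a.maximum(b if _is_tensor(b) else Tensor(np.asarray(b, dtype=np.float64)))
    if _is_tensor(b):
        return b.maximum(Tensor(np.asarray(a, dtype=np.float64)))
    return np.maximum(a, b)


def _minimum(a, b):
    if _is_tensor(a):
        return a.minimum(b if _is_tensor(b) else Tensor(np.asarray(b, dtype=np.float64)))
    if _is_tensor(b):
        return b.minimum(Tensor(np.asarray(a, dtype=np.float64)))
    return np.minimum(a, b)


def _arctan(x):
    return x.arctan() if _is_tensor(x) else np.arctan(x)


def _raw(x):
    return x.data if _is_tensor(x) else np.asarray(x)


def _check_size(w, h, who: str):
    if np.any(_raw(w) <= 0) or np.any(_raw(h) <= 0):
        raise InvalidBoxError(f"{who} box has non-positive width or height")


# -- the SDIoU chain ---------------------------------------------------------

def _iou_fields(cx1, cy1, w1, h1, cx2, cy2, w2, h2):
    ix1 = _maximum(cx1 - w1 * 0.5, cx2 - w2 * 0.5)
    iy1 = _maximum(cy1 - h1 * 0.5, cy2 - h2 * 0.5)
    ix2 = _minimum(cx1 + w1 * 0.5, cx2 + w2 * 0.5)
    iy2 = _minimum(cy1 + h1 * 0.5, cy2 + h2 * 0.5)
    iw = _maximum(ix2 - ix1, 0.0)
    ih = _maximum(iy2 - iy1, 0.0)
    inter = iw * ih
    return inter / (w1 * h1 + w2 * h2 - inter)


def iou(b1: AxisBox, b2: AxisBox) -> float:
    """Intersection over union; 0 for disjoint boxes, symmetric."""
    return float(_iou_fields(b1.cx, b1.cy, b1.w, b1.h, b2.cx, b2.cy, b2.w, b2.h))


def _v_fields(w1, h1, w2, h2):
    d = _arctan(w2 / h2) - _arctan(w1 / h1)
    return d * d * (4.0 / math.pi ** 2)


def shape_penalty_v(b1: AxisBox, b2: AxisBox) -> float:
    """Aspect-ratio mismatch penalty in [0, 1]; 0 iff the ratios agree."""
    return float(_v_fields(b1.w, b1.h, b2.w, b2.h))


def alpha(v: float, iou_value: float):
    """Trade-off weight v / (1 - IoU + v); alpha * v is defined as 0 at v = 0."""
    v = np.asarray(v, dtype=float)
    iou_value = np.asarray(iou_value, dtype=float)
    denom = 1.0 - iou_value + v
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(v > 0, v / np.where(denom > 0, denom, 1.0), 0.0)
    return float(a) if a.ndim == 0 else a


def beta(target_area, params: SDIoUParams = SDIoUParams()):
    """Size-aware coefficient in [0, delta], non-increasing in target area.

    beta(s_max) = 0; areas beyond s_max are clamped at 0 rather than going
    negative.
    """
    area = np.asarray(target_area, dtype=float)
    if np.any(area <= 0):
        raise InvalidBoxError("target area must be positive")
    b = params.delta * (1.0 - np.log1p(area) / np.log1p(params.s_max))
    b = np.clip(b, 0.0, params.delta)
    return float(b) if b.ndim == 0 else b


def sdiou_terms(cx1, cy1, w1, h1, cx2, cy2, w2, h2,
                params: SDIoUParams = SDIoUParams()):
    """Vectorised SDIoU over parallel box fields.

    The first box is the prediction and may carry gradients; the second is
    the target and is treated as constant, as are alpha and beta.
    """
    _check_size(w1, h1, "predicted")
    _check_size(w2, h2, "target")
    iou_t = _iou_fields(cx1, cy1, w1, h1, cx2, cy2, w2, h2)
    v_t = _v_fields(w1, h1, w2, h2)
    a = alpha(_raw(v_t), _raw(iou_t))
    b = beta(_raw(w2) * _raw(h2), params)

    dx = cx1 - cx2
    dy = cy1 - cy2
    rho2 = dx * dx + dy * dy
    ex1 = _minimum(cx1 - w1 * 0.5, cx2 - w2 * 0.5)
    ey1 = _minimum(cy1 - h1 * 0.5, cy2 - h2 * 0.5)
    ex2 = _maximum(cx1 + w1 * 0.5, cx2 + w2 * 0.5)
    ey2 = _maximum(cy1 + h1 * 0.5, cy2 + h2 * 0.5)
    cw = ex2 - ex1
    ch = ey2 - ey1
    c2 = cw * cw + ch * ch

    d = params.delta
    return (d - b) + iou_t * (1.0 - d + b) - v_t * a - (rho2 / c2) * (1.0 + d - b)


def sdiou(b1: AxisBox, b2: AxisBox, params: SDIoUParams = SDIoUParams()) -> float:
    """SDIoU similarity of predicted box b1 against target b2; 1 at b1 = b2."""
    return float(sdiou_terms(b1.cx, b1.cy, b1.w, b1.h,
                             b2.cx, b2.cy, b2.w, b2.h, params))


def sdiou_loss(b1: AxisBox, b2: AxisBox, params: SDIoUParams = SDIoUParams()) -> float:
    """1 - SDIoU: zero at a perfect match, larger for worse localisation."""
    return 1.0 - sdiou(b1, b2, params)
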