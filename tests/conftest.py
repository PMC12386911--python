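"""Shared independent oracles for the acceptance checks.

These reimplement the quantities under test with plain ``math`` and
pixel-counting, sharing no code with the library paths they check.
"""

import math

import numpy as np
import pytest


def sdiou_reference(b1, b2, delta=0.5, smax=8100.0):
    """Direct evaluation of the SDIoU chain on two AxisBoxes."""
    x11, y11, x12, y12 = b1.corners
    x21, y21, x22, y22 = b2.corners
    iw = max(0.0, min(x12, x22) - max(x11, x21))
    ih = max(0.0, min(y12, y22) - max(y11, y21))
    inter = iw * ih
    i = inter / (b1.w * b1.h + b2.w * b2.h - inter)
    v = (4 / math.pi ** 2) * (math.atan(b2.w / b2.h) - math.atan(b1.w / b1.h)) ** 2
    a = 0.0 if v == 0 else v / (1 - i + v)
    b = min(delta, max(0.0, delta * (1 - math.log1p(b2.w * b2.h) / math.log1p(smax))))
    rho2 = (b1.cx - b2.cx) ** 2 + (b1.cy - b2.cy) ** 2
    cw = max(x12, x22) - min(x11, x21)
    ch = max(y12, y22) - min(y11, y21)
    return (delta - b) + (1 - delta + b) * i - a * v \
        - (1 + delta - b) * rho2 / (cw ** 2 + ch ** 2)


def raster_iou(b1, b2, grid=200):
    """Pixel-count IoU for integer-corner boxes; returns (iou, union_area)."""
    m1 = np.zeros((grid, grid), dtype=bool)
    m2 = np.zeros((grid, grid), dtype=bool)
    x11, y11, x12, y12 = (int(v) for v in b1.corners)
    x21, y21, x22, y22 = (int(v) for v in b2.corners)
    m1[y11:y12, x11:x12] = True
    m2[y21:y22, x21:x22] = True
    union = np.logical_or(m1, m2).sum()
    return np.logical_and(m1, m2).sum() / union, union


@pytest.fixture
def sdiou_oracle():
    return sdiou_reference


@pytest.fixture
def raster_iou_oracle():
    return raster_iou
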