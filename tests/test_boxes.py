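"""Box arithmetic and the SDIoU similarity chain.

The reference values here were frozen from an independent direct
evaluation of the defining formulas in a standalone script before the
library was written; the in-test oracle below reproduces that evaluation
with plain ``math`` calls and no shared code with the library path.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowndetect.boxes import (AxisBox, InvalidBoxError, SDIoUParams, alpha,
                               beta, iou, sdiou, sdiou_loss, sdiou_terms,
                               shape_penalty_v)

B1 = AxisBox.from_corners(40, 30, 60, 70)   # 20 x 40
B2 = AxisBox.from_corners(45, 40, 65, 60)   # 20 x 20


# -- independent scalar oracle ----------------------------------------------

def oracle_iou(b1, b2):
    x11, y11, x12, y12 = b1.corners
    x21, y21, x22, y22 = b2.corners
    iw = max(0.0, min(x12, x22) - max(x11, x21))
    ih = max(0.0, min(y12, y22) - max(y11, y21))
    inter = iw * ih
    return inter / (b1.w * b1.h + b2.w * b2.h - inter)


def oracle_sdiou(b1, b2, delta=0.5, smax=8100.0):
    i = oracle_iou(b1, b2)
    v = (4 / math.pi ** 2) * (math.atan(b2.w / b2.h) - math.atan(b1.w / b1.h)) ** 2
    a = 0.0 if v == 0 else v / (1 - i + v)
    b = min(delta, max(0.0, delta * (1 - math.log1p(b2.w * b2.h) / math.log1p(smax))))
    rho2 = (b1.cx - b2.cx) ** 2 + (b1.cy - b2.cy) ** 2
    x11, y11, x12, y12 = b1.corners
    x21, y21, x22, y22 = b2.corners
    cw = max(x12, x22) - min(x11, x21)
    ch = max(y12, y22) - min(y11, y21)
    return (delta - b) + (1 - delta + b) * i - a * v \
        - (1 + delta - b) * rho2 / (cw ** 2 + ch ** 2)


def random_boxes(rng, n, lo=1.0, hi=120.0):
    cx = rng.uniform(0, 600, n)
    cy = rng.uniform(0, 600, n)
    w = rng.uniform(lo, hi, n)
    h = rng.uniform(lo, hi, n)
    return [AxisBox(*t) for t in zip(cx, cy, w, h)]


# -- iou ---------------------------------------------------------------------

class TestIoU:
    def test_identity(self):
        b = AxisBox(50, 50, 10, 20)
        assert iou(b, b) == 1.0

    def test_reference_overlap(self):
        # 300 px^2 intersection over 900 px^2 union
        assert iou(B1, B2) == pytest.approx(1 / 3, abs=1e-12)

    def test_disjoint(self):
        assert iou(AxisBox.from_corners(0, 0, 10, 10),
                   AxisBox.from_corners(20, 20, 30, 30)) == 0.0

    def test_symmetry(self):
        assert iou(B1, B2) == iou(B2, B1)

    def test_invalid_box_rejected(self):
        with pytest.raises(InvalidBoxError):
            AxisBox(0, 0, 0, 5)
        with pytest.raises(InvalidBoxError):
            AxisBox(0, 0, 5, -1)

    def test_matches_pixel_rasterization_oracle(self):
        """IoU agrees with a pixel-count oracle on integer-coordinate boxes."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            x1, y1 = rng.integers(0, 80, 2)
            w1, h1 = rng.integers(1, 60, 2)
            x2, y2 = rng.integers(0, 80, 2)
            w2, h2 = rng.integers(1, 60, 2)
            b1 = AxisBox.from_corners(x1, y1, x1 + w1, y1 + h1)
            b2 = AxisBox.from_corners(x2, y2, x2 + w2, y2 + h2)
            grid = np.zeros((160, 160), dtype=bool)
            m1 = grid.copy()
            m1[y1:y1 + h1, x1:x1 + w1] = True
            m2 = grid.copy()
            m2[y2:y2 + h2, x2:x2 + w2] = True
            union = np.logical_or(m1, m2).sum()
            expected = np.logical_and(m1, m2).sum() / union
            assert iou(b1, b2) == pytest.approx(expected, abs=1.0 / union)


# -- shape penalty and coefficients -----------------------------------------

class TestShapeAndCoefficients:
    def test_v_zero_for_equal_aspect(self):
        assert shape_penalty_v(AxisBox(0, 0, 10, 20), AxisBox(5, 5, 30, 60)) == 0.0

    def test_v_reference_value(self):
        v = shape_penalty_v(AxisBox(0, 0, 20, 40), AxisBox(0, 0, 20, 20))
        assert v == pytest.approx(0.04195646149429057, abs=1e-12)

    def test_v_bounds_and_symmetry(self):
        rng = np.random.default_rng(7)
        for b1, b2 in zip(random_boxes(rng, 200), random_boxes(rng, 200)):
            v = shape_penalty_v(b1, b2)
            assert 0.0 <= v <= 1.0
            flipped = shape_penalty_v(AxisBox(0, 0, b1.h, b1.w),
                                      AxisBox(0, 0, b2.h, b2.w))
            assert v == pytest.approx(flipped, abs=1e-12)

    def test_v_extreme_aspect_limit(self):
        v = shape_penalty_v(AxisBox(0, 0, 1e-6, 1.0), AxisBox(0, 0, 1.0, 1e-6))
        assert v == pytest.approx(1.0, abs=1e-4)

    def test_alpha_guard_and_value(self):
        assert alpha(0.0, 0.5) == 0.0
        assert alpha(0.0, 1.0) == 0.0          # 0/0 guarded
        a = alpha(0.04195646149429057, 1 / 3)
        assert a == pytest.approx(0.05920842804436456, abs=1e-12)

    def test_beta_endpoints(self):
        p = SDIoUParams()
        assert beta(8100.0, p) == 0.0
        assert beta(1e-9, p) == pytest.approx(0.5, abs=1e-6)
        assert beta(400.0, p) == pytest.approx(0.16699262594039843, abs=1e-12)

    def test_beta_monotone_and_clamped(self):
        p = SDIoUParams()
        areas = np.linspace(1.0, 20000.0, 500)
        vals = beta(areas, p)
        assert np.all(np.diff(vals) <= 1e-15)
        assert np.all(vals >= 0.0) and np.all(vals <= p.delta)
        assert beta(20000.0, p) == 0.0          # beyond s_max stays clamped

    def test_beta_rejects_nonpositive_area(self):
        with pytest.raises(InvalidBoxError):
            beta(0.0)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SDIoUParams(delta=0.0)
        with pytest.raises(ValueError):
            SDIoUParams(s_max=-1.0)


# -- sdiou -------------------------------------------------------------------

class TestSDIoU:
    def test_perfect_match_is_one(self):
        rng = np.random.default_rng(3)
        for b in random_boxes(rng, 1000):
            assert sdiou(b, b) == pytest.approx(1.0, abs=1e-12)
            assert sdiou_loss(b, b) == pytest.approx(0.0, abs=1e-12)

    def test_reference_pair_regression(self):
        # frozen from the standalone direct evaluation
        assert sdiou(B1, B2) == pytest.approx(0.5378764622971969, abs=1e-12)
        assert sdiou_loss(B1, B2) == pytest.approx(0.4621235377028031, abs=1e-12)

    def test_matches_independent_oracle_on_seeded_pairs(self):
        rng = np.random.default_rng(11)
        for b1, b2 in zip(random_boxes(rng, 1000), random_boxes(rng, 1000)):
            assert sdiou(b1, b2) == pytest.approx(oracle_sdiou(b1, b2), abs=1e-6)

    def test_far_disjoint_pair_goes_negative(self):
        b1 = AxisBox(0, 0, 10, 10)
        b2 = AxisBox(500, 500, 10, 10)
        assert sdiou(b1, b2) < 0.0

    def test_vectorised_terms_match_scalar(self):
        rng = np.random.default_rng(5)
        bs1 = random_boxes(rng, 64)
        bs2 = random_boxes(rng, 64)
        vec = sdiou_terms(np.array([b.cx for b in bs1]), np.array([b.cy for b in bs1]),
                          np.array([b.w for b in bs1]), np.array([b.h for b in bs1]),
                          np.array([b.cx for b in bs2]), np.array([b.cy for b in bs2]),
                          np.array([b.w for b in bs2]), np.array([b.h for b in bs2]))
        for k, (b1, b2) in enumerate(zip(bs1, bs2)):
            assert vec[k] == pytest.approx(sdiou(b1, b2), abs=1e-9)


finite_coord = st.floats(min_value=-1000, max_value=1000, allow_nan=False)
finite_size = st.floats(min_value=0.1, max_value=500, allow_nan=False)


class TestPropertyInvariants:
    @settings(max_examples=200, derandomize=True)
    @given(cx=finite_coord, cy=finite_coord, w=finite_size, h=finite_size)
    def test_self_similarity_is_one_everywhere(self, cx, cy, w, h):
        b = AxisBox(cx, cy, w, h)
        assert sdiou(b, b) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(cx1=finite_coord, cy1=finite_coord, w1=finite_size, h1=finite_size,
           cx2=finite_coord, cy2=finite_coord, w2=finite_size, h2=finite_size)
    def test_iou_symmetric_and_bounded(self, cx1, cy1, w1, h1,
                                       cx2, cy2, w2, h2):
        b1, b2 = AxisBox(cx1, cy1, w1, h1), AxisBox(cx2, cy2, w2, h2)
        v = iou(b1, b2)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(iou(b2, b1), abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(a1=st.floats(min_value=1, max_value=20000),
           a2=st.floats(min_value=1, max_value=20000))
    def test_beta_order_reversal(self, a1, a2):
        # larger targets never receive a larger size coefficient
        lo, hi = sorted((a1, a2))
        assert beta(hi) <= beta(lo) + 1e-12


class TestSDIoUAsLoss:
    def test_gradient_descent_recovers_target(self):
        """From a perturbed start, first-order descent on 1 - SDIoU recovers
        the target box within 1 px in >= 95 % of 100 seeded random trials.

        Centers live in pixels and sizes in log-pixels, so the raw gradient
        scales differ by orders of magnitude; the harness uses adaptive
        per-coordinate steps (Adam) with a linearly decayed rate.
        """
        from crowndetect.nn import Tensor
        rng = np.random.default_rng(99)
        params = SDIoUParams()
        hits = 0
        steps, lr0 = 300, 0.1
        for _ in range(100):
            tgt = AxisBox(rng.uniform(100, 500), rng.uniform(100, 500),
                          rng.uniform(15, 90), rng.uniform(15, 90))
            state = np.array([tgt.cx + rng.uniform(-15, 15),
                              tgt.cy + rng.uniform(-15, 15),
                              math.log(tgt.w * rng.uniform(0.6, 1.6)),
                              math.log(tgt.h * rng.uniform(0.6, 1.6))])
            m = np.zeros(4)
            v = np.zeros(4)
            for step in range(steps):
                t = Tensor(state, requires_grad=True)
                loss = 1.0 - sdiou_terms(t[0], t[1], t[2].exp(), t[3].exp(),
                                         tgt.cx, tgt.cy, tgt.w, tgt.h, params)
                loss.backward()
                g = t.grad
                m = 0.9 * m + 0.1 * g
                v = 0.999 * v + 0.001 * g * g
                mh = m / (1 - 0.9 ** (step + 1))
                vh = v / (1 - 0.999 ** (step + 1))
                state = state - lr0 * (1 - step / steps) * mh / (np.sqrt(vh) + 1e-9)
            w, h = math.exp(state[2]), math.exp(state[3])
            err = max(abs(state[0] - tgt.cx), abs(state[1] - tgt.cy),
                      abs(w - tgt.w), abs(h - tgt.h))
            hits += err <= 1.0
        assert hits >= 95

    def test_small_target_gradient_exceeds_plain_iou(self):
        """For targets far below the reference area, the center gradient of
        the SDIoU loss is stronger than that of a plain 1 - IoU loss at
        low-IoU configurations."""
        from crowndetect.boxes import _iou_fields
        from crowndetect.nn import Tensor
        rng = np.random.default_rng(17)
        params = SDIoUParams()
        wins = 0
        trials = 50
        for _ in range(trials):
            side = rng.uniform(6, 15)                # area << 8100
            tgt = AxisBox(300, 300, side, side)
            off = rng.uniform(0.8, 1.5) * side       # low-IoU offset
            ang = rng.uniform(0, 2 * math.pi)
            cx0, cy0 = 300 + off * math.cos(ang), 300 + off * math.sin(ang)

            t = Tensor(np.array([cx0, cy0]), requires_grad=True)
            (1.0 - sdiou_terms(t[0], t[1], side, side,
                               tgt.cx, tgt.cy, tgt.w, tgt.h, params)).backward()
            g_sd = np.linalg.norm(t.grad)

            t2 = Tensor(np.array([cx0, cy0]), requires_grad=True)
            (1.0 - _iou_fields(t2[0], t2[1], side, side,
                               tgt.cx, tgt.cy, tgt.w, tgt.h)).backward()
            g_iou = np.linalg.norm(t2.grad)
            wins += g_sd > g_iou
        assert wins == trials
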