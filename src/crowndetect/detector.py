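"""Single-stage anchor-free crown-health detector.

Assembly follows the familiar one-stage layout: a convolutional
downsampling backbone whose split/fuse containers host StripBlocks, a
top-down + bottom-up feature-fusion neck whose containers are the CAA
variant, and a per-cell prediction head at three pyramid strides.  Each
of the three substitutions can be toggled independently (plain containers
in place of strip/CAA, plain 1-IoU loss in place of SDIoU) for ablation
experiments.

Head parameterisation per cell (stride s, cell indices gx, gy):

    cx = (gx + 2*sigmoid(tx) - 0.5) * s        cy analogous
    w  = exp(tw) * s                           h analogous (tw clamped)

Class scores are independent sigmoids; the decoded confidence is the
maximum class probability.  Training targets are assigned by a center
prior: each ground-truth box selects the pyramid level whose stride best
matches its size, and claims the cells whose centers fall inside its
central half (plus the cell containing its center).  The loss is

    total = cls_w * BCE(class scores, targets) + box_w * mean(1 - SDIoU)

over assigned cells, with BCE evaluated densely over all cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .boxes import AxisBox, SDIoUParams, iou, sdiou_terms
from .caa import C3k2CAA
from .metrics import Detection
from .nn import Tensor, concat
from .strip import C3k2Strip

__all__ = ["DetectorConfig", "TrainConfig", "Detector", "build_detector",
           "assign_targets", "compute_loss", "predict", "letterbox",
           "unletterbox_box", "nms", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class DetectorConfig:
    input_size: int = 640
    n_classes: int = 2                      # Weak, Dead
    width_multiple: float = 1.0
    depth_multiple: float = 1.0
    strides: tuple = (8, 16, 32)
    base_channels: tuple = (12, 24, 40, 56, 72)
    box_loss_weight: float = 5.0
    cls_loss_weight: float = 1.0
    cls_pos_weight: float = 20.0            # BCE weight on positive cells
    conf_threshold: float = 0.25
    nms_iou_threshold: float = 0.45
    # ablation toggles
    use_strip: bool = True
    use_caa: bool = True
    use_sdiou: bool = True
    sdiou: SDIoUParams = field(default_factory=SDIoUParams)

    def __post_init__(self):
        if self.input_size % max(self.strides) != 0:
            raise ValueError("input_size must be divisible by the largest stride")

    def width(self, c: int) -> int:
        return max(2, int(round(c * self.width_multiple)))

    def depth(self, n: int) -> int:
        return max(1, int(round(n * self.depth_multiple)))


@dataclass(frozen=True)
class TrainConfig:
    """Full-scale defaults match the study regime (SGD, lr 0.01, momentum
    0.8, batch 16, 300 epochs, 640 px input); desk-scale runs override
    epochs/batch/input through DetectorConfig and the harness."""

    learning_rate: float = 0.01
    batch_size: int = 16
    epochs: int = 300
    momentum: float = 0.8
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size, epochs must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")


class _ConvBNAct(nn.Module):
    def __init__(self, c_in, c_out, k, stride, rng):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, k, stride=stride, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        return self.bn(self.conv(x)).silu()


class _PlainC3k2(nn.Module):
    """Baseline split/process/concat/fuse container with 3x3 conv blocks."""

    def __init__(self, c_in, c_out, n_blocks, rng):
        super().__init__()
        hidden = max(1, c_out // 2)
        self.hidden = hidden
        self.split = nn.Conv2d(c_in, 2 * hidden, 1, rng=rng)
        self.blocks = [_ConvBNAct(hidden, hidden, 3, 1, rng) for _ in range(n_blocks)]
        self.fuse = nn.Conv2d(2 * hidden, c_out, 1, rng=rng)

    def forward(self, x):
        s = self.split(x).silu()
        a = s[:, :self.hidden]
        b = s[:, self.hidden:]
        for blk in self.blocks:
            b = blk(b)
        return self.fuse(concat([a, b], axis=1)).silu()


def _stage_block(cfg: DetectorConfig, c_in, c_out, n, rng, *, neck: bool):
    if neck:
        return C3k2CAA(c_in, c_out, n_units=n, rng=rng) if cfg.use_caa \
            else _PlainC3k2(c_in, c_out, n, rng)
    return C3k2Strip(c_in, c_out, n_blocks=n, rng=rng) if cfg.use_strip \
        else _PlainC3k2(c_in, c_out, n, rng)


class _Head(nn.Module):
    """Per-level prediction head: shared trunk, decoupled branches.

    Emits (B, 4 + n_classes, H, W): box offsets first, class logits after,
    with class bias initialised toward background."""

    def __init__(self, c, n_classes, rng):
        super().__init__()
        self.trunk = _ConvBNAct(c, c, 3, 1, rng)
        self.box_branch = nn.Sequential(_ConvBNAct(c, c, 3, 1, rng),
                                        nn.Conv2d(c, 4, 1, rng=rng))
        self.cls_branch = nn.Sequential(_ConvBNAct(c, c, 3, 1, rng),
                                        nn.Conv2d(c, n_classes, 1, rng=rng))
        self.cls_branch[1].bias.data[:] = -4.0

    def forward(self, x):
        t = self.trunk(x)
        return concat([self.box_branch(t), self.cls_branch(t)], axis=1)


class Detector(nn.Module):
    """Backbone + neck + per-level detection head."""

    def __init__(self, cfg: DetectorConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        c1, c2, c3, c4, c5 = (cfg.width(c) for c in cfg.base_channels)
        n = cfg.depth(1)
        # backbone: /2 stem then four downsampling stages -> P3, P4, P5
        self.stem = _ConvBNAct(3, c1, 3, 2, rng)
        self.down1 = _ConvBNAct(c1, c2, 3, 2, rng)     # /4
        self.b1 = _stage_block(cfg, c2, c2, n, rng, neck=False)
        self.down2 = _ConvBNAct(c2, c3, 3, 2, rng)     # /8
        self.b2 = _stage_block(cfg, c3, c3, n, rng, neck=False)
        self.down3 = _ConvBNAct(c3, c4, 3, 2, rng)     # /16
        self.b3 = _stage_block(cfg, c4, c4, n, rng, neck=False)
        self.down4 = _ConvBNAct(c4, c5, 3, 2, rng)     # /32
        self.b4 = _stage_block(cfg, c5, c5, n, rng, neck=False)
        # neck: top-down then bottom-up fusion
        self.n4 = _stage_block(cfg, c5 + c4, c4, n, rng, neck=True)
        self.n3 = _stage_block(cfg, c4 + c3, c3, n, rng, neck=True)
        self.d3 = _ConvBNAct(c3, c3, 3, 2, rng)
        self.n4b = _stage_block(cfg, c3 + c4, c4, n, rng, neck=True)
        self.d4 = _ConvBNAct(c4, c4, 3, 2, rng)
        self.n5b = _stage_block(cfg, c4 + c5, c5, n, rng, neck=True)
        # head: per level, a shared trunk then decoupled box / class
        # branches (coupling them lets one class channel collapse into
        # the box-objectness solution on some inits)
        self.heads = [_Head(c, cfg.n_classes, rng) for c in (c3, c4, c5)]

    def forward(self, x: Tensor) -> list:
        """(B, 3, H, W) -> list of per-level maps (B, 4 + n_classes, H/s, W/s)."""
        x = self.stem(x)
        x = self.b1(self.down1(x))
        p3 = self.b2(self.down2(x))
        p4 = self.b3(self.down3(p3))
        p5 = self.b4(self.down4(p4))
        u4 = self.n4(concat([nn.upsample_nearest2d(p5, 2), p4], axis=1))
        u3 = self.n3(concat([nn.upsample_nearest2d(u4, 2), p3], axis=1))
        m4 = self.n4b(concat([self.d3(u3), u4], axis=1))
        m5 = self.n5b(concat([self.d4(m4), p5], axis=1))
        return [h(f) for h, f in zip(self.heads, (u3, m4, m5))]


def build_detector(cfg: DetectorConfig, seed: int = 0) -> Detector:
    return Detector(cfg, np.random.default_rng(seed))


# -- target assignment -------------------------------------------------------

def _pick_level(box: AxisBox, strides: tuple) -> int:
    """Level whose stride best matches the box size (target ~4 cells/side)."""
    side = max(box.w, box.h)
    scores = [abs(math.log2(max(side, 1e-6) / (4.0 * s))) for s in strides]
    return int(np.argmin(scores))


def assign_targets(truth_boxes: list, truth_classes: list,
                   cfg: DetectorConfig, image_size: int | None = None) -> list:
    """Per-level assignment maps for one image.

    Returns, per pyramid level, a dict with integer arrays ``gy``, ``gx``,
    ``cls`` and a float array ``boxes`` (N, 4) of matched ground truth in
    pixels.  A cell is claimed by the first box whose central half
    contains the cell center (the center cell is always claimed); boxes
    are clipped to the image first.
    """
    size = image_size or cfg.input_size
    levels = [{"gy": [], "gx": [], "cls": [], "boxes": [], "taken": set()}
              for _ in cfg.strides]
    for box, cls in zip(truth_boxes, truth_classes):
        x1, y1, x2, y2 = box.corners
        x1, y1 = max(0.0, x1), max(0.0, y1)
        x2, y2 = min(float(size), x2), min(float(size), y2)
        if x2 - x1 <= 1e-6 or y2 - y1 <= 1e-6:
            continue
        box = AxisBox.from_corners(x1, y1, x2, y2)
        li = _pick_level(box, cfg.strides)
        s = cfg.strides[li]
        ncells = size // s
        lvl = levels[li]
        # candidate cells: centers inside the central half of the box
        gx_lo = int(np.floor((box.cx - box.w / 4) / s - 0.5 + 1))
        gx_hi = int(np.floor((box.cx + box.w / 4) / s - 0.5))
        gy_lo = int(np.floor((box.cy - box.h / 4) / s - 0.5 + 1))
        gy_hi = int(np.floor((box.cy + box.h / 4) / s - 0.5))
        cand = [(gy, gx)
                for gy in range(max(0, gy_lo), min(ncells - 1, gy_hi) + 1)
                for gx in range(max(0, gx_lo), min(ncells - 1, gx_hi) + 1)]
        center_cell = (min(ncells - 1, max(0, int(box.cy / s))),
                       min(ncells - 1, max(0, int(box.cx / s))))
        if center_cell not in cand:
            cand.append(center_cell)
        for gy, gx in cand:
            if (gy, gx) in lvl["taken"]:
                continue
            lvl["taken"].add((gy, gx))
            lvl["gy"].append(gy)
            lvl["gx"].append(gx)
            lvl["cls"].append(cls)
            lvl["boxes"].append([box.cx, box.cy, box.w, box.h])
    out = []
    for lvl in levels:
        out.append({"gy": np.array(lvl["gy"], dtype=np.intp),
                    "gx": np.array(lvl["gx"], dtype=np.intp),
                    "cls": np.array(lvl["cls"], dtype=np.intp),
                    "boxes": np.array(lvl["boxes"], dtype=np.float64).reshape(-1, 4)})
    return out


# -- loss --------------------------------------------------------------------

def _bce_with_logits(logits: Tensor, targets: np.ndarray,
                     weights: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on raw scores.

    ``weights`` rebalances cells, not individual targets: every class
    channel of an assigned cell carries the high weight, so the penalty
    for lighting up the wrong class at an object is as strong as the
    reward for the right one.
    """
    t = targets.astype(logits.data.dtype)
    absx = logits.relu() + (-logits).relu()
    per = logits.clamp_min(0.0) - logits * t + ((-absx).exp() + 1.0).log()
    return (per * weights).sum() * (1.0 / per.data.size)


def compute_loss(preds: list, batch_targets: list, cfg: DetectorConfig) -> tuple:
    """Total loss and (box, cls) components for a batch.

    ``preds``: per-level Tensors (B, 4+nc, H, W); ``batch_targets``: one
    ``assign_targets`` result per image.
    """
    params = cfg.sdiou
    box_losses, n_assigned = [], 0
    cls_loss = None
    for li, p in enumerate(preds):
        s = cfg.strides[li]
        B, C, H, W = p.shape
        tgt_cls = np.zeros((B, cfg.n_classes, H, W), dtype=np.float32)
        cell_w = np.ones((B, 1, H, W), dtype=np.float32)
        bi, gy, gx, tb = [], [], [], []
        for b, tlevels in enumerate(batch_targets):
            lvl = tlevels[li]
            for j in range(len(lvl["gy"])):
                tgt_cls[b, lvl["cls"][j], lvl["gy"][j], lvl["gx"][j]] = 1.0
                cell_w[b, 0, lvl["gy"][j], lvl["gx"][j]] = cfg.cls_pos_weight
            bi.extend([b] * len(lvl["gy"]))
            gy.extend(lvl["gy"].tolist())
            gx.extend(lvl["gx"].tolist())
            tb.append(lvl["boxes"])
        lvl_cls = _bce_with_logits(p[:, 4:], tgt_cls, cell_w)
        cls_loss = lvl_cls if cls_loss is None else cls_loss + lvl_cls
        if bi:
            bi = np.array(bi, dtype=np.intp)
            gy = np.array(gy, dtype=np.intp)
            gx = np.array(gx, dtype=np.intp)
            tb = np.concatenate(tb, axis=0)
            tx = p[bi, 0, gy, gx]
            ty = p[bi, 1, gy, gx]
            tw = p[bi, 2, gy, gx]
            th = p[bi, 3, gy, gx]
            cx = (tx.sigmoid() * 2.0 - 0.5 + gx.astype(np.float64)) * float(s)
            cy = (ty.sigmoid() * 2.0 - 0.5 + gy.astype(np.float64)) * float(s)
            w = tw.clamp_min(-6.0).clamp_max(4.0).exp() * float(s)
            h = th.clamp_min(-6.0).clamp_max(4.0).exp() * float(s)
            if cfg.use_sdiou:
                sim = sdiou_terms(cx, cy, w, h,
                                  tb[:, 0], tb[:, 1], tb[:, 2], tb[:, 3], params)
            else:
                from .boxes import _iou_fields
                sim = _iou_fields(cx, cy, w, h, tb[:, 0], tb[:, 1], tb[:, 2], tb[:, 3])
            box_losses.append((1.0 - sim).sum())
            n_assigned += len(bi)
    if n_assigned:
        box_loss = box_losses[0]
        for bl in box_losses[1:]:
            box_loss = box_loss + bl
        box_loss = box_loss * (1.0 / n_assigned)
    else:
        box_loss = Tensor(np.zeros(()))
    total = box_loss * cfg.box_loss_weight + cls_loss * cfg.cls_loss_weight
    return total, {"box": float(box_loss.data), "cls": float(cls_loss.data)}


# -- decoding / inference ----------------------------------------------------

def letterbox(image: np.ndarray, size: int, pad_value: int = 114) -> tuple:
    """Resize keeping aspect, pad to (size, size) with gray.

    Returns (padded float CHW array in [0,1], scale, (pad_x, pad_y)).
    """
    from PIL import Image as PILImage
    h, w = image.shape[:2]
    scale = size / max(h, w)
    nw, nh = max(1, round(w * scale)), max(1, round(h * scale))
    im = PILImage.fromarray(image).resize((nw, nh), PILImage.BILINEAR)
    canvas = np.full((size, size, 3), pad_value, dtype=np.uint8)
    px, py = (size - nw) // 2, (size - nh) // 2
    canvas[py:py + nh, px:px + nw] = np.asarray(im)
    chw = canvas.astype(np.float32).transpose(2, 0, 1) / 255.0
    return chw, scale, (px, py)


def unletterbox_box(box: AxisBox, scale: float, pad: tuple) -> AxisBox:
    """Map a box from network-input frame back to the original image frame."""
    return AxisBox((box.cx - pad[0]) / scale, (box.cy - pad[1]) / scale,
                   box.w / scale, box.h / scale)


def nms(boxes: list, scores: list, thr: float) -> list:
    """Greedy IoU suppression; returns kept indices (descending score)."""
    order = sorted(range(len(boxes)), key=lambda i: -scores[i])
    keep = []
    for i in order:
        if all(iou(boxes[i], boxes[k]) <= thr for k in keep):
            keep.append(i)
    return keep


def _decode_level(p: np.ndarray, stride: int, cfg: DetectorConfig) -> tuple:
    B, C, H, W = p.shape
    assert B == 1
    scores = 1.0 / (1.0 + np.exp(-p[0, 4:]))          # (nc, H, W)
    cls_id = scores.argmax(axis=0)
    conf = scores.max(axis=0)
    gy, gx = np.nonzero(conf > cfg.conf_threshold)
    out = []
    for y, x in zip(gy, gx):
        tx, ty, tw, th = p[0, :4, y, x]
        sig = lambda z: 1.0 / (1.0 + np.exp(-z))
        cx = (sig(tx) * 2.0 - 0.5 + x) * stride
        cy = (sig(ty) * 2.0 - 0.5 + y) * stride
        w = math.exp(np.clip(tw, -6.0, 4.0)) * stride
        h = math.exp(np.clip(th, -6.0, 4.0)) * stride
        out.append((AxisBox(cx, cy, max(w, 1e-3), max(h, 1e-3)),
                    int(cls_id[y, x]), float(conf[y, x])))
    return out


def predict(image: np.ndarray, model: Detector, cfg: DetectorConfig,
            image_id: str = "") -> list:
    """Full inference on one HWC uint8 image -> list of Detection."""
    chw, scale, pad = letterbox(image, cfg.input_size)
    model.eval()
    preds = model(Tensor(chw[None]))
    raw = []
    for p, s in zip(preds, cfg.strides):
        raw.extend(_decode_level(p.data, s, cfg))
    dets = []
    h, w = image.shape[:2]
    for cid in range(cfg.n_classes):
        sel = [(b, c, conf) for b, c, conf in raw if c == cid]
        keep = nms([b for b, _, _ in sel], [conf for _, _, conf in sel],
                   cfg.nms_iou_threshold)
        for i in keep:
            box = unletterbox_box(sel[i][0], scale, pad)
            x1, y1, x2, y2 = box.corners
            x1, y1 = max(0.0, x1), max(0.0, y1)
            x2, y2 = min(float(w), x2), min(float(h), y2)
            if x2 - x1 < 1e-3 or y2 - y1 < 1e-3:
                continue
            dets.append(Detection(AxisBox.from_corners(x1, y1, x2, y2),
                                  cid, min(1.0, sel[i][2]), image_id))
    return dets


# -- checkpointing -----------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: Detector, cfg: DetectorConfig, path, extra: dict | None = None):
    """Single-file serialized weights plus a config snapshot."""
    state = model.state_dict()
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(cfg),
            "extra": extra or {}}
    np.savez_compressed(path, __meta__=np.frombuffer(
        __import__("json").dumps(meta, default=list).encode(), dtype=np.uint8),
        **state)


def load_checkpoint(path) -> tuple:
    import json
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        ccfg = meta["config"]
        ccfg["strides"] = tuple(ccfg["strides"])
        ccfg["base_channels"] = tuple(ccfg["base_channels"])
        ccfg["sdiou"] = SDIoUParams(**ccfg["sdiou"])
        cfg = DetectorConfig(**ccfg)
        model = build_detector(cfg)
        model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    return model, cfg, meta["extra"]
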