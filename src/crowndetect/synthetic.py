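"""Seeded generator of UAV-style forest scenes with crown health classes.

The generator emulates the two capture regimes of a drone forest-health
campaign over a conifer stand attacked by wood-boring pests:

* **ortho** (nadir) — crowns are small and near-square (aspect ratio
  0.8–1.25, largest annotated target capped at 90 px at the 640 px
  reference resolution);
* **oblique** — crowns are tall and narrow (height/width 2–5) with a
  partial trunk below the canopy.

Three visual health classes are rendered: *healthy* crowns are dense and
dark green, *weakened* crowns are yellow-green, visibly sparser and
thinned toward the top, and *dead* crowns are bare grey-brown speckle
with exposed branches.  Matching field practice, only weakened and dead
trees are annotated (class ids 0 and 1); healthy canopy is background the
detector must learn to ignore.

Crowns are layered soft ellipses over a textured green/brown clutter
background.  Later-drawn crowns occlude earlier ones; annotation boxes
cover the *visible* extent (what an annotator would draw on the image),
computed from a per-pixel ownership buffer.  Everything is drawn from one
`numpy` generator seeded per scene, so a (config, seed) pair reproduces
the image and its annotations bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .boxes import AxisBox, iou
from .dataset_io import split_dataset, write_yolo_labels
from .metrics import Detection

__all__ = ["SceneConfig", "SceneSample", "render_scene", "generate_dataset",
           "perturb_detections", "CLASS_NAMES", "GenerationError"]

CLASS_NAMES = ["Weak", "Dead"]          # annotated classes; healthy is background

# fixed palette (R, G, B); per-tree jitter is applied on top
PALETTE = {
    "background_green": (52, 84, 44),
    "background_brown": (96, 78, 52),
    "healthy": (30, 72, 34),
    "weak": (148, 144, 58),
    "dead": (138, 114, 92),
    "trunk": (84, 60, 40),
}

HEALTHY, WEAK, DEAD = -1, 0, 1          # internal class codes; healthy unannotated


class GenerationError(RuntimeError):
    """Raised when placement constraints cannot be satisfied."""


@dataclass(frozen=True)
class SceneConfig:
    image_size: int = 640
    view_mode: str = "ortho"                       # "ortho" | "oblique"
    n_trees: tuple = (8, 16)                       # inclusive range
    class_mix: tuple = (0.5, 0.3, 0.2)             # healthy, weak, dead
    crown_size_range: tuple = (24, 88)             # crown width in px
    aspect_ratio_range: tuple | None = None        # h/w; regime default if None
    ortho_max_side: int = 90                       # cap on annotated ortho boxes
    occlusion_max_fraction: float = 0.3            # max pairwise box IoU
    color_jitter: float = 0.08
    background_clutter: float = 0.5

    def __post_init__(self):
        if self.view_mode not in ("ortho", "oblique"):
            raise ValueError("view_mode must be 'ortho' or 'oblique'")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not (0.0 <= self.occlusion_max_fraction < 1.0):
            raise ValueError("occlusion_max_fraction must be in [0, 1)")
        if self.crown_size_range[0] > self.crown_size_range[1]:
            raise ValueError("empty crown_size_range")

    @property
    def aspect_range(self) -> tuple:
        if self.aspect_ratio_range is not None:
            return self.aspect_ratio_range
        return (0.8, 1.25) if self.view_mode == "ortho" else (2.0, 5.0)


@dataclass
class SceneSample:
    image: np.ndarray                  # (H, W, 3) uint8
    truths: list                       # (AxisBox, class_id in {0 Weak, 1 Dead})
    metadata: dict = field(default_factory=dict)


def _background(size: int, clutter: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth green/brown mottle plus fine speckle."""
    coarse = rng.random((size // 16 + 1, size // 16 + 1))
    # bilinear upsample of the coarse mottle field
    yy = np.linspace(0, coarse.shape[0] - 1, size)
    xx = np.linspace(0, coarse.shape[1] - 1, size)
    y0 = np.floor(yy).astype(int).clip(0, coarse.shape[0] - 2)
    x0 = np.floor(xx).astype(int).clip(0, coarse.shape[1] - 2)
    fy = (yy - y0)[:, None]
    fx = (xx - x0)[None, :]
    m = (coarse[np.ix_(y0, x0)] * (1 - fy) * (1 - fx)
         + coarse[np.ix_(y0 + 1, x0)] * fy * (1 - fx)
         + coarse[np.ix_(y0, x0 + 1)] * (1 - fy) * fx
         + coarse[np.ix_(y0 + 1, x0 + 1)] * fy * fx)
    green = np.array(PALETTE["background_green"], dtype=float)
    brown = np.array(PALETTE["background_brown"], dtype=float)
    img = green[None, None] * (1 - m[..., None] * clutter) \
        + brown[None, None] * (m[..., None] * clutter)
    img += rng.normal(0.0, 6.0, size=img.shape)
    return img


def _sample_tree(cfg: SceneConfig, rng: np.random.Generator) -> dict:
    u = rng.random()
    mix = np.cumsum(cfg.class_mix)
    cls = HEALTHY if u < mix[0] else (WEAK if u < mix[1] else DEAD)
    w = rng.uniform(*cfg.crown_size_range)
    ar = rng.uniform(*cfg.aspect_range)
    h = w * ar
    if cfg.view_mode == "ortho":
        cap = cfg.ortho_max_side * cfg.image_size / 640.0
        scale = min(1.0, cap / max(w, h))
        w, h = w * scale, h * scale
    return {"cls": cls, "w": w, "h": h}


def _place_trees(cfg: SceneConfig, rng: np.random.Generator) -> list:
    lo, hi = cfg.n_trees
    n = int(rng.integers(lo, hi + 1))
    size = cfg.image_size
    placed = []
    for _ in range(n):
        t = _sample_tree(cfg, rng)
        for _attempt in range(200):
            cx = rng.uniform(t["w"] / 2, size - t["w"] / 2)
            cy = rng.uniform(t["h"] / 2, size - t["h"] / 2)
            box = AxisBox(cx, cy, t["w"], t["h"])
            if all(iou(box, p["box"]) <= cfg.occlusion_max_fraction for p in placed):
                placed.append({**t, "box": box})
                break
        else:
            raise GenerationError(
                f"could not place {n} trees of size ~{cfg.crown_size_range} in a "
                f"{size} px scene under occlusion budget {cfg.occlusion_max_fraction}")
    return placed


def _draw_crown(img: np.ndarray, owner: np.ndarray, idx: int, tree: dict,
                cfg: SceneConfig, rng: np.random.Generator):
    size = cfg.image_size
    box: AxisBox = tree["box"]
    cls = tree["cls"]
    x1 = max(0, int(np.floor(box.cx - box.w / 2)))
    y1 = max(0, int(np.floor(box.cy - box.h / 2)))
    x2 = min(size, int(np.ceil(box.cx + box.w / 2)))
    y2 = min(size, int(np.ceil(box.cy + box.h / 2)))
    yy, xx = np.mgrid[y1:y2, x1:x2]
    # crown ellipse occupies the upper part in oblique view (trunk below)
    trunk_frac = 0.25 if cfg.view_mode == "oblique" else 0.0
    crown_h = box.h * (1 - trunk_frac)
    ccy = box.cy - box.h / 2 + crown_h / 2
    r2 = (((xx + 0.5) - box.cx) / (box.w / 2)) ** 2 \
        + (((yy + 0.5) - ccy) / (crown_h / 2)) ** 2
    density = {HEALTHY: 0.97, WEAK: 0.60, DEAD: 0.38}[cls]
    speck = rng.random(r2.shape)
    mask = (r2 <= 1.0) & (speck < density * np.clip(1.35 - r2, 0.0, 1.0) * 1.2)
    if cls == WEAK:  # thinned top: extra needle loss in the crown's upper third
        top = (yy + 0.5) < (ccy - crown_h / 6)
        mask &= ~(top & (speck > density * 0.55))
    color_key = {HEALTHY: "healthy", WEAK: "weak", DEAD: "dead"}[cls]
    base = np.array(PALETTE[color_key], dtype=float)
    jit = 1.0 + rng.normal(0.0, cfg.color_jitter, size=3)
    shade = 1.0 - 0.25 * np.clip(r2, 0.0, 1.0)  # darker toward the rim
    patch_color = base[None, None] * jit[None, None] * shade[..., None]
    if cls == DEAD:  # exposed branches: a few radial spokes
        ang = np.arctan2((yy + 0.5) - ccy, (xx + 0.5) - box.cx)
        spokes = np.cos(ang * int(rng.integers(5, 9)) + rng.uniform(0, np.pi)) > 0.92
        branch = (r2 <= 1.0) & spokes
        mask |= branch
        patch_color = np.where(branch[..., None],
                               np.array(PALETTE["trunk"], dtype=float) * 1.2,
                               patch_color)
    if trunk_frac > 0.0:
        tw = max(2.0, box.w * 0.12)
        trunk = (np.abs((xx + 0.5) - box.cx) <= tw / 2) \
            & ((yy + 0.5) >= ccy + crown_h * 0.3) \
            & ((yy + 0.5) <= box.cy + box.h / 2)
        mask |= trunk
        patch_color = np.where(trunk[..., None],
                               np.array(PALETTE["trunk"], dtype=float) * jit[None, None],
                               patch_color)
    img[y1:y2, x1:x2][mask] = patch_color[mask]
    owner[y1:y2, x1:x2][mask] = idx


def render_scene(cfg: SceneConfig, seed: int) -> SceneSample:
    """Render one scene; bit-identical for equal (cfg, seed)."""
    rng = np.random.default_rng(seed)
    size = cfg.image_size
    img = _background(size, cfg.background_clutter, rng)
    owner = np.full((size, size), -1, dtype=np.int32)
    trees = _place_trees(cfg, rng)
    for i, t in enumerate(trees):
        _draw_crown(img, owner, i, t, cfg, rng)

    truths, per_tree = [], []
    for i, t in enumerate(trees):
        vis = np.argwhere(owner == i)
        record = {"class": int(t["cls"]), "box": [t["box"].cx, t["box"].cy,
                                                  t["box"].w, t["box"].h]}
        if t["cls"] != HEALTHY and len(vis) >= 4:
            (ys, xs), (ye, xe) = vis.min(axis=0), vis.max(axis=0)
            vbox = AxisBox.from_corners(float(xs), float(ys), float(xe + 1), float(ye + 1))
            truths.append((vbox, int(t["cls"])))
            record["visible_box"] = [vbox.cx, vbox.cy, vbox.w, vbox.h]
        per_tree.append(record)

    image = np.clip(img, 0, 255).astype(np.uint8)
    meta = {"seed": int(seed), "view_mode": cfg.view_mode, "trees": per_tree}
    return SceneSample(image=image, truths=truths, metadata=meta)


def generate_dataset(cfg: SceneConfig, n_images: int, out_dir, seed: int,
                     split_ratio: float = 0.7) -> dict:
    """Write images/, YOLO labels/, 7:3 train/val stem lists and a manifest."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    image_seeds = [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n_images)]
    stems = []
    for i, s in enumerate(image_seeds):
        stem = f"scene_{i:05d}"
        sample = render_scene(cfg, s)
        Image.fromarray(sample.image).save(out / "images" / f"{stem}.png")
        write_yolo_labels(out / "labels" / f"{stem}.txt",
                          [(cid, box) for box, cid in sample.truths],
                          cfg.image_size, cfg.image_size)
        stems.append(stem)
    train, val = split_dataset(stems, split_ratio, seed)
    (out / "train.txt").write_text("\n".join(train) + "\n")
    (out / "val.txt").write_text("\n".join(val) + "\n")
    manifest = {"config": asdict(cfg), "seed": int(seed),
                "image_seeds": image_seeds, "n_images": n_images,
                "split_ratio": split_ratio, "class_names": CLASS_NAMES,
                "palette": {k: list(v) for k, v in PALETTE.items()}}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def perturb_detections(truths: list, *, image_size: int, seed: int,
                       jitter: float = 0.05, fp_rate: float = 0.0,
                       conf_range: tuple = (0.55, 0.99),
                       miss_rate: float = 0.0, image_id: str = "") -> list:
    """Jittered copies of truth boxes as synthetic detections.

    ``jitter`` scales a Gaussian perturbation of center and log-size by the
    box size; ``fp_rate`` injects that fraction of random false-positive
    boxes; ``miss_rate`` drops truths.  Useful for exercising metrics and
    survey matching without a trained model.
    """
    rng = np.random.default_rng(seed)
    dets = []
    for box, cid in truths:
        if rng.random() < miss_rate:
            continue
        cx = box.cx + rng.normal(0, jitter) * box.w
        cy = box.cy + rng.normal(0, jitter) * box.h
        w = box.w * np.exp(rng.normal(0, jitter))
        h = box.h * np.exp(rng.normal(0, jitter))
        conf = float(rng.uniform(*conf_range))
        dets.append(Detection(AxisBox(cx, cy, w, h), cid, conf, image_id))
    n_fp = int(np.floor(fp_rate * len(truths) + 1e-9))
    for _ in range(n_fp):
        w = float(rng.uniform(10, 60))
        h = float(rng.uniform(10, 60))
        cx = float(rng.uniform(w / 2, image_size - w / 2))
        cy = float(rng.uniform(h / 2, image_size - h / 2))
        cid = int(rng.integers(0, 2))
        conf = float(rng.uniform(conf_range[0], conf_range[1]))
        dets.append(Detection(AxisBox(cx, cy, w, h), cid, conf, image_id))
    return dets
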