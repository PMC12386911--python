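"""Training loop and evaluation harness.

Scenes are trained at the detector's input resolution, so synthetic
training skips letterboxing (scale 1); images from disk are letterboxed
in :func:`crowndetect.detector.predict`.  Optimisation is plain SGD with
momentum, per the study regime; the desk-scale smoke configuration
(small input, narrow width, tens of epochs) lives in
:func:`smoke_configs`.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .detector import (Detector, DetectorConfig, TrainConfig, assign_targets,
                       build_detector, compute_loss, predict, save_checkpoint)
from .metrics import EvalReport, evaluate_detections
from .nn import SGD, Tensor
from .synthetic import CLASS_NAMES, SceneConfig, SceneSample, render_scene

__all__ = ["smoke_configs", "make_scenes", "train_detector", "evaluate_model",
           "smoke_protocol", "TrainHistory"]


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)   # per-epoch dicts
    best_map: float = 0.0
    best_epoch: int = -1


def smoke_configs(input_size: int = 128) -> tuple:
    """Desk-scale detector + scene configs used by tests and examples.

    Crown sizes scale with the input so the object/stride geometry matches
    the full-resolution regime.
    """
    det = DetectorConfig(input_size=input_size, n_classes=2)
    f = input_size / 640.0
    ortho = SceneConfig(image_size=input_size, view_mode="ortho",
                        n_trees=(5, 10),
                        crown_size_range=(max(8, int(56 * f)), max(12, int(120 * f))))
    oblique = SceneConfig(image_size=input_size, view_mode="oblique",
                          n_trees=(4, 8),
                          crown_size_range=(max(6, int(36 * f)), max(10, int(72 * f))))
    return det, ortho, oblique


def smoke_protocol(seed: int = 0, n_train: int = 200, n_val: int = 50,
                   epochs: int = 30, log=None) -> tuple:
    """End-to-end desk-scale training run: 200 mixed ortho/oblique scenes,
    50 held-out scenes, 30 epochs of SGD at the study hyperparameters
    (lr 0.01, momentum 0.8) with cosine decay and batch 4.

    Returns (model, detector_config, history, eval_report).
    """
    det, ortho, oblique = smoke_configs()
    rng = np.random.default_rng(seed)
    s_train, s_val, s_init, s_opt = rng.integers(0, 2 ** 31 - 1, size=4)
    train_scenes = make_scenes(n_train, int(s_train), ortho, oblique)
    val_scenes = make_scenes(n_val, int(s_val), ortho, oblique)
    model = build_detector(det, seed=int(s_init))
    tcfg = TrainConfig(learning_rate=0.01, batch_size=4, epochs=epochs,
                       momentum=0.8, seed=int(s_opt))
    hist = train_detector(model, det, tcfg, train_scenes, val_scenes,
                          epochs=epochs, eval_every=10, log=log)
    report = evaluate_model(model, det, val_scenes)
    return model, det, hist, report


def make_scenes(n: int, seed: int, ortho_cfg: SceneConfig,
                oblique_cfg: SceneConfig | None = None,
                oblique_fraction: float = 0.5) -> list:
    """Render a mixed ortho/oblique scene list with per-scene derived seeds."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    modes = rng.random(n) < (oblique_fraction if oblique_cfg is not None else 0.0)
    out = []
    for i in range(n):
        cfg = oblique_cfg if modes[i] else ortho_cfg
        out.append(render_scene(cfg, int(seeds[i])))
    return out


def _scene_inputs(scene: SceneSample) -> np.ndarray:
    return scene.image.astype(np.float32).transpose(2, 0, 1) / 255.0


def train_detector(model: Detector, cfg: DetectorConfig, tcfg: TrainConfig,
                   train_scenes: list, val_scenes: list | None = None,
                   epochs: int | None = None, eval_every: int = 5,
                   checkpoint_path=None, log=None,
                   start_epoch: int = 0) -> TrainHistory:
    """SGD training over in-memory scenes; returns the per-epoch history."""
    epochs = epochs if epochs is not None else tcfg.epochs
    rng = np.random.default_rng(tcfg.seed)
    opt = SGD(model.parameters(), lr=tcfg.learning_rate,
              momentum=tcfg.momentum, weight_decay=tcfg.weight_decay)
    lr0 = tcfg.learning_rate
    inputs = [_scene_inputs(s) for s in train_scenes]
    targets = [assign_targets([b for b, _ in s.truths],
                              [c for _, c in s.truths], cfg)
               for s in train_scenes]
    hist = TrainHistory()
    n = len(train_scenes)
    for ep in range(start_epoch, start_epoch + epochs):
        model.train()
        # linear warmup over the first epochs, then half-cosine decay of
        # the learning rate to a tenth over the run
        frac = (ep - start_epoch) / max(1, epochs - 1)
        warm = min(1.0, (ep - start_epoch + 1) / 3.0)
        opt.lr = warm * lr0 * (0.1 + 0.9 * 0.5 * (1.0 + np.cos(np.pi * frac)))
        order = rng.permutation(n)
        t0 = time.time()
        tot = box = cls = 0.0
        nb = 0
        for i in range(0, n, tcfg.batch_size):
            idx = order[i:i + tcfg.batch_size]
            x = Tensor(np.stack([inputs[j] for j in idx]), requires_grad=False)
            preds = model(x)
            loss, comps = compute_loss(preds, [targets[j] for j in idx], cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += loss.item()
            box += comps["box"]
            cls += comps["cls"]
            nb += 1
        rec = {"epoch": ep, "loss": tot / nb, "box_loss": box / nb,
               "cls_loss": cls / nb, "time_s": time.time() - t0}
        if val_scenes and ((ep + 1) % eval_every == 0 or ep == start_epoch + epochs - 1):
            report = evaluate_model(model, cfg, val_scenes)
            rec["val_map50"] = report.map50
            if report.map50 >= hist.best_map:
                hist.best_map = report.map50
                hist.best_epoch = ep
                if checkpoint_path is not None:
                    save_checkpoint(model, cfg, checkpoint_path,
                                    {"epoch": ep, "val_map50": report.map50})
        hist.epochs.append(rec)
        if log:
            log(rec)
    if checkpoint_path is not None and hist.best_epoch < 0:
        save_checkpoint(model, cfg, checkpoint_path, {"epoch": start_epoch + epochs - 1})
    return hist


def evaluate_model(model: Detector, cfg: DetectorConfig, scenes: list,
                   iou_thr: float = 0.5, eval_conf: float = 0.05) -> EvalReport:
    """mAP@IoU over a scene list (detections matched within each scene).

    The PR sweep needs low-confidence detections to trace the full recall
    range, so evaluation decodes at ``eval_conf`` regardless of the
    deployment threshold in ``cfg``.
    """
    eval_cfg = replace(cfg, conf_threshold=min(cfg.conf_threshold, eval_conf))
    dets, boxes, classes, img_ids = [], [], [], []
    for i, s in enumerate(scenes):
        sid = f"scene{i}"
        dets.extend(predict(s.image, model, eval_cfg, image_id=sid))
        for b, c in s.truths:
            boxes.append(b)
            classes.append(c)
            img_ids.append(sid)
    return evaluate_detections(dets, boxes, classes, CLASS_NAMES,
                               iou_thr=iou_thr, truth_image_ids=img_ids)
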