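"""Detection evaluation: greedy matching, precision/recall/F1, AP and mAP.

Matching follows the standard protocol: per class, detections are sorted
by descending confidence and each is greedily matched to the unmatched
same-class ground-truth box with highest IoU at or above the threshold
(default 0.5); a ground-truth box is consumed by at most one detection, so
duplicate hits count as false positives.

AP is the area under the precision envelope versus recall using all-points
interpolation (every operating point on the descending-confidence sweep
contributes, not an 11-point grid).  mAP is the unweighted mean of
per-class APs; a "pooled" aggregate that merges all classes into a single
matching problem is also provided for dataset-level summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import AxisBox, iou

__all__ = ["Detection", "MatchOutcome", "EvalReport", "match_detections",
           "precision_recall_f1", "average_precision", "mean_ap",
           "evaluate_detections", "write_report", "read_report"]


@dataclass(frozen=True)
class Detection:
    """A scored, classified box in image pixel coordinates."""

    box: AxisBox
    class_id: int
    confidence: float
    image_id: str = ""

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class MatchOutcome:
    """Per-detection TP flags (descending-confidence order) plus counts."""

    tp_flags: np.ndarray          # bool, aligned with sorted detections
    confidences: np.ndarray       # sorted descending
    n_truth: int

    @property
    def tp(self) -> int:
        return int(self.tp_flags.sum())

    @property
    def fp(self) -> int:
        return int((~self.tp_flags).sum())

    @property
    def fn(self) -> int:
        return self.n_truth - self.tp


@dataclass
class EvalReport:
    """Per-class and aggregate metrics at a fixed matching IoU threshold."""

    iou_threshold: float
    class_names: list
    per_class_ap: dict
    per_class_prf: dict          # class -> (P, R, F1) at best-F1 confidence
    map50: float
    pooled_ap: float
    pr_curves: dict = field(default_factory=dict)  # class -> (recall, precision) arrays


def match_detections(dets: list, truth_boxes: list, truth_classes: list,
                     class_id: int, iou_thr: float = 0.5,
                     truth_image_ids: list | None = None) -> MatchOutcome:
    """Greedy confidence-ordered matching for one class.

    ``dets`` may contain any classes; only ``class_id`` is considered.
    ``truth_image_ids`` (parallel to truths) restricts matches to the same
    image; detections carry their own ``image_id``.
    """
    sel = [d for d in dets if d.class_id == class_id]
    order = sorted(range(len(sel)), key=lambda i: (-sel[i].confidence, i))
    t_idx = [i for i, c in enumerate(truth_classes) if c == class_id]
    used = set()
    flags = np.zeros(len(sel), dtype=bool)
    confs = np.array([sel[i].confidence for i in order], dtype=float)
    for rank, di in enumerate(order):
        d = sel[di]
        best, best_iou = None, -1.0
        for ti in t_idx:  # index order => ties broken by first index
            if ti in used:
                continue
            if truth_image_ids is not None and truth_image_ids[ti] != d.image_id:
                continue
            ov = iou(d.box, truth_boxes[ti])
            if ov >= iou_thr and ov > best_iou:
                best, best_iou = ti, ov
        if best is not None:
            used.add(best)
            flags[rank] = True
    return MatchOutcome(tp_flags=flags, confidences=confs, n_truth=len(t_idx))


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 -> 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _pr_curve(outcome: MatchOutcome):
    tp_cum = np.cumsum(outcome.tp_flags)
    fp_cum = np.cumsum(~outcome.tp_flags)
    denom = np.maximum(tp_cum + fp_cum, 1)
    precision = tp_cum / denom
    recall = tp_cum / outcome.n_truth if outcome.n_truth else np.zeros_like(tp_cum, dtype=float)
    return recall, precision


def average_precision(outcome: MatchOutcome) -> float:
    """All-points-interpolated area under the precision envelope vs recall."""
    if outcome.n_truth == 0:
        return 0.0
    if len(outcome.tp_flags) == 0:
        return 0.0
    recall, precision = _pr_curve(outcome)
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], precision, [0.0]])
    # precision envelope: running max from the right
    p = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum(np.diff(r) * p[1:]))


def mean_ap(per_class_ap: list) -> float:
    """Unweighted mean of per-class average precisions."""
    if not per_class_ap:
        raise ValueError("mean_ap over an empty class list")
    return float(np.mean(per_class_ap))


def _best_f1(outcome: MatchOutcome) -> tuple:
    """P, R, F1 at the confidence cut that maximises F1 along the sweep."""
    if len(outcome.tp_flags) == 0 or outcome.n_truth == 0:
        return 0.0, 0.0, 0.0
    tp_cum = np.cumsum(outcome.tp_flags)
    fp_cum = np.cumsum(~outcome.tp_flags)
    best = (0.0, 0.0, 0.0)
    for k in range(len(tp_cum)):
        p, r, f1 = precision_recall_f1(int(tp_cum[k]), int(fp_cum[k]),
                                       outcome.n_truth - int(tp_cum[k]))
        if f1 > best[2]:
            best = (p, r, f1)
    return best


def evaluate_detections(dets: list, truth_boxes: list, truth_classes: list,
                        class_names: list, iou_thr: float = 0.5,
                        truth_image_ids: list | None = None) -> EvalReport:
    """Full evaluation over all classes plus the pooled aggregate."""
    per_ap, per_prf, curves = {}, {}, {}
    for cid, name in enumerate(class_names):
        out = match_detections(dets, truth_boxes, truth_classes, cid, iou_thr,
                               truth_image_ids)
        per_ap[name] = average_precision(out)
        per_prf[name] = _best_f1(out)
        curves[name] = _pr_curve(out)
    # pooled: all classes merged into one matching problem
    pooled_dets = [Detection(d.box, 0, d.confidence, d.image_id) for d in dets]
    pooled_out = match_detections(pooled_dets, truth_boxes, [0] * len(truth_classes),
                                  0, iou_thr, truth_image_ids)
    pooled = average_precision(pooled_out)
    curves["__pooled__"] = _pr_curve(pooled_out)
    return EvalReport(iou_threshold=iou_thr, class_names=list(class_names),
                      per_class_ap=per_ap, per_class_prf=per_prf,
                      map50=mean_ap(list(per_ap.values())), pooled_ap=pooled,
                      pr_curves=curves)


# -- plain-text serialisation ------------------------------------------------

def write_report(report: EvalReport, path):
    lines = [f"iou_threshold={report.iou_threshold}",
             f"classes={','.join(report.class_names)}",
             f"mAP={report.map50:.6f}",
             f"pooled_AP={report.pooled_ap:.6f}"]
    for name in report.class_names:
        p, r, f1 = report.per_class_prf[name]
        lines.append(f"class[{name}] AP={report.per_class_ap[name]:.6f} "
                     f"P={p:.6f} R={r:.6f} F1={f1:.6f}")
    for name, (rec, prec) in report.pr_curves.items():
        pts = ";".join(f"{r:.6f},{p:.6f}" for r, p in zip(rec, prec))
        lines.append(f"pr[{name}]={pts}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_report(path) -> dict:
    """Parse a written report back into a plain dict (loss-free for scalars)."""
    out = {"classes": [], "per_class": {}, "pr": {}}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("iou_threshold="):
                out["iou_threshold"] = float(line.split("=", 1)[1])
            elif line.startswith("classes="):
                out["classes"] = line.split("=", 1)[1].split(",")
            elif line.startswith("mAP="):
                out["mAP"] = float(line.split("=", 1)[1])
            elif line.startswith("pooled_AP="):
                out["pooled_AP"] = float(line.split("=", 1)[1])
            elif line.startswith("class["):
                name = line[len("class["):line.index("]")]
                fields = dict(kv.split("=") for kv in line.split("] ", 1)[1].split())
                out["per_class"][name] = {k: float(v) for k, v in fields.items()}
            elif line.startswith("pr["):
                name = line[len("pr["):line.index("]")]
                body = line.split("=", 1)[1]
                if body:
                    pts = [tuple(map(float, p.split(","))) for p in body.split(";")]
                    out["pr"][name] = pts
    return out
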