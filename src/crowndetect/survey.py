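"""Ground-survey validation of detector output.

Field crews record damaged trees as georeferenced points (here: pixel
positions in a referenced image), split into trees damaged in previous
years and trees newly damaged in the current season.  Validation proceeds
in three steps:

1. keep only detections with confidence strictly greater than a threshold
   (0.60 by default) to suppress false positives;
2. a survey point counts as successfully detected (SD) when it falls
   inside at least one retained box of the *Weak* class in its image —
   survey targets are weakened, still-living trees, so Dead boxes do not
   match by default (configurable);
3. the accuracy rate per category is AR% = 100 * SD / DT, with DT the
   number of surveyed damaged trees, rounded half-up to two decimals; the
   overall AR pools the counts (sum of SD over sum of DT), not the mean of
   the category rates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .metrics import Detection

__all__ = ["SurveyPoint", "CategoryResult", "SurveyReport",
           "filter_by_confidence", "match_survey_points", "accuracy_rate",
           "build_survey_report", "read_survey_points", "write_survey_points",
           "render_report_table", "CATEGORIES", "WEAK_CLASS_ID", "DEAD_CLASS_ID"]

CATEGORIES = ("previously_damaged", "newly_damaged")
WEAK_CLASS_ID = 0
DEAD_CLASS_ID = 1


@dataclass(frozen=True)
class SurveyPoint:
    image_id: str
    x: float
    y: float
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown survey category {self.category!r}; "
                             f"expected one of {CATEGORIES}")


@dataclass(frozen=True)
class CategoryResult:
    category: str
    dt: int      # damaged trees surveyed
    sd: int      # successfully detected
    ar: float    # percentage


@dataclass
class SurveyReport:
    per_category: list            # CategoryResult per category
    overall: CategoryResult
    n_weak_detections: int        # retained Weak boxes
    n_dead_detections: int        # retained Dead boxes


def filter_by_confidence(dets: list, threshold: float = 0.60) -> list:
    """Retain detections with confidence strictly greater than threshold."""
    return [d for d in dets if d.confidence > threshold]


def _point_in_box(px: float, py: float, det: Detection) -> bool:
    x1, y1, x2, y2 = det.box.corners
    return x1 <= px <= x2 and y1 <= py <= y2   # boundary-inclusive


def match_survey_points(points: list, dets: list,
                        match_class_ids: tuple = (WEAK_CLASS_ID,),
                        known_images: set | None = None) -> list:
    """Per-point matched flags against already-filtered detections.

    A point matches when it lies inside >= 1 detection of an eligible class
    in its own image; points are evaluated independently, so one box may
    cover several points.
    """
    if known_images is not None:
        for p in points:
            if p.image_id not in known_images:
                raise KeyError(f"survey point references unknown image {p.image_id!r}")
    by_img: dict = {}
    for d in dets:
        if d.class_id in match_class_ids:
            by_img.setdefault(d.image_id, []).append(d)
    return [any(_point_in_box(p.x, p.y, d) for d in by_img.get(p.image_id, ()))
            for p in points]


def accuracy_rate(dt: int, sd: int) -> float:
    """AR% = 100 * SD / DT, rounded half-up to two decimals."""
    if dt <= 0:
        raise ValueError("accuracy rate undefined for DT = 0")
    if not (0 <= sd <= dt):
        raise ValueError("SD must satisfy 0 <= SD <= DT")
    return float((Decimal(100) * Decimal(sd) / Decimal(dt)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))


def build_survey_report(points: list, dets: list,
                        conf_threshold: float = 0.60,
                        match_class_ids: tuple = (WEAK_CLASS_ID,),
                        known_images: set | None = None) -> SurveyReport:
    """Confidence-filter, match, and tabulate per-category and overall AR."""
    kept = filter_by_confidence(dets, conf_threshold)
    matched = match_survey_points(points, kept, match_class_ids, known_images)
    per = []
    for cat in CATEGORIES:
        idx = [i for i, p in enumerate(points) if p.category == cat]
        dt = len(idx)
        sd = sum(matched[i] for i in idx)
        per.append(CategoryResult(cat, dt, sd, accuracy_rate(dt, sd) if dt else 0.0))
    dt_all = sum(c.dt for c in per)
    sd_all = sum(c.sd for c in per)
    overall = CategoryResult("overall", dt_all, sd_all,
                             accuracy_rate(dt_all, sd_all) if dt_all else 0.0)
    return SurveyReport(
        per_category=per, overall=overall,
        n_weak_detections=sum(d.class_id == WEAK_CLASS_ID for d in kept),
        n_dead_detections=sum(d.class_id == DEAD_CLASS_ID for d in kept))


def render_report_table(report: SurveyReport) -> str:
    """Aligned plain-text table of retained counts and per-category AR."""
    rows = [("Category", "DT", "SD", "AR (%)"),
            ("Model detected Weak", str(report.n_weak_detections), "-", "-"),
            ("Model detected Dead", str(report.n_dead_detections), "-", "-")]
    for c in report.per_category + [report.overall]:
        rows.append((c.category.replace("_", " "), str(c.dt), str(c.sd), f"{c.ar:.2f}"))
    widths = [max(len(r[i]) for r in rows) for i in range(4)]
    return "\n".join("  ".join(f"{v:<{w}}" for v, w in zip(r, widths)).rstrip()
                     for r in rows)


# -- CSV interface -----------------------------------------------------------

def read_survey_points(path) -> list:
    """CSV with header image_id,x,y,category."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(SurveyPoint(row["image_id"], float(row["x"]),
                                   float(row["y"]), row["category"].strip()))
    return out


def write_survey_points(points: list, path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "x", "y", "category"])
        for p in points:
            w.writerow([p.image_id, p.x, p.y, p.category])
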