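"""Annotation readers/writers and dataset split utilities.

Two annotation dialects are supported:

* LabelImg-style Pascal-VOC XML, whose ``bndbox`` corners are 1-based
  *inclusive* pixel indices — a box spanning xmin=1..xmax=100 covers 100
  pixel columns, hence width = xmax - xmin + 1 in pixel-count terms but,
  under the continuous convention used internally (corner at xmin-1,
  far edge at xmax), width = xmax - xmin + 1 - ... ; see ``_voc_to_box``
  for the exact arithmetic used (and tested).
* YOLO plain-text labels: one ``class cx cy w h`` line per object, all
  four geometry fields normalised to [0, 1] by the image size.

The default class vocabulary maps Weak -> 0 and Dead -> 1; a custom
mapping supports multi-disease vocabularies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .boxes import AxisBox

__all__ = ["AnnotatedImage", "DEFAULT_CLASS_MAP", "read_voc_xml",
           "write_voc_xml", "read_yolo_labels", "write_yolo_labels",
           "yolo_line_to_pixels", "pixels_to_yolo_line", "split_dataset",
           "read_class_map", "write_class_map"]

DEFAULT_CLASS_MAP = {"Weak": 0, "Dead": 1}


@dataclass
class AnnotatedImage:
    image_path: str
    width: int
    height: int
    objects: list = field(default_factory=list)   # (AxisBox, class_name)
    unknown_classes: set = field(default_factory=set)


def _voc_to_box(xmin: float, ymin: float, xmax: float, ymax: float) -> AxisBox:
    """1-based inclusive VOC corners -> continuous center/size box.

    The 1-based pixel column i has its centre at continuous coordinate
    i - 0.5 (origin top-left, pixel centres at integer + 0.5).  The corner
    fields of the LabelImg dialect index the first and last pixel of the
    rectangle inclusively, so the box spans their centres: a record
    (1, 1, 100, 50) becomes centre (50.0, 25.0), size (99, 49).
    """
    return AxisBox.from_corners(xmin - 0.5, ymin - 0.5, xmax - 0.5, ymax - 0.5)


def _box_to_voc(box: AxisBox) -> tuple:
    x1, y1, x2, y2 = box.corners
    return x1 + 0.5, y1 + 0.5, x2 + 0.5, y2 + 0.5


class VocParseError(ValueError):
    pass


def read_voc_xml(path, class_map: dict = DEFAULT_CLASS_MAP) -> AnnotatedImage:
    """Parse a LabelImg Pascal-VOC XML annotation file."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise VocParseError(f"{path}: malformed XML ({e})") from e
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise VocParseError(f"{path}: missing <size> element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    filename = root.findtext("filename") or path.stem

    ann = AnnotatedImage(image_path=filename, width=width, height=height)
    for obj in root.findall("object"):
        name = obj.findtext("name")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise VocParseError(f"{path}: <object> without <bndbox> (line {obj.sourceline})")
        xmin = float(bnd.findtext("xmin"))
        ymin = float(bnd.findtext("ymin"))
        xmax = float(bnd.findtext("xmax"))
        ymax = float(bnd.findtext("ymax"))
        box = _voc_to_box(xmin, ymin, xmax, ymax)
        if name not in class_map:
            ann.unknown_classes.add(name)
        ann.objects.append((box, name))
    return ann


def write_voc_xml(ann: AnnotatedImage, path):
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = ann.image_path
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.width)
    etree.SubElement(size, "height").text = str(ann.height)
    etree.SubElement(size, "depth").text = "3"
    for box, name in ann.objects:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = name
        bnd = etree.SubElement(obj, "bndbox")
        x1, y1, x2, y2 = _box_to_voc(box)
        etree.SubElement(bnd, "xmin").text = repr(x1) if x1 != int(x1) else str(int(x1))
        etree.SubElement(bnd, "ymin").text = repr(y1) if y1 != int(y1) else str(int(y1))
        etree.SubElement(bnd, "xmax").text = repr(x2) if x2 != int(x2) else str(int(x2))
        etree.SubElement(bnd, "ymax").text = repr(y2) if y2 != int(y2) else str(int(y2))
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


# -- YOLO text labels --------------------------------------------------------

def yolo_line_to_pixels(line: str, image_w: int, image_h: int) -> tuple:
    parts = line.split()
    cid = int(parts[0])
    cx, cy, w, h = (float(p) for p in parts[1:5])
    return cid, AxisBox(cx * image_w, cy * image_h, w * image_w, h * image_h)


def pixels_to_yolo_line(class_id: int, box: AxisBox, image_w: int, image_h: int) -> str:
    vals = (box.cx / image_w, box.cy / image_h, box.w / image_w, box.h / image_h)
    return f"{class_id} " + " ".join(f"{v:.6f}" for v in vals)


def read_yolo_labels(path, image_w: int, image_h: int) -> list:
    """Read a YOLO label file -> list of (class_id, AxisBox in pixels)."""
    out, bad = [], []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 5:
            bad.append(ln)
            continue
        vals = [float(p) for p in parts[1:5]]
        if any(not (0.0 <= v <= 1.0) for v in vals):
            bad.append(ln)
            continue
        out.append(yolo_line_to_pixels(line, image_w, image_h))
    if bad:
        raise ValueError(f"{path}: malformed or out-of-range label lines {bad}")
    return out


def write_yolo_labels(path, objects: list, image_w: int, image_h: int):
    """Write (class_id, AxisBox) pairs as YOLO normalised text."""
    lines = [pixels_to_yolo_line(cid, box, image_w, image_h) for cid, box in objects]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# -- splits and class maps ---------------------------------------------------

def split_dataset(stems: list, ratio: float = 0.7, seed: int = 0) -> tuple:
    """Seeded shuffle split; train size = round(ratio * n); disjoint, exhaustive."""
    if not stems:
        raise ValueError("cannot split an empty stem list")
    rng = np.random.default_rng(seed)
    order = list(stems)
    rng.shuffle(order)
    n_train = round(ratio * len(order))
    return order[:n_train], order[n_train:]


def read_class_map(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            name, idx = line.split()
            out[name] = int(idx)
    return out


def write_class_map(class_map: dict, path):
    Path(path).write_text("\n".join(f"{k} {v}" for k, v in
                                    sorted(class_map.items(), key=lambda kv: kv[1])) + "\n")
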