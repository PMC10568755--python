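"""Bounding-box labels, annotation file formats, and dataset splitting.

Coordinates are 0-based pixel corners, x right / y down, half-open in the
sense that a box spans [x1, x2) x [y1, y2) with 0 <= x1 < x2 <= W.  Two
annotation dialects are supported: Pascal-VOC XML (the LabelImg output) and
normalised YOLO txt (``class cx cy w h``).  Round trips are lossless to
within 1 px of normalisation rounding.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["CLASS_NAMES", "BoxLabel", "read_labels", "write_labels",
           "split_dataset", "LabelParseError"]

CLASS_NAMES = ("not_sprout", "sprout")
_NAME_TO_ID = {n: i for i, n in enumerate(CLASS_NAMES)}


class LabelParseError(ValueError):
    pass


@dataclass
class BoxLabel:
    """One annotated seed: class plus corner coordinates in the image frame."""
    cls: int
    x1: float
    y1: float
    x2: float
    y2: float

    @property
    def name(self) -> str:
        return CLASS_NAMES[self.cls]

    @property
    def area(self) -> float:
        return max(0.0, self.x2 - self.x1) * max(0.0, self.y2 - self.y1)

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2, self.cls],
                        dtype=np.float64)


def read_labels(path, dialect: str,
                image_size: Tuple[int, int] | None = None) -> List[BoxLabel]:
    """Read a label file.  ``image_size=(W, H)`` is required for yolo_txt."""
    path = Path(path)
    if dialect == "voc_xml":
        return _read_voc(path)
    if dialect == "yolo_txt":
        if image_size is None:
            raise ValueError("yolo_txt requires image_size=(W, H)")
        return _read_yolo(path, image_size)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_labels(labels: Sequence[BoxLabel], path, dialect: str,
                 image_size: Tuple[int, int]):
    path = Path(path)
    w, h = image_size
    if dialect == "voc_xml":
        _write_voc(labels, path, w, h)
    elif dialect == "yolo_txt":
        lines = []
        for b in labels:
            cx, cy = (b.x1 + b.x2) / 2 / w, (b.y1 + b.y2) / 2 / h
            bw, bh = (b.x2 - b.x1) / w, (b.y2 - b.y1) / h
            lines.append(f"{b.cls} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_yolo(path: Path, image_size) -> List[BoxLabel]:
    w, h = image_size
    out = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 5:
            raise LabelParseError(f"{path}:{i}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(float(parts[0]))
            cx, cy, bw, bh = (float(v) for v in parts[1:5])
        except ValueError as e:
            raise LabelParseError(f"{path}:{i}: {e}") from e
        out.append(BoxLabel(cls, (cx - bw / 2) * w, (cy - bh / 2) * h,
                            (cx + bw / 2) * w, (cy + bh / 2) * h))
    return out


def _read_voc(path: Path) -> List[BoxLabel]:
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as e:
        raise LabelParseError(f"{path}: malformed XML: {e}") from e
    out = []
    for i, obj in enumerate(root.iter("object")):
        name_el = obj.find("name")
        box_el = obj.find("bndbox")
        if name_el is None or box_el is None:
            raise LabelParseError(f"{path}: object {i}: missing name/bndbox")
        name = name_el.text.strip()
        if name not in _NAME_TO_ID:
            raise LabelParseError(f"{path}: object {i}: unknown class {name!r}")
        try:
            vals = [float(box_el.find(t).text) for t in
                    ("xmin", "ymin", "xmax", "ymax")]
        except (AttributeError, ValueError) as e:
            raise LabelParseError(f"{path}: object {i}: bad bndbox: {e}") from e
        out.append(BoxLabel(_NAME_TO_ID[name], *vals))
    return out


def _write_voc(labels, path: Path, w: int, h: int):
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = path.stem
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "3"
    for b in labels:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = b.name
        box = ET.SubElement(obj, "bndbox")
        ET.SubElement(box, "xmin").text = f"{b.x1:.1f}"
        ET.SubElement(box, "ymin").text = f"{b.y1:.1f}"
        ET.SubElement(box, "xmax").text = f"{b.x2:.1f}"
        ET.SubElement(box, "ymax").text = f"{b.y2:.1f}"
    ET.ElementTree(root).write(str(path))


def split_dataset(items: Sequence, ratios=(3, 1, 1), seed: int = 0,
                  key=None) -> Tuple[list, list, list]:
    """Random disjoint, exhaustive train/val/test split.

    Ratios are normalised; sizes follow largest-remainder rounding.  With
    ``key`` (e.g. plate id) all items sharing a key land in the same split.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.sum() <= 0:
        raise ValueError("ratios must sum to a positive value")
    ratios = ratios / ratios.sum()
    if key is not None:
        groups = {}
        for it in items:
            groups.setdefault(key(it), []).append(it)
        gsplit = split_dataset(sorted(groups), ratios, seed)
        return tuple([it for g in part for it in groups[g]] for part in gsplit)
    n = len(items)
    if n < (ratios > 0).sum():
        raise ValueError(f"cannot split {n} items into {(ratios > 0).sum()} parts")
    exact = ratios * n
    sizes = np.floor(exact).astype(int)
    rem = exact - sizes
    for i in np.argsort(-rem)[: n - sizes.sum()]:
        sizes[i] += 1
    order = np.random.default_rng(seed).permutation(n)
    out, ofs = [], 0
    for s in sizes:
        out.append([items[i] for i in order[ofs:ofs + s]])
        ofs += s
    return tuple(out)
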