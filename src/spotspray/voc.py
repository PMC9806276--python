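"""PASCAL VOC XML annotation I/O (CVAT dialect) and dataset splitting.

One XML file per image, with ``<object><bndbox>`` entries holding inclusive
1-based ``xmin/ymin/xmax/ymax`` as written by CVAT's VOC export.  Reading
converts to 0-based half-open pixel rectangles; writing does the inverse.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class VocAnnotation:
    filename: str
    width: int
    height: int
    boxes: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))  # xyxy, 0-based half-open
    names: list[str] = field(default_factory=list)


def read_voc(path: str | Path) -> VocAnnotation:
    root = ET.parse(str(path)).getroot()
    size = root.find("size")
    ann = VocAnnotation(
        filename=root.findtext("filename", default=""),
        width=int(size.findtext("width")), height=int(size.findtext("height")))
    boxes, names = [], []
    for obj in root.findall("object"):
        bb = obj.find("bndbox")
        xmin = float(bb.findtext("xmin")) - 1
        ymin = float(bb.findtext("ymin")) - 1
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        boxes.append([xmin, ymin, xmax, ymax])
        names.append(obj.findtext("name", default=""))
    ann.boxes = np.array(boxes, dtype=float).reshape(-1, 4)
    ann.names = names
    return ann


def write_voc(path: str | Path, filename: str, width: int, height: int,
              boxes: np.ndarray, names: list[str] | str = "weed") -> None:
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    if isinstance(names, str):
        names = [names] * len(boxes)
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = filename
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(width)
    ET.SubElement(size, "height").text = str(height)
    ET.SubElement(size, "depth").text = "3"
    for (x1, y1, x2, y2), name in zip(boxes, names):
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = name
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = str(int(round(x1)) + 1)
        ET.SubElement(bb, "ymin").text = str(int(round(y1)) + 1)
        ET.SubElement(bb, "xmax").text = str(int(round(x2)))
        ET.SubElement(bb, "ymax").text = str(int(round(y2)))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), encoding="unicode")


def split_dataset(items: list, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> tuple[list, list, list]:
    """Random train/val/test split (default 8:1:1), reproducible by seed.

    Fractional boundaries are rounded so every item lands in exactly one
    split and train gets any remainder.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_val = int(round(len(items) * ratios[1]))
    n_test = int(round(len(items) * ratios[2]))
    n_train = len(items) - n_val - n_test
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:n_train + n_val]]
    test = [items[i] for i in order[n_train + n_val:]]
    return train, val, test
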