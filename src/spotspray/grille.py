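"""Grille decision algorithm: prediction boxes -> valve open/close bits.

A single row of grid cells ("grille") spans the image width; each cell maps
to one solenoid valve.  Per frame, a cell's bit is set to 1 when some
detection box overlaps it by strictly more than an area threshold.  The
evaluation is stateless: a bit drops back to 0 in the first frame whose
boxes no longer clear the threshold, like a momentary switch pressed while
a box passes over the cell.

Rectangles are 0-based, half-open ``[x1, x2) x [y1, y2)`` in pixel
coordinates with the origin at the top-left and y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .calibration import InvalidConfigurationError


@dataclass(frozen=True)
class PredictionBox:
    """One detection: pixel rectangle, class id, confidence."""

    x1: float
    y1: float
    x2: float
    y2: float
    class_id: int = 0
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError(
                f"degenerate box: ({self.x1}, {self.y1}, {self.x2}, {self.y2})")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    def clipped(self, image_width_px: int, image_height_px: int) -> "PredictionBox | None":
        """Clip to image bounds; None if nothing remains."""
        x1 = max(self.x1, 0.0)
        y1 = max(self.y1, 0.0)
        x2 = min(self.x2, float(image_width_px))
        y2 = min(self.y2, float(image_height_px))
        if x2 <= x1 or y2 <= y1:
            return None
        return PredictionBox(x1, y1, x2, y2, self.class_id, self.confidence)


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle (grille cell)."""

    x1: float
    y1: float
    x2: float
    y2: float

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)


@dataclass(frozen=True)
class GrilleConfig:
    """Geometry of the valve grid row.

    ``n_cells`` cells tile ``[0, image_width_px)`` exactly, any remainder
    pixels distributed one-per-cell from the left.  The row sits at
    ``row_top_px`` (defaults to the bottom of a 1080-row frame, where ground
    just ahead of the nozzles appears as the image scrolls downward).
    ``area_threshold_px2`` is the strict overlap-area trigger; 0 means any
    positive overlap opens the valve.
    """

    n_cells: int = 11
    image_width_px: int = 1920
    image_height_px: int = 1080
    row_height_px: int = 60
    row_top_px: int | None = None
    area_threshold_px2: float = 0.0
    weed_class_id: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidConfigurationError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.n_cells > self.image_width_px:
            raise InvalidConfigurationError(
                f"n_cells={self.n_cells} exceeds image width {self.image_width_px}")
        if self.row_height_px < 1:
            raise InvalidConfigurationError("row_height_px must be >= 1")
        if self.area_threshold_px2 < 0:
            raise InvalidConfigurationError("area_threshold_px2 must be >= 0")
        if self.top + self.row_height_px > self.image_height_px:
            raise InvalidConfigurationError(
                f"grille row [{self.top}, {self.top + self.row_height_px}) exceeds "
                f"image height {self.image_height_px}")

    @property
    def top(self) -> int:
        if self.row_top_px is not None:
            return self.row_top_px
        return self.image_height_px - self.row_height_px


@dataclass(frozen=True)
class DecisionVector:
    """Per-frame open(1)/closed(0) state, index 0 = leftmost valve."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0 or 1")

    def __len__(self) -> int:
        return len(self.bits)

    def __iter__(self) -> Iterator[int]:
        return iter(self.bits)

    def __getitem__(self, i: int) -> int:
        return self.bits[i]

    def as_string(self) -> str:
        return "".join(str(b) for b in self.bits)


def build_grille(config: GrilleConfig) -> list[Rect]:
    """Cell rectangles tiling the image width; widths differ by at most 1 px."""
    base, extra = divmod(config.image_width_px, config.n_cells)
    cells: list[Rect] = []
    x = 0
    top, bot = config.top, config.top + config.row_height_px
    for i in range(config.n_cells):
        w = base + (1 if i < extra else 0)
        cells.append(Rect(float(x), float(top), float(x + w), float(bot)))
        x += w
    return cells


def intersection_area(box: PredictionBox, cell: Rect) -> float:
    """Overlap area [px^2] of a box and a cell (half-open rectangles)."""
    ox = min(box.x2, cell.x2) - max(box.x1, cell.x1)
    oy = min(box.y2, cell.y2) - max(box.y1, cell.y1)
    return max(0.0, ox) * max(0.0, oy)


def decide_frame(boxes: Sequence[PredictionBox], config: GrilleConfig) -> DecisionVector:
    """One frame's valve bits: OR over boxes of strict-threshold cell overlap.

    Only boxes of the configured weed class participate; boxes are clipped
    to the image first.  A bit is set iff some box overlaps the cell by
    strictly more than ``area_threshold_px2``.
    """
    cells = build_grille(config)
    bits = [0] * config.n_cells
    for raw in boxes:
        if raw.class_id != config.weed_class_id:
            continue
        box = raw.clipped(config.image_width_px, config.image_height_px)
        if box is None:
            continue
        for i, cell in enumerate(cells):
            if bits[i]:
                continue
            if intersection_area(box, cell) > config.area_threshold_px2:
                bits[i] = 1
    return DecisionVector(tuple(bits))


def decision_stream(frame_boxes: Iterable[Sequence[PredictionBox]],
                    config: GrilleConfig) -> list[DecisionVector]:
    """Stateless per-frame decisions for a sequence of frames."""
    return [decide_frame(boxes, config) for boxes in frame_boxes]
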