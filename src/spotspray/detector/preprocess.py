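"""Image preprocessing: letterbox resize and mosaic augmentation.

Images are HWC uint8 or float arrays; boxes are (N, 4) xyxy pixel arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRAY = 114  # constant pad value


@dataclass(frozen=True)
class LetterboxTransform:
    """Affine record of a letterbox: x' = x*scale + pad."""

    scale: float
    pad_x: float
    pad_y: float

    def apply_boxes(self, boxes: np.ndarray) -> np.ndarray:
        boxes = np.asarray(boxes, dtype=float)
        if boxes.size == 0:
            return boxes.reshape(0, 4)
        out = boxes.copy()
        out[:, [0, 2]] = boxes[:, [0, 2]] * self.scale + self.pad_x
        out[:, [1, 3]] = boxes[:, [1, 3]] * self.scale + self.pad_y
        return out

    def invert_boxes(self, boxes: np.ndarray) -> np.ndarray:
        boxes = np.asarray(boxes, dtype=float)
        if boxes.size == 0:
            return boxes.reshape(0, 4)
        out = boxes.copy()
        out[:, [0, 2]] = (boxes[:, [0, 2]] - self.pad_x) / self.scale
        out[:, [1, 3]] = (boxes[:, [1, 3]] - self.pad_y) / self.scale
        return out


def _resize_nearest(image: np.ndarray, new_h: int, new_w: int) -> np.ndarray:
    h, w = image.shape[:2]
    rows = np.clip((np.arange(new_h) + 0.5) * h / new_h, 0, h - 1).astype(int)
    cols = np.clip((np.arange(new_w) + 0.5) * w / new_w, 0, w - 1).astype(int)
    return image[rows][:, cols]


def letterbox(image: np.ndarray, target_size: int = 640
              ) -> tuple[np.ndarray, LetterboxTransform]:
    """Aspect-preserving resize to ``target x target`` with symmetric gray pad.

    The longer side is scaled to ``target_size``; the shorter side is padded
    equally on both sides (odd remainders put the extra pixel at the
    bottom/right).  Returns the padded image and the invertible transform
    for remapping boxes.
    """
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape[:2]
    scale = target_size / max(h, w)
    new_h, new_w = round(h * scale), round(w * scale)
    resized = _resize_nearest(image, new_h, new_w)
    pad_y = (target_size - new_h) / 2
    pad_x = (target_size - new_w) / 2
    top, left = int(np.floor(pad_y)), int(np.floor(pad_x))
    shape = (target_size, target_size) + image.shape[2:]
    canvas = np.full(shape, GRAY, dtype=image.dtype)
    canvas[top:top + new_h, left:left + new_w] = resized
    return canvas, LetterboxTransform(scale=scale, pad_x=left, pad_y=top)


def mosaic_augment(samples: list[tuple[np.ndarray, np.ndarray]],
                   canvas_size: int = 640,
                   rng: np.random.Generator | None = None,
                   center: tuple[int, int] | None = None,
                   min_box_px: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Compose 4 (image, boxes) samples into one mosaic canvas.

    A random center splits the canvas into four quadrants; each sample is
    scaled (anisotropically) to fill its quadrant and its boxes are mapped
    by the same affine, clipped to the canvas, and dropped when the
    remaining extent is under ``min_box_px`` in either direction.
    """
    if len(samples) != 4:
        raise ValueError(f"mosaic needs exactly 4 samples, got {len(samples)}")
    rng = rng or np.random.default_rng(0)
    if center is None:
        lo, hi = canvas_size // 4, 3 * canvas_size // 4
        cx, cy = int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1))
    else:
        cx, cy = center
    quadrants = [(0, 0, cx, cy), (cx, 0, canvas_size, cy),
                 (0, cy, cx, canvas_size), (cx, cy, canvas_size, canvas_size)]
    canvas = np.full((canvas_size, canvas_size) + samples[0][0].shape[2:],
                     GRAY, dtype=samples[0][0].dtype)
    all_boxes = []
    for (image, boxes), (x0, y0, x1, y1) in zip(samples, quadrants):
        qw, qh = x1 - x0, y1 - y0
        if qw < 1 or qh < 1:
            continue
        h, w = image.shape[:2]
        canvas[y0:y1, x0:x1] = _resize_nearest(image, qh, qw)
        if len(boxes) == 0:
            continue
        b = np.asarray(boxes, dtype=float).copy()
        b[:, [0, 2]] = b[:, [0, 2]] * (qw / w) + x0
        b[:, [1, 3]] = b[:, [1, 3]] * (qh / h) + y0
        b[:, [0, 2]] = np.clip(b[:, [0, 2]], x0, x1)
        b[:, [1, 3]] = np.clip(b[:, [1, 3]], y0, y1)
        keep = ((b[:, 2] - b[:, 0]) >= min_box_px) & ((b[:, 3] - b[:, 1]) >= min_box_px)
        all_boxes.append(b[keep])
    boxes_out = (np.concatenate(all_boxes, axis=0) if all_boxes
                 else np.zeros((0, 4)))
    return canvas, boxes_out
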