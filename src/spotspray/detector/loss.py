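"""Detection training loss: weighted classification + localization + objectness.

``Loss = lambda1 * L_cls + lambda2 * L_loc + lambda3 * L_obj`` with

* ``L_cls`` — binary cross-entropy of per-class logits at positive anchors;
* ``L_loc`` — mean ``1 - IoU`` between decoded positive predictions and
  their assigned ground-truth boxes;
* ``L_obj`` — binary cross-entropy of the objectness map against 1 at
  positive anchors and 0 elsewhere, averaged over the three scales
  (``soft_obj_targets=True`` switches to the IoU-weighted variant, whose
  soft labels put an entropy floor under the loss).

Positive samples are assigned across the grid cell: besides the cell
containing a target's center, the laterally adjacent cell(s) whose center
offset is within half a cell also predict it, and anchors are eligible when
the width/height ratio to the target is below 4.  The balance coefficients
default to single-stage-detector convention (0.5, 0.05, 1.0) and are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, bce_with_logits

ANCHOR_RATIO_LIMIT = 4.0
NEIGHBOR_BIAS = 0.5
DEFAULT_LAMBDAS = (0.5, 0.05, 1.0)


@dataclass(frozen=True)
class LossTerms:
    """The three loss components and their weighted total."""

    L_cls: float
    L_loc: float
    L_obj: float
    lambdas: tuple[float, float, float]

    @property
    def total(self) -> float:
        l1, l2, l3 = self.lambdas
        return l1 * self.L_cls + l2 * self.L_loc + l3 * self.L_obj


def build_targets(targets: list[np.ndarray], anchors: np.ndarray,
                  strides: tuple[int, ...], grid_sizes: list[tuple[int, int]]
                  ) -> list[dict[str, np.ndarray]]:
    """Assign ground-truth boxes to (image, anchor, cell) positives per level.

    ``targets[i]`` is an (Ni, 5) array of ``class, cx, cy, w, h`` in input
    pixels for image i.  Returns one dict per level with integer index
    arrays ``img/anchor/gy/gx``, float ``boxes`` (cx, cy, w, h in pixels)
    and ``anchor_wh``, and integer ``cls``.
    """
    rows = []
    for img_idx, t in enumerate(targets):
        t = np.asarray(t, dtype=float).reshape(-1, 5)
        for row in t:
            rows.append([img_idx, *row])
    per_level = []
    all_t = np.array(rows, dtype=float) if rows else np.zeros((0, 6))
    for level, stride in enumerate(strides):
        H, W = grid_sizes[level]
        level_anchors = anchors[3 * level:3 * level + 3]
        img, anc, gy, gx, boxes, awh, cls = [], [], [], [], [], [], []
        for row in all_t:
            i, c, cx, cy, w, h = row
            for a, (aw, ah) in enumerate(level_anchors):
                ratio = max(w / aw, aw / w, h / ah, ah / h)
                if ratio >= ANCHOR_RATIO_LIMIT:
                    continue
                fx, fy = cx / stride, cy / stride
                cells = {(int(fx), int(fy))}
                # cross-grid expansion: neighbors within half a cell
                if fx % 1 < NEIGHBOR_BIAS and fx > 1:
                    cells.add((int(fx) - 1, int(fy)))
                if fx % 1 > 1 - NEIGHBOR_BIAS and fx < W - 1:
                    cells.add((int(fx) + 1, int(fy)))
                if fy % 1 < NEIGHBOR_BIAS and fy > 1:
                    cells.add((int(fx), int(fy) - 1))
                if fy % 1 > 1 - NEIGHBOR_BIAS and fy < H - 1:
                    cells.add((int(fx), int(fy) + 1))
                for cxi, cyi in sorted(cells):
                    if not (0 <= cxi < W and 0 <= cyi < H):
                        continue
                    img.append(int(i)); anc.append(a)
                    gy.append(cyi); gx.append(cxi)
                    boxes.append([cx, cy, w, h]); awh.append([aw, ah])
                    cls.append(int(c))
        per_level.append({
            "img": np.array(img, dtype=int),
            "anchor": np.array(anc, dtype=int),
            "gy": np.array(gy, dtype=int),
            "gx": np.array(gx, dtype=int),
            "boxes": np.array(boxes, dtype=float).reshape(-1, 4),
            "anchor_wh": np.array(awh, dtype=float).reshape(-1, 2),
            "cls": np.array(cls, dtype=int),
        })
    return per_level


def _pairwise_iou(pxy: Tensor, pwh: Tensor, tboxes: np.ndarray) -> Tensor:
    """Elementwise IoU between decoded (cx, cy, w, h) predictions and targets."""
    px1 = pxy[:, 0] - pwh[:, 0] * 0.5
    py1 = pxy[:, 1] - pwh[:, 1] * 0.5
    px2 = pxy[:, 0] + pwh[:, 0] * 0.5
    py2 = pxy[:, 1] + pwh[:, 1] * 0.5
    tx1, ty1 = tboxes[:, 0] - tboxes[:, 2] / 2, tboxes[:, 1] - tboxes[:, 3] / 2
    tx2, ty2 = tboxes[:, 0] + tboxes[:, 2] / 2, tboxes[:, 1] + tboxes[:, 3] / 2
    iw = (px2.minimum(Tensor(tx2)) - px1.maximum(Tensor(tx1))).clamp_min(0.0)
    ih = (py2.minimum(Tensor(ty2)) - py1.maximum(Tensor(ty1))).clamp_min(0.0)
    inter = iw * ih
    union = pwh[:, 0] * pwh[:, 1] + Tensor(tboxes[:, 2] * tboxes[:, 3]) - inter
    return inter / (union + 1e-9)


def total_loss(pred_maps: list[Tensor], targets: list[np.ndarray],
               anchors: np.ndarray, n_classes: int = 1,
               lambdas: tuple[float, float, float] = DEFAULT_LAMBDAS,
               strides: tuple[int, ...] = (8, 16, 32),
               soft_obj_targets: bool = False) -> tuple[Tensor, LossTerms]:
    """Compute the weighted detection loss over a batch.

    Returns the differentiable total plus a :class:`LossTerms` record of
    the unweighted component values.
    """
    grid_sizes = [(m.shape[2], m.shape[3]) for m in pred_maps]
    assigned = build_targets(targets, anchors, strides, grid_sizes)
    l_cls_terms, l_loc_terms, l_obj_terms = [], [], []
    for level, raw in enumerate(pred_maps):
        B, _, H, W = raw.shape
        stride = strides[level]
        p = raw.reshape(B, 3, 5 + n_classes, H, W).transpose(0, 1, 3, 4, 2)
        a = assigned[level]
        obj_target = np.zeros((B, 3, H, W))
        if len(a["img"]):
            pos = p[a["img"], a["anchor"], a["gy"], a["gx"]]  # (P, 5+nc)
            grid = np.stack([a["gx"], a["gy"]], axis=1).astype(float)
            pxy = (pos[:, 0:2].sigmoid() * 2.0 - 0.5 + Tensor(grid)) * stride
            pwh = (pos[:, 2:4].sigmoid() * 2.0) ** 2 * Tensor(a["anchor_wh"])
            iou = _pairwise_iou(pxy, pwh, a["boxes"])
            l_loc_terms.append((1.0 - iou).mean())
            iou_detached = (np.clip(iou.data, 0.0, 1.0) if soft_obj_targets
                            else np.ones(len(a["img"])))
            np.maximum.at(obj_target, (a["img"], a["anchor"], a["gy"], a["gx"]),
                          iou_detached)
            cls_target = np.zeros((len(a["cls"]), n_classes))
            cls_target[np.arange(len(a["cls"])), a["cls"]] = 1.0
            l_cls_terms.append(bce_with_logits(pos[:, 5:], cls_target).mean())
        obj_logits = p[:, :, :, :, 4]
        l_obj_terms.append(bce_with_logits(obj_logits, obj_target).mean())

    zero = Tensor(np.zeros(()))
    l_cls = sum(l_cls_terms, zero) * (1.0 / max(len(l_cls_terms), 1))
    l_loc = sum(l_loc_terms, zero) * (1.0 / max(len(l_loc_terms), 1))
    l_obj = sum(l_obj_terms, zero) * (1.0 / len(l_obj_terms))
    l1, l2, l3 = lambdas
    total = l_cls * l1 + l_loc * l2 + l_obj * l3
    terms = LossTerms(L_cls=l_cls.item(), L_loc=l_loc.item(),
                      L_obj=l_obj.item(), lambdas=tuple(lambdas))
    return total, terms
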