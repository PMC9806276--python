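"""Detection evaluation: precision, recall, F1 and average precision.

Single-class evaluation at a fixed IoU threshold (default 0.5).
Detections are matched to ground truths greedily in descending confidence
order (ties broken by input order); each ground truth can match at most
one detection.  Then::

    P  = TP / (TP + FP) * 100%
    R  = TP / (TP + FN) * 100%
    F1 = 2 P R / (P + R)
    AP = integral of P(R) dR over the full precision-recall curve

AP uses the exact all-points area under the precision envelope, not the
11-point approximation.  TN is carried in the counts for completeness but
enters no formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import WeedDetector, box_iou_matrix


@dataclass(frozen=True)
class MatchCounts:
    TP: int
    FP: int
    FN: int
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class EvalResult:
    P: float          # percent
    R: float          # percent
    F1: float         # 0..1
    AP: float         # 0..1
    counts: MatchCounts
    degenerate: bool = False  # some denominator was zero


def prf_from_counts(c: MatchCounts) -> tuple[float, float, float, bool]:
    """Precision/recall (percent) and F1 from match counts; zero-safe."""
    degenerate = False
    if c.TP + c.FP == 0:
        p, degenerate = 0.0, True
    else:
        p = 100.0 * c.TP / (c.TP + c.FP)
    if c.TP + c.FN == 0:
        r, degenerate = 0.0, True
    else:
        r = 100.0 * c.TP / (c.TP + c.FN)
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r) / 100.0
    return p, r, f1, degenerate


def match_detections(detections: list[np.ndarray], ground_truths: list[np.ndarray],
                     iou_threshold: float = 0.5) -> np.ndarray:
    """Greedy one-to-one matching across images.

    ``detections[i]`` is (Ni, 5+) ``x1 y1 x2 y2 conf`` for image i;
    ``ground_truths[i]`` is (Mi, 4).  Returns an (N, 2) array of
    ``(confidence, is_tp)`` rows pooled over images, sorted by descending
    confidence with input-order tie-breaks.
    """
    rows = []
    for img, (dets, gts) in enumerate(zip(detections, ground_truths)):
        dets = np.asarray(dets, dtype=float)
        dets = dets.reshape(-1, dets.shape[-1]) if dets.size else np.zeros((0, 5))
        gts = np.asarray(gts, dtype=float).reshape(-1, 4)
        order = np.argsort(-dets[:, 4], kind="stable")
        iou = box_iou_matrix(dets[:, :4], gts)
        taken = np.zeros(len(gts), dtype=bool)
        for d in order:
            best, best_iou = -1, iou_threshold
            for g in range(len(gts)):
                if not taken[g] and iou[d, g] >= best_iou:
                    best, best_iou = g, iou[d, g]
            is_tp = best >= 0
            if is_tp:
                taken[best] = True
            rows.append((dets[d, 4], float(is_tp)))
    if not rows:
        return np.zeros((0, 2))
    arr = np.array(rows)
    return arr[np.argsort(-arr[:, 0], kind="stable")]


def average_precision(conf_tp: np.ndarray, n_gt: int) -> float:
    """All-points AP from (confidence, is_tp) rows sorted by confidence.

    The precision-recall curve is swept over distinct confidence
    thresholds — detections with tied confidence enter together, which
    makes the area invariant to how ties are ordered.
    """
    if n_gt == 0 or len(conf_tp) == 0:
        return 0.0
    tp_cum = np.cumsum(conf_tp[:, 1])
    fp_cum = np.cumsum(1.0 - conf_tp[:, 1])
    # keep only the last row of each tied-confidence group
    last = np.r_[np.nonzero(np.diff(conf_tp[:, 0]) < 0)[0], len(conf_tp) - 1]
    tp_cum, fp_cum = tp_cum[last], fp_cum[last]
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope, then sum rectangle areas at recall steps
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    steps = np.nonzero(np.diff(r) > 0)[0]
    return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))


def evaluate(detections: list[np.ndarray], ground_truths: list[np.ndarray],
             iou_threshold: float = 0.5, conf_threshold: float = 0.5
             ) -> EvalResult:
    """Full evaluation of pooled detections against ground truths.

    P/R/F1 count only detections at or above ``conf_threshold``; AP sweeps
    the whole confidence range.
    """
    conf_tp = match_detections(detections, ground_truths, iou_threshold)
    n_gt = sum(len(np.asarray(g).reshape(-1, 4)) for g in ground_truths)
    ap = average_precision(conf_tp, n_gt)
    kept = conf_tp[conf_tp[:, 0] >= conf_threshold]
    tp = int(kept[:, 1].sum())
    fp = int(len(kept) - tp)
    counts = MatchCounts(TP=tp, FP=fp, FN=n_gt - tp)
    p, r, f1, degenerate = prf_from_counts(counts)
    return EvalResult(P=p, R=r, F1=f1, AP=ap, counts=counts, degenerate=degenerate)


def evaluate_dataset(model: WeedDetector, dataset: list[tuple[np.ndarray, np.ndarray]],
                     iou_threshold: float = 0.5, conf_threshold: float | None = None
                     ) -> EvalResult:
    """Run the detector over a dataset of (image_chw, targets) and evaluate."""
    detections, gts = [], []
    for image, targets in dataset:
        dets = model.predict(image, conf_threshold=0.001)
        detections.append(dets[:, :5] if len(dets) else np.zeros((0, 5)))
        t = np.asarray(targets, dtype=float).reshape(-1, 5)
        xyxy = np.stack([t[:, 1] - t[:, 3] / 2, t[:, 2] - t[:, 4] / 2,
                         t[:, 1] + t[:, 3] / 2, t[:, 2] + t[:, 4] / 2], axis=1) \
            if len(t) else np.zeros((0, 4))
        gts.append(xyxy)
    conf = model.config.conf_threshold if conf_threshold is None else conf_threshold
    return evaluate(detections, gts, iou_threshold, conf)
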