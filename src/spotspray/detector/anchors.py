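"""Anchor generation by K-means under the 1 - IoU box distance.

Boxes are compared co-located at the origin, so the distance between two
(w, h) pairs is ``1 - intersection/union`` of the axis-aligned rectangles.
Initialization is k-means++ (seeded); centroids update to the mean (w, h)
of their cluster; empty clusters are reseeded to the farthest box.
"""

from __future__ import annotations

import numpy as np


def iou_wh(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N, 2) and (K, 2) width/height pairs at the origin."""
    inter = (np.minimum(a[:, None, 0], b[None, :, 0])
             * np.minimum(a[:, None, 1], b[None, :, 1]))
    union = (a[:, 0] * a[:, 1])[:, None] + (b[:, 0] * b[:, 1])[None, :] - inter
    return inter / union


def kmeans_anchors(boxes: np.ndarray, k: int = 9, iterations: int = 100,
                   seed: int = 0) -> np.ndarray:
    """Cluster (w, h) boxes into k anchors, returned sorted by area.

    Raises ``ValueError`` with fewer boxes than clusters.  Deterministic
    given the seed.
    """
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 2)
    if len(boxes) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(boxes)}")
    if np.any(boxes <= 0):
        raise ValueError("box dimensions must be positive")
    rng = np.random.default_rng(seed)

    # k-means++ seeding under 1 - IoU
    centroids = [boxes[rng.integers(len(boxes))]]
    while len(centroids) < k:
        d = 1.0 - iou_wh(boxes, np.array(centroids)).max(axis=1)
        total = d.sum()
        if total <= 1e-12:  # all boxes already coincide with a centroid
            centroids.append(boxes[rng.integers(len(boxes))])
            continue
        centroids.append(boxes[rng.choice(len(boxes), p=d / total)])
    centroids = np.array(centroids)

    assign = np.full(len(boxes), -1)
    for _ in range(iterations):
        new_assign = iou_wh(boxes, centroids).argmax(axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = boxes[assign == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
            else:
                d = 1.0 - iou_wh(boxes, centroids).max(axis=1)
                centroids[j] = boxes[d.argmax()]
    order = np.argsort(centroids[:, 0] * centroids[:, 1], kind="stable")
    return centroids[order]
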