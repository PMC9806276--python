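"""The lightweight single-stage weed detector.

Architecture: a MobileNetv3-Small backbone truncated at its stride-8/16/32
stages, an extra SE attention block after each of the three backbone
outputs (sharpening small-target channels before fusion), an FPN top-down
plus PAN bottom-up neck fusing levels by channel concatenation, and three
anchor-based detection heads emitting ``3 * (5 + n_classes)`` channels at
strides 8, 16 and 32.

Raw head outputs are decoded YOLOv5-style::

    xy = (2 * sigmoid(t_xy) - 0.5 + grid) * stride
    wh = (2 * sigmoid(t_wh)) ** 2 * anchor
    conf = sigmoid(t_obj) * sigmoid(t_cls)

The MobileNetv3-Small layer table is used as published; which size variant
backs the detector is a swappable design choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, no_grad, upsample_nearest2x
from .blocks import ConfigurationError, DepthwiseSeparableConv, MNv3Bottleneck, SEBlock
from .nn import BatchNorm2d, Conv2d, HSwish, Module, ReLU, Sequential

# MobileNetv3-Small inverted-residual table truncated after the last
# stride-32 stage: (kernel, expand, out, SE, activation, stride)
_MNV3_SMALL = [
    (3, 16, 16, True, ReLU, 2),    # -> /4
    (3, 72, 24, False, ReLU, 2),   # -> /8
    (3, 88, 24, False, ReLU, 1),
    (5, 96, 40, True, HSwish, 2),  # -> /16
    (5, 240, 40, True, HSwish, 1),
    (5, 240, 40, True, HSwish, 1),
    (5, 120, 48, True, HSwish, 1),
    (5, 144, 48, True, HSwish, 1),
    (5, 288, 96, True, HSwish, 2),  # -> /32
    (5, 576, 96, True, HSwish, 1),
    (5, 576, 96, True, HSwish, 1),
]
_C3_IDX, _C4_IDX, _C5_IDX = 2, 7, 10  # last block of each stride stage

DEFAULT_ANCHORS = np.array([
    [10, 13], [16, 30], [33, 23],      # stride 8
    [30, 61], [62, 45], [59, 119],     # stride 16
    [116, 90], [156, 198], [373, 326], # stride 32
], dtype=float)


@dataclass
class DetectorConfig:
    input_size: int = 640
    n_classes: int = 1
    backbone: str = "mobilenetv3-small"
    se_reduction: int = 4
    neck_width: int = 48
    conf_threshold: float = 0.5
    nms_threshold: float = 0.5
    anchors: np.ndarray = field(default_factory=lambda: DEFAULT_ANCHORS.copy())

    def __post_init__(self) -> None:
        if self.input_size % 32 != 0:
            raise ConfigurationError(
                f"input_size must be divisible by 32, got {self.input_size}")
        self.anchors = np.asarray(self.anchors, dtype=float).reshape(9, 2)


class Backbone(Module):
    def __init__(self, rng: np.random.Generator):
        self.stem = Sequential(Conv2d(3, 16, k=3, stride=2, bias=False, rng=rng),
                               BatchNorm2d(16), HSwish())
        self.blocks = []
        c_in = 16
        for k, expand, c_out, use_se, act, stride in _MNV3_SMALL:
            self.blocks.append(MNv3Bottleneck(c_in, expand, c_out, k, stride,
                                              use_se, act, rng=rng))
            c_in = c_out
        self.out_channels = (24, 48, 96)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        h = self.stem(x)
        feats = {}
        for i, block in enumerate(self.blocks):
            h = block(h)
            if i in (_C3_IDX, _C4_IDX, _C5_IDX):
                feats[i] = h
        return feats[_C3_IDX], feats[_C4_IDX], feats[_C5_IDX]


class WeedDetector(Module):
    """Backbone + per-output SE + FPN/PAN neck + three detection heads."""

    def __init__(self, config: DetectorConfig | None = None, seed: int = 0):
        self.config = config or DetectorConfig()
        rng = np.random.default_rng(seed)
        w = self.config.neck_width
        nc = self.config.n_classes
        self.backbone = Backbone(rng)
        c3, c4, c5 = self.backbone.out_channels
        red = self.config.se_reduction
        self.se3 = SEBlock(c3, reduction=red, rng=rng)
        self.se4 = SEBlock(c4, reduction=red, rng=rng)
        self.se5 = SEBlock(c5, reduction=red, rng=rng)
        # FPN top-down: lateral 1x1 projections, upsample + concat + fuse
        self.lat3 = Sequential(Conv2d(c3, w, k=1, bias=False, rng=rng),
                               BatchNorm2d(w), HSwish())
        self.lat4 = Sequential(Conv2d(c4, w, k=1, bias=False, rng=rng),
                               BatchNorm2d(w), HSwish())
        self.lat5 = Sequential(Conv2d(c5, w, k=1, bias=False, rng=rng),
                               BatchNorm2d(w), HSwish())
        self.fuse4 = DepthwiseSeparableConv(2 * w, w, k=3, act=HSwish, rng=rng)
        self.fuse3 = DepthwiseSeparableConv(2 * w, w, k=3, act=HSwish, rng=rng)
        # PAN bottom-up: stride-2 downsample + concat + fuse
        self.down3 = DepthwiseSeparableConv(w, w, k=3, stride=2, act=HSwish, rng=rng)
        self.pan4 = DepthwiseSeparableConv(2 * w, w, k=3, act=HSwish, rng=rng)
        self.down4 = DepthwiseSeparableConv(w, w, k=3, stride=2, act=HSwish, rng=rng)
        self.pan5 = DepthwiseSeparableConv(2 * w, w, k=3, act=HSwish, rng=rng)
        self.heads = [Conv2d(w, 3 * (5 + nc), k=1, rng=rng) for _ in range(3)]

    @property
    def strides(self) -> tuple[int, int, int]:
        return (8, 16, 32)

    def forward(self, x: Tensor) -> list[Tensor]:
        """Raw head maps [(B, 3*(5+nc), H/8, W/8), ..., (B, ..., W/32)]."""
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ConfigurationError(
                f"input spatial dims must be divisible by 32, got {x.shape[2:]}")
        c3, c4, c5 = self.backbone(x)
        p3 = self.lat3(self.se3(c3))
        p4 = self.lat4(self.se4(c4))
        p5 = self.lat5(self.se5(c5))
        t4 = self.fuse4(concat([p4, upsample_nearest2x(p5)], axis=1))
        t3 = self.fuse3(concat([p3, upsample_nearest2x(t4)], axis=1))
        n4 = self.pan4(concat([t4, self.down3(t3)], axis=1))
        n5 = self.pan5(concat([p5, self.down4(n4)], axis=1))
        return [self.heads[0](t3), self.heads[1](n4), self.heads[2](n5)]

    # -- inference ------------------------------------------------------------
    def predict(self, image_chw: np.ndarray,
                conf_threshold: float | None = None,
                nms_threshold: float | None = None) -> np.ndarray:
        """Detect on one preprocessed CHW image in [0, 1].

        Returns an (N, 6) array of ``x1, y1, x2, y2, confidence, class`` in
        the network input's pixel coordinates, confidence-sorted descending.
        """
        conf_thr = self.config.conf_threshold if conf_threshold is None else conf_threshold
        nms_thr = self.config.nms_threshold if nms_threshold is None else nms_threshold
        self.eval()
        with no_grad():
            maps = self.forward(Tensor(image_chw[None]))
        rows = []
        nc = self.config.n_classes
        for level, raw in enumerate(maps):
            stride = self.strides[level]
            anchors = self.config.anchors[3 * level:3 * level + 3]
            _, _, H, W = raw.shape
            p = raw.data.reshape(3, 5 + nc, H, W)
            s = 1.0 / (1.0 + np.exp(-p))
            gy, gx = np.mgrid[0:H, 0:W]
            for a in range(3):
                cx = (2 * s[a, 0] - 0.5 + gx) * stride
                cy = (2 * s[a, 1] - 0.5 + gy) * stride
                bw = (2 * s[a, 2]) ** 2 * anchors[a, 0]
                bh = (2 * s[a, 3]) ** 2 * anchors[a, 1]
                cls_conf = s[a, 5:]
                best_cls = cls_conf.argmax(axis=0)
                conf = s[a, 4] * np.take_along_axis(cls_conf, best_cls[None], 0)[0]
                keep = conf >= conf_thr
                if keep.any():
                    rows.append(np.stack([
                        (cx - bw / 2)[keep], (cy - bh / 2)[keep],
                        (cx + bw / 2)[keep], (cy + bh / 2)[keep],
                        conf[keep], best_cls[keep].astype(float)], axis=1))
        if not rows:
            return np.zeros((0, 6))
        dets = np.concatenate(rows, axis=0)
        return nms(dets, nms_thr)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N, 4) and (M, 4) xyxy boxes."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:4], b[None, :, 2:4])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)


def nms(dets: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression; dets are (N, 6) xyxy+conf+class."""
    order = np.argsort(-dets[:, 4], kind="stable")
    dets = dets[order]
    keep: list[int] = []
    for i in range(len(dets)):
        ok = True
        for j in keep:
            if dets[i, 5] == dets[j, 5] and \
                    box_iou_matrix(dets[i:i + 1, :4], dets[j:j + 1, :4])[0, 0] > iou_threshold:
                ok = False
                break
        if ok:
            keep.append(i)
    return dets[keep]


def build_model(config: DetectorConfig | None = None, seed: int = 0) -> WeedDetector:
    """Construct the detector with seeded initialization."""
    return WeedDetector(config, seed=seed)
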