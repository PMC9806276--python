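"""MobileNetv3 building blocks: SE attention, depthwise-separable
convolution, and the inverted-residual bottleneck.

The squeeze-and-excitation (SE) block compresses each channel's spatial
map to one number by global average pooling, passes the channel vector
through a two-layer bottleneck MLP (reduction ratio r), and multiplies the
sigmoid weights back onto the channels — channel attention at negligible
cost.  The depthwise-separable convolution replaces a dense k x k
convolution with a per-channel k x k convolution followed by a 1 x 1
cross-channel mix, cutting the multiply-accumulate count by a factor of
``1/c_out + 1/k**2``.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .nn import (BatchNorm2d, Conv2d, DepthwiseConv2d, HSwish, Module, ReLU,
                 Sequential)


class ConfigurationError(ValueError):
    pass


class SEBlock(Module):
    """Squeeze-and-excitation channel attention.

    Uses the MobileNetv3 hard-sigmoid gate by default; ``gate="sigmoid"``
    gives the original smooth gate whose weights are strictly inside (0, 1).
    """

    def __init__(self, channels: int, reduction: int = 4, gate: str = "sigmoid",
                 rng: np.random.Generator | None = None):
        if channels % reduction != 0:
            raise ConfigurationError(
                f"channels={channels} not divisible by reduction={reduction}")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.gate = gate
        self.fc1 = Conv2d(channels, channels // reduction, k=1, rng=rng)
        self.fc2 = Conv2d(channels // reduction, channels, k=1, rng=rng)

    def channel_weights(self, x: Tensor) -> Tensor:
        squeezed = x.mean(axis=(2, 3), keepdims=True)  # (B, C, 1, 1)
        h = self.fc1(squeezed).relu()
        h = self.fc2(h)
        return h.sigmoid() if self.gate == "sigmoid" else h.hard_sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"SE block built for {self.channels} channels, got {x.shape[1]}")
        return x * self.channel_weights(x)


class DepthwiseSeparableConv(Module):
    """Depthwise k x k + pointwise 1 x 1 convolution, each with BN + activation."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 act: type[Module] = ReLU, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.depthwise = Sequential(
            DepthwiseConv2d(c_in, k=k, stride=stride, bias=False, rng=rng),
            BatchNorm2d(c_in), act())
        self.pointwise = Sequential(
            Conv2d(c_in, c_out, k=1, bias=False, rng=rng),
            BatchNorm2d(c_out), act())

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


def separable_macs(c_in: int, c_out: int, k: int, h_out: int, w_out: int) -> int:
    """Multiply-accumulates of a depthwise-separable conv on an h x w output."""
    return c_in * k * k * h_out * w_out + c_in * c_out * h_out * w_out


def standard_macs(c_in: int, c_out: int, k: int, h_out: int, w_out: int) -> int:
    """Multiply-accumulates of a dense conv on the same output."""
    return c_in * c_out * k * k * h_out * w_out


def mac_ratio(c_out: int, k: int) -> float:
    """Closed-form separable/standard MAC ratio: 1/c_out + 1/k^2."""
    return 1.0 / c_out + 1.0 / (k * k)


class MNv3Bottleneck(Module):
    """MobileNetv3 inverted residual: expand 1x1 -> depthwise kxk -> [SE] ->
    project 1x1, with a shortcut when stride is 1 and channels match."""

    def __init__(self, c_in: int, expand: int, c_out: int, k: int, stride: int,
                 use_se: bool, act: type[Module],
                 rng: np.random.Generator | None = None,
                 se_reduction: int = 4):
        rng = rng or np.random.default_rng(0)
        self.use_shortcut = stride == 1 and c_in == c_out
        self.expand_conv = None
        if expand != c_in:
            self.expand_conv = Sequential(
                Conv2d(c_in, expand, k=1, bias=False, rng=rng),
                BatchNorm2d(expand), act())
        self.depthwise = Sequential(
            DepthwiseConv2d(expand, k=k, stride=stride, bias=False, rng=rng),
            BatchNorm2d(expand), act())
        # in-bottleneck SE channels are not generally divisible by 4; pad the
        # reduction down to a divisor
        self.se = None
        if use_se:
            red = se_reduction
            while expand % red != 0:
                red -= 1
            self.se = SEBlock(expand, reduction=red, gate="hard", rng=rng)
        self.project = Sequential(
            Conv2d(expand, c_out, k=1, bias=False, rng=rng),
            BatchNorm2d(c_out))

    def forward(self, x: Tensor) -> Tensor:
        h = x if self.expand_conv is None else self.expand_conv(x)
        h = self.depthwise(h)
        if self.se is not None:
            h = self.se(h)
        h = self.project(h)
        if self.use_shortcut:
            h = h + x
        return h
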