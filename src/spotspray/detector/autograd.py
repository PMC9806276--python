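"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the detector needs: broadcasting
arithmetic, matmul, 2-D convolution (dense and depthwise) via im2col,
nearest-neighbour upsampling, batch normalization, the MobileNet
activations, advanced indexing, concatenation and stable binary
cross-entropy with logits.  Gradients are accumulated on a topologically
sorted tape; all tensors are float64 unless constructed otherwise.

The engine is deliberately small: no graphs across devices, no in-place
ops, no higher-order gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "bce_with_logits", "conv2d", "depthwise_conv2d",
           "batch_norm2d", "upsample_nearest2x", "no_grad"]


class _NoGrad:
    _active = False

    def __enter__(self):
        self.prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self.prev
        return False


def no_grad() -> _NoGrad:
    """Context manager disabling tape construction (inference)."""
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and not _NoGrad._active
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents) and not _NoGrad._active
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)

        def backward(g):
            return (g @ other.data.swapaxes(-1, -2), self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    def __getitem__(self, idx):
        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            return (g.reshape(orig),)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def relu6(self):
        mask = (self.data > 0) & (self.data < 6)
        return Tensor._make(np.clip(self.data, 0, 6), (self,), lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor._make(s, (self,), lambda g: (g * s * (1 - s),))

    def hard_sigmoid(self):
        """relu6(x + 3) / 6 — the MobileNetv3 sigmoid approximation."""
        y = np.clip(self.data + 3.0, 0, 6) / 6.0
        mask = (self.data > -3) & (self.data < 3)
        return Tensor._make(y, (self,), lambda g: (g * mask / 6.0,))

    def hard_swish(self):
        """x * relu6(x + 3) / 6 (H-Swish)."""
        inner = np.clip(self.data + 3.0, 0, 6) / 6.0
        mask = (self.data > -3) & (self.data < 3)

        def backward(g):
            return (g * (inner + self.data * mask / 6.0),)

        return Tensor._make(self.data * inner, (self,), backward)

    def minimum(self, other):
        other = self._coerce(other)
        take_self = self.data <= other.data

        def backward(g):
            return (_unbroadcast(g * take_self, self.shape),
                    _unbroadcast(g * ~take_self, other.shape))

        return Tensor._make(np.minimum(self.data, other.data), (self, other), backward)

    def maximum(self, other):
        other = self._coerce(other)
        take_self = self.data >= other.data

        def backward(g):
            return (_unbroadcast(g * take_self, self.shape),
                    _unbroadcast(g * ~take_self, other.shape))

        return Tensor._make(np.maximum(self.data, other.data), (self, other), backward)

    def clamp_min(self, lo: float):
        return self.maximum(Tensor(np.array(lo)))

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)


# -- free functions -----------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def bce_with_logits(logits: Tensor, target: np.ndarray | Tensor) -> Tensor:
    """Elementwise stable binary cross-entropy with logits (no reduction)."""
    t = target.data if isinstance(target, Tensor) else np.asarray(target, dtype=np.float64)
    x = logits.data
    loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

    def backward(g):
        return (g * (sig - t),)

    return Tensor._make(loss, (logits,), backward)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(B, C, H, W) -> patches (B, C, Ho, Wo, k, k) plus padded input shape."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride], x.shape


def _col2im(dpatches: np.ndarray, padded_shape, k: int, stride: int,
            pad: int) -> np.ndarray:
    """Scatter-add patch gradients back to the (unpadded) input."""
    B, C, Ho, Wo = dpatches.shape[:4]
    dx = np.zeros(padded_shape, dtype=np.float64)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                dpatches[:, :, :, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad or None, pad:-pad or None]
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int | None = None) -> Tensor:
    """Dense 2-D convolution; weight is (C_out, C_in, k, k); default same-pad."""
    C_out, C_in, k, _ = weight.shape
    if pad is None:
        pad = k // 2
    patches, padded_shape = _im2col(x.data, k, stride, pad)
    B, _, Ho, Wo = patches.shape[:4]
    cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C_in * k * k)
    w_flat = weight.data.reshape(C_out, C_in * k * k)
    out = cols @ w_flat.T  # (B, Ho*Wo, C_out)
    out = out.transpose(0, 2, 1).reshape(B, C_out, Ho, Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, C_out, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g_flat = g.reshape(B, C_out, Ho * Wo).transpose(0, 2, 1)  # (B, L, C_out)
        dw = np.einsum("blo,blk->ok", g_flat, cols)
        dcols = g_flat @ w_flat  # (B, L, C_in*k*k)
        dpatches = dcols.reshape(B, Ho, Wo, C_in, k, k).transpose(0, 3, 1, 2, 4, 5)
        dx = _col2im(dpatches, padded_shape, k, stride, pad)
        grads = [dx, dw.reshape(weight.shape)]
        if bias is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return Tensor._make(out, parents, backward)


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 1, pad: int | None = None) -> Tensor:
    """Per-channel (depthwise) convolution; weight is (C, k, k)."""
    C, k, _ = weight.shape
    if pad is None:
        pad = k // 2
    patches, padded_shape = _im2col(x.data, k, stride, pad)  # (B, C, Ho, Wo, k, k)
    out = np.einsum("bchwij,cij->bchw", patches, weight.data)
    if bias is not None:
        out = out + bias.data.reshape(1, C, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        dw = np.einsum("bchwij,bchw->cij", patches, g)
        dpatches = g[..., None, None] * weight.data[None, :, None, None, :, :]
        dx = _col2im(dpatches, padded_shape, k, stride, pad)
        grads = [dx, dw]
        if bias is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return Tensor._make(out, parents, backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
                 var: np.ndarray, eps: float = 1e-5,
                 training: bool = False) -> Tensor:
    """Channelwise batch normalization.

    In training mode `mean`/`var` must be the batch statistics (the layer
    computes and passes them in, and maintains running averages itself);
    their dependence on x is included in the gradient.  In eval mode they
    are constants.
    """
    m = mean.reshape(1, -1, 1, 1)
    v = var.reshape(1, -1, 1, 1)
    invstd = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m) * invstd
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
    B, C, H, W = x.shape
    n = B * H * W

    def backward(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        gg = g * gamma.data.reshape(1, -1, 1, 1)
        if training:
            # full batch-norm backward (mean/var are functions of x)
            dx = (invstd / n) * (n * gg
                                 - gg.sum(axis=(0, 2, 3), keepdims=True)
                                 - xhat * (gg * xhat).sum(axis=(0, 2, 3), keepdims=True))
        else:
            dx = gg * invstd
        return (dx, dgamma, dbeta)

    return Tensor._make(out, (x, gamma, beta), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    B, C, H, W = x.shape

    def backward(g):
        return (g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)),)

    return Tensor._make(out, (x,), backward)
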