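"""A compact reverse-mode automatic differentiation engine on numpy arrays.

Implements exactly the operations the gated U-Net needs: stride-1 2-D
convolution (im2col), 2 x 2 average pooling, 2 x 2 nearest-neighbour
upsampling, channel concatenation, dense layers, batch normalisation,
dropout, ReLU/sigmoid and a numerically clipped binary cross-entropy.
Tensors are float32 and laid out NHWC.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "conv2d",
    "avg_pool2",
    "upsample_nearest2",
    "concat",
    "reshape",
    "dropout",
    "batch_norm",
    "bce_loss",
    "same_padding",
]


class Tensor:
    """A numpy array plus the closure that propagates its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _result(data: np.ndarray, parents: Sequence[Tensor],
            backward: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast up from ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(grad):
        if a.requires_grad:
            a.accumulate(_unbroadcast(grad, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(grad, b.shape))

    return _result(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(grad):
        if a.requires_grad:
            a.accumulate(_unbroadcast(grad * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(grad * a.data, b.shape))

    return _result(data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(grad):
        if a.requires_grad:
            a.accumulate(grad @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ grad)

    return _result(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    data = np.maximum(x.data, 0.0)

    def backward(grad):
        if x.requires_grad:
            x.accumulate(grad * (x.data > 0.0))

    return _result(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(grad):
        if x.requires_grad:
            x.accumulate(grad * data * (1.0 - data))

    return _result(data, (x,), backward)


def same_padding(k: int) -> tuple[int, int]:
    """(before, after) zero padding giving output size == input size, stride 1.

    Even kernels pad asymmetrically (0 before, 1 after for k=2).
    """
    total = k - 1
    return total // 2, total - total // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: tuple[tuple[int, int], tuple[int, int]] | None = None) -> Tensor:
    """Stride-1 correlation of NHWC input with (kh, kw, Cin, Cout) weights."""
    kh, kw, cin, cout = w.shape
    if padding is None:
        padding = (same_padding(kh), same_padding(kw))
    (pt, pb), (pl, pr) = padding
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # N,Ho,Wo,Ci,kh,kw
    n, ho, wo = win.shape[:3]
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * ho * wo, kh * kw * cin
    )
    wmat = w.data.transpose(0, 1, 2, 3).reshape(kh * kw * cin, cout)
    out = cols @ wmat
    if b is not None:
        out = out + b.data
    data = out.reshape(n, ho, wo, cout)

    def backward(grad):
        g2 = grad.reshape(n * ho * wo, cout)
        if w.requires_grad:
            w.accumulate((cols.T @ g2).reshape(kh, kw, cin, cout))
        if b is not None and b.requires_grad:
            b.accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcols = (g2 @ wmat.T).reshape(n, ho, wo, kh, kw, cin)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + ho, j : j + wo, :] += dcols[:, :, :, i, j, :]
            h, wdt = x.shape[1], x.shape[2]
            x.accumulate(dxp[:, pt : pt + h, pl : pl + wdt, :])

    parents = (x, w) if b is None else (x, w, b)
    return _result(data, parents, backward)


def avg_pool2(x: Tensor) -> Tensor:
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    data = x.data.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(grad):
        if x.requires_grad:
            g = np.repeat(np.repeat(grad, 2, axis=1), 2, axis=2) / 4.0
            x.accumulate(g)

    return _result(data, (x,), backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(grad):
        if x.requires_grad:
            n, h2, w2, c = grad.shape
            g = grad.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))
            x.accumulate(g)

    return _result(data, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(a, b)
                t.accumulate(grad[tuple(sl)])

    return _result(data, tuple(tensors), backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    data = x.data.reshape(shape)

    def backward(grad):
        if x.requires_grad:
            x.accumulate(grad.reshape(x.shape))

    return _result(data, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float32) / (1.0 - rate)

    def backward(grad):
        if x.requires_grad:
            x.accumulate(grad * keep)

    return _result(x.data * keep, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.9,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation (channels on the last axis).

    In training mode uses batch statistics and updates the running buffers in
    place; in inference mode uses the running statistics, so inference is
    deterministic.
    """
    axes = tuple(range(x.data.ndim - 1))
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mean
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    data = gamma.data * xhat + beta.data

    def backward(grad):
        if gamma.requires_grad:
            gamma.accumulate((grad * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta.accumulate(grad.sum(axis=axes))
        if x.requires_grad:
            if training:
                m = float(np.prod([x.data.shape[a] for a in axes]))
                dxhat = grad * gamma.data
                dx = (inv_std / m) * (
                    m * dxhat
                    - dxhat.sum(axis=axes)
                    - xhat * (dxhat * xhat).sum(axis=axes)
                )
            else:
                dx = grad * gamma.data * inv_std
            x.accumulate(dx.astype(np.float32))

    return _result(data, (x, gamma, beta), backward)


def bce_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy with clipped probabilities."""
    y = np.asarray(target, dtype=np.float32)
    p = np.clip(pred.data, eps, 1.0 - eps)
    data = np.float32(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())

    def backward(grad):
        if pred.requires_grad:
            g = grad * (p - y) / (p * (1.0 - p)) / p.size
            pred.accumulate(g.astype(np.float32))

    return _result(data, (pred,), backward)
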