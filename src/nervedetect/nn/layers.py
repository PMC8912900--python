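"""Parameterised layers and the Adam optimiser for the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Layer", "Conv2D", "BatchNorm", "Dense", "Adam"]


class Layer:
    """Base class: anything with parameters and named state buffers."""

    def parameters(self) -> list[Tensor]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        return {}


class Conv2D(Layer):
    """Stride-1 'same' convolution with He-initialised weights."""

    def __init__(self, kh: int, kw: int, cin: int, cout: int,
                 rng: np.random.Generator, bias: bool = True):
        fan_in = kh * kw * cin
        self.w = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (kh, kw, cin, cout)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b)

    def parameters(self) -> list[Tensor]:
        return [self.w] + ([self.b] if self.b is not None else [])


class BatchNorm(Layer):
    def __init__(self, channels: int, momentum: float = 0.9):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ad.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training, self.momentum,
        )

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def buffers(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.w = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / nin), (nin, nout)), requires_grad=True
        )
        self.b = Tensor(np.zeros(nout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.w), self.b)

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            mhat = m / (1.0 - self.beta1**self.t)
            vhat = v / (1.0 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
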