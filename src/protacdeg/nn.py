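"""Small neural-network building blocks over the autodiff core.

Initialization is uniform fan-in (U(-1/sqrt(fan_in), 1/sqrt(fan_in)))
from a caller-supplied ``numpy.random.Generator``, so model construction
is fully reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, silu

__all__ = ["Linear", "MLP", "Adam", "Parameter"]


def Parameter(value: np.ndarray) -> Tensor:
    return Tensor(value, requires_grad=True)


def _fan_in_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear:
    """Affine map ``x @ W + b`` with fan-in uniform init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            self.W = Parameter(np.zeros((d_in, d_out)))
        else:
            self.W = Parameter(_fan_in_uniform(rng, d_in, (d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class MLP:
    """Multilayer perceptron with SiLU activations between layers.

    ``zero_init_last`` zeroes the final layer's weights so the network's
    initial output is its (zero) bias — used for the coordinate gate so
    early coordinate updates are small.
    """

    def __init__(self, dims, rng: np.random.Generator, zero_init_last: bool = False):
        self.layers = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            last = i == len(dims) - 2
            self.layers.append(Linear(a, b, rng, zero_init=zero_init_last and last))

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = silu(x)
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adaptive-moment optimizer over a flat parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
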