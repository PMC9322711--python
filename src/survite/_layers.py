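"""Network building blocks: linear layers, batch norm, dropout, MLPs, Adam.

State is held as plain :class:`~survite._autodiff.Tensor` parameters so the
whole model can be copied, serialized and stepped by the optimizer without a
framework dependency.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["Linear", "BatchNorm", "MLP", "Adam"]


class Linear:
    """Affine layer ``x @ W + b`` with seeded Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class BatchNorm:
    """Batch normalization over axis 0 with running statistics.

    During training the batch mean/variance enter the graph (gradients flow
    through them); at evaluation the frozen running statistics are used, so
    inference is deterministic.
    """

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n), requires_grad=True)
        self.beta = Tensor(np.zeros(n), requires_grad=True)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
        xhat = (x - mu) / (var + self.eps).sqrt()
        return self.gamma * xhat + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class MLP:
    """Fully connected stack with a choice of activation on every layer.

    ``batch_norm``/``dropout`` apply to hidden activations only, matching the
    usual placement (affine -> BN -> activation -> dropout).
    """

    def __init__(self, widths: list[int], activation: str,
                 rng: np.random.Generator, *, batch_norm: bool = False,
                 dropout: float = 0.0, activate_last: bool = True):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.bns = ([BatchNorm(w) for w in widths[1:]] if batch_norm else None)
        self.activation = activation
        self.dropout = dropout
        self.activate_last = activate_last

    def _act(self, x: Tensor) -> Tensor:
        if self.activation == "leaky_relu":
            return x.leaky_relu()
        if self.activation == "tanh":
            return x.tanh()
        if self.activation == "linear":
            return x
        raise ValueError(f"unknown activation {self.activation!r}")

    def __call__(self, x: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        n_last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if self.bns is not None:
                x = self.bns[i](x, training)
            if i < n_last or self.activate_last:
                x = self._act(x)
            if self.dropout > 0 and training:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng for dropout")
                keep = (rng.random(x.shape) >= self.dropout) / (1.0 - self.dropout)
                x = x * Tensor(keep)
        return x

    def parameters(self) -> list[Tensor]:
        params = [p for layer in self.layers for p in layer.parameters()]
        if self.bns is not None:
            params += [p for bn in self.bns for p in bn.parameters()]
        return params


class Adam:
    """Adaptive-moment gradient descent (Kingma & Ba defaults for betas)."""

    def __init__(self, params: list[Tensor], lr: float = 3e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
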