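"""Parameterized layers and the SGD-with-momentum optimizer.

Layers register their parameters with a shared dict keyed by layer-local
names so checkpoints and the optimizer see one flat namespace.
"""

from __future__ import annotations

import numpy as np

from .core import Tensor, batch_norm, conv2d, dense

__all__ = ["Conv2d", "BatchNorm2d", "Dense", "SGD"]


class Conv2d:
    """Convolution without bias (batch norm follows in every use here).

    Weights use He-normal initialization, std = sqrt(2 / fan_in), the
    standard choice for ReLU residual networks.
    """

    def __init__(self, cin, cout, kernel, stride=1, pad=0, *, rng, params, name):
        fan_in = cin * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.stride = stride
        self.pad = pad
        params[f"{name}.weight"] = self.weight

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, stride=self.stride, pad=self.pad)


class BatchNorm2d:
    """Batch normalization with running statistics for inference.

    ``momentum`` is the fraction of the batch statistic blended into the
    running average per step (0.1, the common convention). ``gamma_init=0``
    implements zero-initialized residual scaling: the last normalization of
    each residual block starts at zero so every block begins as an identity
    map, which stabilizes early training of deep stacks.
    """

    def __init__(self, c, *, params, name, gamma_init=1.0, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.full(c, gamma_init, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        params[f"{name}.gamma"] = self.gamma
        params[f"{name}.beta"] = self.beta
        self._buffers = {f"{name}.running_mean": self, f"{name}.running_var": self}
        self.name = name

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            out, mean, var = batch_norm(x, self.gamma, self.beta, eps=self.eps)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return out
        out, _, _ = batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var, eps=self.eps
        )
        return out


class Dense:
    def __init__(self, din, dout, *, rng, params, name):
        w = rng.normal(0.0, np.sqrt(1.0 / din), size=(din, dout))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(dout, dtype=np.float32), requires_grad=True)
        params[f"{name}.weight"] = self.weight
        params[f"{name}.bias"] = self.bias

    def __call__(self, x: Tensor) -> Tensor:
        return dense(x, self.weight, self.bias)


class SGD:
    """Stochastic gradient descent with classical momentum (default 0.9)."""

    def __init__(self, params: dict[str, Tensor], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        for k, p in self.params.items():
            if p.grad is None:
                continue
            v = self._velocity[k]
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()
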