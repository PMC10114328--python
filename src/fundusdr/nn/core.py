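"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical engine behind the residual network: a ``Tensor`` wraps a
float32 ndarray, records the operation that produced it, and ``backward()``
accumulates gradients through the recorded graph in reverse topological order.
Only the operations the network needs are implemented (elementwise arithmetic,
2-D convolution, batch normalization, max/average pooling, dense layers, the
sigmoid head and its binary cross-entropy), each with a hand-written backward
pass verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "maximum",
    "sigmoid",
    "conv2d",
    "batch_norm",
    "max_pool2d",
    "global_avg_pool",
    "dense",
    "sum_squares",
    "sum_abs",
    "bce_with_logits",
]


class Tensor:
    """A node in the computation graph.

    Parameters hold ``requires_grad=True``; intermediate results inherit the
    flag from their parents so inference-only subgraphs stay cheap.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph traversal ---------------------------------------------------

    def backward(self):
        """Backpropagate d(self)/d(node) into every reachable parameter."""
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __sub__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data - other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(-g, other.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, other):
        if np.isscalar(other):
            out = Tensor(self.data * other, parents=(self,))

            def bwd_s(g):
                if self.requires_grad:
                    self.accumulate(g * other)

            out._backward = bwd_s
            return out
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.accumulate(np.full_like(self.data, float(g)))

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- nonlinearities --------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * (x.data > 0))

    out._backward = bwd
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; on ties the gradient goes to the first argument."""
    out = Tensor(np.maximum(a.data, b.data), parents=(a, b))
    take_a = a.data >= b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g * take_a)
        if b.requires_grad:
            b.accumulate(g * ~take_a)

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * s * (1.0 - s))

    out._backward = bwd
    return out


# -- spatial operations (NCHW layout) --------------------------------------


def conv2d(x: Tensor, w: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation of ``x`` (N,C,H,W) with kernels ``w`` (F,C,KH,KW).

    Implemented as a sum over kernel offsets of strided-slice contractions,
    which keeps 1x1 convolutions (most of a bottleneck network) a single
    einsum and avoids materializing im2col buffers.
    """
    N, C, H, W = x.data.shape
    F, Cw, KH, KW = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    OH = (H + 2 * pad - KH) // stride + 1
    OW = (W + 2 * pad - KW) // stride + 1
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        if pad
        else x.data
    )
    out_data = np.zeros((N, F, OH, OW), dtype=np.float32)
    for i in range(KH):
        for j in range(KW):
            xs = xp[:, :, i : i + OH * stride : stride, j : j + OW * stride : stride]
            out_data += np.einsum("ncij,fc->nfij", xs, w.data[:, :, i, j], optimize=True)
    out = Tensor(out_data, parents=(x, w))

    def bwd(g):
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(KH):
                for j in range(KW):
                    xs = xp[
                        :, :, i : i + OH * stride : stride, j : j + OW * stride : stride
                    ]
                    dw[:, :, i, j] = np.einsum("nfij,ncij->fc", g, xs, optimize=True)
            w.accumulate(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(KH):
                for j in range(KW):
                    dxp[
                        :, :, i : i + OH * stride : stride, j : j + OW * stride : stride
                    ] += np.einsum("nfij,fc->ncij", g, w.data[:, :, i, j], optimize=True)
            x.accumulate(dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp)

    out._backward = bwd
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    mean: np.ndarray | None = None,
    var: np.ndarray | None = None,
    eps: float = 1e-5,
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Channelwise batch normalization of (N,C,H,W).

    With ``mean``/``var`` omitted the batch statistics are used (training
    mode) and returned so the caller can update running averages; passing
    stored statistics gives deterministic inference.
    """
    axes = (0, 2, 3)
    training = mean is None
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(out_data, parents=(x, gamma, beta))
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bwd(g):
        dbeta = g.sum(axis=axes)
        dgamma = (g * xhat).sum(axis=axes)
        if gamma.requires_grad:
            gamma.accumulate(dgamma)
        if beta.requires_grad:
            beta.accumulate(dbeta)
        if x.requires_grad:
            gi = gamma.data * inv_std
            if training:
                dx = (gi[None, :, None, None] / m) * (
                    m * g
                    - dbeta[None, :, None, None]
                    - xhat * dgamma[None, :, None, None]
                )
            else:
                dx = gi[None, :, None, None] * g
            x.accumulate(dx)

    out._backward = bwd
    return out, mean, var


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    N, C, H, W = x.data.shape
    OH = (H + 2 * pad - kernel) // stride + 1
    OW = (W + 2 * pad - kernel) // stride + 1
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (pad, pad), (pad, pad)),
        constant_values=-np.inf,
    )
    windows = np.stack(
        [
            xp[:, :, i : i + OH * stride : stride, j : j + OW * stride : stride]
            for i in range(kernel)
            for j in range(kernel)
        ]
    )  # (k*k, N, C, OH, OW)
    arg = windows.argmax(axis=0)
    out = Tensor(windows.max(axis=0), parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        for idx in range(kernel * kernel):
            i, j = divmod(idx, kernel)
            sel = arg == idx
            dxp[:, :, i : i + OH * stride : stride, j : j + OW * stride : stride] += (
                g * sel
            )
        x.accumulate(dxp[:, :, pad : pad + H, pad : pad + W])

    out._backward = bwd
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    N, C, H, W = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3)), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(
                np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape).astype(
                    np.float32
                )
            )

    out._backward = bwd
    return out


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """(N,D) @ (D,K) + (K,)."""
    out = Tensor(x.data @ w.data + b.data, parents=(x, w, b))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g @ w.data.T)
        if w.requires_grad:
            w.accumulate(x.data.T @ g)
        if b.requires_grad:
            b.accumulate(g.sum(axis=0))

    out._backward = bwd
    return out


# -- reductions used by the regularizers and the loss ----------------------


def sum_squares(x: Tensor) -> Tensor:
    out = Tensor(np.sum(x.data.astype(np.float64) ** 2), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(2.0 * float(g) * x.data)

    out._backward = bwd
    return out


def sum_abs(x: Tensor) -> Tensor:
    out = Tensor(np.sum(np.abs(x.data, dtype=np.float64)), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(float(g) * np.sign(x.data))

    out._backward = bwd
    return out


def bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(z) against labels y, numerically
    stable form ``softplus(z) - y*z`` averaged over the batch."""
    y = np.asarray(y, dtype=np.float32).reshape(z.data.shape)
    zd = z.data
    loss = np.maximum(zd, 0.0) - y * zd + np.log1p(np.exp(-np.abs(zd)))
    out = Tensor(loss.mean(), parents=(z,))
    n = zd.size

    def bwd(g):
        if z.requires_grad:
            s = 1.0 / (1.0 + np.exp(-zd))
            z.accumulate(float(g) * (s - y) / n)

    out._backward = bwd
    return out
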