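"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operations the sequence networks need: broadcasting
arithmetic, matrix products, sigmoid/tanh/ReLU, time-axis slicing and
stacking, same-padding 1-D convolution, max pooling, batch normalization
and a fused weighted softmax cross-entropy. Gradients flow through a
topologically sorted tape; everything is float64.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this (typically scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        out = _node(self.data - other.data, (self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(-_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    def __mul__(self, other: "Tensor") -> "Tensor":
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    def scale(self, c: float) -> "Tensor":
        out = _node(self.data * c, (self,))
        out._backward = lambda g: self._accumulate(g * c)
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = _node(self.data @ other.data, (self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out._backward = bw
        return out


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    out._parents = tuple(p for p in parents if p.requires_grad) or parents
    return out


def parameter(shape_or_array, rng: Optional[np.random.Generator] = None, scale: Optional[float] = None) -> Tensor:
    """Trainable tensor; Glorot-style init when a shape is given."""
    if isinstance(shape_or_array, np.ndarray):
        return Tensor(shape_or_array, requires_grad=True)
    shape = tuple(shape_or_array)
    if rng is None:
        data = np.zeros(shape)
    else:
        fan = sum(shape) if len(shape) > 1 else shape[0]
        s = scale if scale is not None else np.sqrt(2.0 / max(fan, 1))
        data = rng.standard_normal(shape) * s
    return Tensor(data, requires_grad=True)


# -- nonlinearities ---------------------------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = _node(y, (x,))
    out._backward = lambda g: x._accumulate(g * y * (1.0 - y))
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = _node(y, (x,))
    out._backward = lambda g: x._accumulate(g * (1.0 - y * y))
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = _node(x.data * mask, (x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


# -- shape ops --------------------------------------------------------------


def select_time(x: Tensor, t: int) -> Tensor:
    """x[:, t, :] for a (B, T, D) tensor."""
    out = _node(x.data[:, t, :], (x,))

    def bw(g):
        full = np.zeros_like(x.data)
        full[:, t, :] = g
        x._accumulate(full)

    out._backward = bw
    return out


def stack_time(tensors: Sequence[Tensor]) -> Tensor:
    """Stack (B, D) tensors into (B, T, D)."""
    out = _node(np.stack([t.data for t in tensors], axis=1), tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._accumulate(g[:, i, :])

    out._backward = bw
    return out


def concat_last(tensors: Sequence[Tensor]) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=-1), tuple(tensors))
    sizes = [t.data.shape[-1] for t in tensors]

    def bw(g):
        o = 0
        for t, s in zip(tensors, sizes):
            t._accumulate(g[..., o : o + s])
            o += s

    out._backward = bw
    return out


def split_last(x: Tensor, n_chunks: int) -> list[Tensor]:
    size = x.data.shape[-1]
    if size % n_chunks:
        raise ValueError("last axis not divisible")
    w = size // n_chunks
    outs = []
    for k in range(n_chunks):
        out = _node(x.data[..., k * w : (k + 1) * w], (x,))

        def bw(g, k=k):
            full = np.zeros_like(x.data)
            full[..., k * w : (k + 1) * w] = g
            x._accumulate(full)

        out._backward = bw
        outs.append(out)
    return outs


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    out = _node(x.data.reshape(shape), (x,))
    out._backward = lambda g: x._accumulate(g.reshape(x.data.shape))
    return out


def mean_time(x: Tensor) -> Tensor:
    """Mean over axis 1 of a (B, T, D) tensor (global average pooling)."""
    T = x.data.shape[1]
    out = _node(x.data.mean(axis=1), (x,))
    out._backward = lambda g: x._accumulate(np.repeat(g[:, None, :], T, axis=1) / T)
    return out


# -- convolution and pooling ------------------------------------------------


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padding stride-1 1-D convolution.

    x: (B, T, C_in); weight: (K, C_in, C_out); bias: (C_out,).
    """
    B, T, Cin = x.data.shape
    K, Cin2, Cout = weight.data.shape
    if Cin != Cin2:
        raise ValueError("channel mismatch in conv1d")
    pl = K // 2
    pr = K - 1 - pl
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # (B, T, Cin, K)
    cols = win.transpose(0, 1, 3, 2).reshape(B, T, K * Cin)
    wr = weight.data.reshape(K * Cin, Cout)
    out = _node(cols @ wr + bias.data, (x, weight, bias))

    def bw(g):
        bias._accumulate(g.sum(axis=(0, 1)))
        gw = cols.reshape(-1, K * Cin).T @ g.reshape(-1, Cout)
        weight._accumulate(gw.reshape(K, Cin, Cout))
        dcols = (g @ wr.T).reshape(B, T, K, Cin)
        dxp = np.zeros_like(xp)
        for k in range(K):
            dxp[:, k : k + T, :] += dcols[:, :, k, :]
        x._accumulate(dxp[:, pl : pl + T, :])

    out._backward = bw
    return out


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling over the time axis (trailing remainder dropped)."""
    B, T, C = x.data.shape
    To = T // size
    xv = x.data[:, : To * size, :].reshape(B, To, size, C)
    arg = xv.argmax(axis=2)
    out = _node(np.take_along_axis(xv, arg[:, :, None, :], axis=2)[:, :, 0, :], (x,))

    def bw(g):
        full = np.zeros((B, To, size, C))
        np.put_along_axis(full, arg[:, :, None, :], g[:, :, None, :], axis=2)
        dx = np.zeros_like(x.data)
        dx[:, : To * size, :] = full.reshape(B, To * size, C)
        x._accumulate(dx)

    out._backward = bw
    return out


# -- batch normalization ----------------------------------------------------


class BatchNorm:
    """Batch normalization over all axes except the last (feature) axis.

    Keeps running mean/variance so inference depends only on the current
    input window, never on batch composition.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = parameter(np.ones(n_features))
        self.beta = parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = tuple(range(x.data.ndim - 1))
        if training:
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean) * inv
        out = _node(xhat * self.gamma.data + self.beta.data, (x, self.gamma, self.beta))
        m = x.data.size / x.data.shape[-1]

        def bw(g):
            self.beta._accumulate(g.sum(axis=axes))
            self.gamma._accumulate((g * xhat).sum(axis=axes))
            gx = g * self.gamma.data
            if training:
                dx = inv * (gx - gx.mean(axis=axes) - xhat * (gx * xhat).sum(axis=axes) / m)
            else:
                dx = gx * inv
            x._accumulate(dx)

        out._backward = bw
        return out


# -- loss -------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: Tensor, targets: np.ndarray, class_weights: Optional[np.ndarray] = None) -> Tensor:
    """Weighted mean cross-entropy over flattened (…, C) logits."""
    C = logits.data.shape[-1]
    flat = logits.data.reshape(-1, C)
    y = np.asarray(targets).reshape(-1)
    p = softmax(flat)
    w = np.ones(C) if class_weights is None else np.asarray(class_weights, dtype=float)
    wy = w[y]
    losses = -np.log(np.clip(p[np.arange(y.size), y], 1e-300, None))
    total_w = wy.sum()
    out = _node(np.array((wy * losses).sum() / total_w), (logits,))

    def bw(g):
        onehot = np.zeros_like(p)
        onehot[np.arange(y.size), y] = 1.0
        grad = (p - onehot) * wy[:, None] / total_w
        logits._accumulate(float(g) * grad.reshape(logits.data.shape))

    out._backward = bw
    return out


# -- optimizer --------------------------------------------------------------


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
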