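"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations the segmentation network needs are provided: elementwise
arithmetic with broadcasting, matrix products, 3-D same-padding convolution,
batch normalization, 2x max-pooling / nearest upsampling, channel softmax and
the usual nonlinearities and reductions. Every op records a closed-over
backward function; ``Tensor.backward()`` runs the tape in reverse
topological order. All arrays are float64 so gradients can be validated
against central finite differences to tight tolerances.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np

Arrayish = Union["Tensor", np.ndarray, float, int]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Operator sugar
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return div(self, other)


def as_tensor(x: Arrayish) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Arrayish, b: Arrayish) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Arrayish, b: Arrayish) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def div(a: Arrayish, b: Arrayish) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def matmul(a: Arrayish, b: Arrayish) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Arrayish) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=backward)


def sigmoid(x: Arrayish) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def log(x: Arrayish, floor: float = 0.0) -> Tensor:
    x = as_tensor(x)
    clipped = np.maximum(x.data, floor) if floor > 0 else x.data
    out = np.log(clipped)

    def backward(g):
        if x.requires_grad:
            gx = g / clipped
            if floor > 0:
                gx = gx * (x.data >= floor)
            x.accumulate(gx)

    return Tensor(out, parents=(x,), backward=backward)


def tsum(x: Arrayish, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not x.requires_grad:
            return
        if axis is None:
            x.accumulate(np.broadcast_to(g, x.data.shape).copy())
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, axes)
        x.accumulate(np.broadcast_to(g, x.data.shape).copy())

    return Tensor(out, parents=(x,), backward=backward)


def tmean(x: Arrayish, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(x: Arrayish, shape) -> Tensor:
    x = as_tensor(x)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g.reshape(x.data.shape))

    return Tensor(x.data.reshape(shape), parents=(x,), backward=backward)


def concat(tensors: Sequence[Arrayish], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    out = np.concatenate([t.data for t in ts], axis=axis)

    def backward(g):
        offset = 0
        for t, s in zip(ts, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + s)
                t.accumulate(g[tuple(sl)])
            offset += s

    return Tensor(out, parents=tuple(ts), backward=backward)


def conv3d(x: Arrayish, w: Arrayish, b: Arrayish) -> Tensor:
    """Same-padding stride-1 3-D cross-correlation.

    x: (N, C, D, H, W); w: (O, C, k, k, k) with odd k; b: (O,).
    Implemented as k^3 channel-mixing matmuls over shifted views, which
    keeps memory at O(input) instead of materializing an im2col matrix.
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    n, c, d, h, wd = x.data.shape
    o, c2, k, _, _ = w.data.shape
    assert c == c2 and k % 2 == 1
    p = k // 2
    s = d * h * wd
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    yf = np.zeros((n, o, s))
    for a in range(k):
        for bb in range(k):
            for cc in range(k):
                xs = xp[:, :, a : a + d, bb : bb + h, cc : cc + wd].reshape(n, c, s)
                yf += np.matmul(w.data[:, :, a, bb, cc], xs)
    out = yf.reshape(n, o, d, h, wd) + b.data[None, :, None, None, None]

    def backward(g):
        gf = g.reshape(n, o, s)
        if b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for a in range(k):
                for bb in range(k):
                    for cc in range(k):
                        xs = xp[:, :, a : a + d, bb : bb + h, cc : cc + wd].reshape(
                            n, c, s
                        )
                        gw[:, :, a, bb, cc] = np.matmul(
                            gf, xs.transpose(0, 2, 1)
                        ).sum(axis=0)
            w.accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for a in range(k):
                for bb in range(k):
                    for cc in range(k):
                        contrib = np.matmul(w.data[:, :, a, bb, cc].T, gf)
                        gxp[:, :, a : a + d, bb : bb + h, cc : cc + wd] += (
                            contrib.reshape(n, c, d, h, wd)
                        )
            x.accumulate(gxp[:, :, p : p + d, p : p + h, p : p + wd])

    return Tensor(out, parents=(x, w, b), backward=backward)


def maxpool2(x: Arrayish) -> Tensor:
    """2x2x2 max pooling with stride 2 (spatial dims must be even)."""
    x = as_tensor(x)
    n, c, d, h, w = x.data.shape
    xr = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5, 7))

    def backward(g):
        if not x.requires_grad:
            return
        mask = xr == out[:, :, :, None, :, None, :, None]
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        gx = mask * (g[:, :, :, None, :, None, :, None] / counts)
        x.accumulate(gx.reshape(x.data.shape))

    return Tensor(out, parents=(x,), backward=backward)


def upsample2(x: Arrayish) -> Tensor:
    """Nearest-neighbor 2x upsampling of the three spatial dims."""
    x = as_tensor(x)
    out = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(g):
        if not x.requires_grad:
            return
        n, c, d, h, w = x.data.shape
        x.accumulate(
            g.reshape(n, c, d, 2, h, 2, w, 2).sum(axis=(3, 5, 7))
        )

    return Tensor(out, parents=(x,), backward=backward)


def global_avg_pool(x: Arrayish) -> Tensor:
    """(N, C, D, H, W) -> (N, C) spatial mean."""
    x = as_tensor(x)
    n, c = x.data.shape[:2]
    s = int(np.prod(x.data.shape[2:]))
    out = x.data.reshape(n, c, s).mean(axis=2)

    def backward(g):
        if x.requires_grad:
            x.accumulate(
                np.broadcast_to(
                    (g / s)[:, :, None, None, None], x.data.shape
                ).copy()
            )

    return Tensor(out, parents=(x,), backward=backward)


def softmax_channels(x: Arrayish) -> Tensor:
    """Softmax over axis 1 (the class/channel axis)."""
    x = as_tensor(x)
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            x.accumulate(p * (g - (g * p).sum(axis=1, keepdims=True)))

    return Tensor(p, parents=(x,), backward=backward)


def batchnorm(
    x: Arrayish,
    gamma: Arrayish,
    beta: Arrayish,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (N, spatial) per channel.

    ``running_mean``/``running_var`` are updated in place during training
    and used verbatim in eval mode.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0,) + tuple(range(2, x.data.ndim))
    shape = (1, -1) + (1,) * (x.data.ndim - 2)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * ivar.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    m = float(np.prod([x.data.shape[a] for a in axes]))

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(shape)
            if training:
                gx = (
                    gxhat
                    - gxhat.mean(axis=axes, keepdims=True)
                    - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True) / m
                ) * ivar.reshape(shape)
            else:
                gx = gxhat * ivar.reshape(shape)
            x.accumulate(gx)

    return Tensor(out, parents=(x, gamma, beta), backward=backward)
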