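"""A compact reverse-mode automatic-differentiation engine over numpy.

Tensors wrap float32 arrays and record the operations producing them; calling
:meth:`Tensor.backward` on a scalar walks the tape and accumulates gradients
into leaf tensors created with ``requires_grad=True``.  The operation set is
exactly what a small convolutional detector needs: broadcasting elementwise
arithmetic, reductions, concatenation/slicing, 2-d (grouped) convolution via
im2col, pooling, nearest-neighbour upsampling, batch normalization, and the
stable binary-cross-entropy-with-logits primitive.

Convolution keeps the unfolded im2col buffer alive for its backward pass;
1x1/stride-1 convolutions take a cheaper path with no unfolding.  All
computation is float32 and single-threaded apart from BLAS matmuls.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "max_pool2d",
    "upsample_nearest2x",
    "space_to_depth2",
    "batch_norm2d",
    "bce_with_logits",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A float32 array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward: Callable[[np.ndarray], tuple] | None = None

    # -------------------------------------------------------------- plumbing
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep)
        topo: list[Tensor] = []
        state: dict[int, int] = {}
        stack: list[Tensor] = [self]
        while stack:
            t = stack[-1]
            st = state.get(id(t), 0)
            if st == 0:
                state[id(t)] = 1
                for p in t._parents:
                    if state.get(id(p), 0) == 0:
                        stack.append(p)
            else:
                stack.pop()
                if st == 1:
                    state[id(t)] = 2
                    topo.append(t)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t._parents:
                if t.requires_grad:
                    t.grad = g if t.grad is None else t.grad + g
                continue
            if t._backward is None:
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None or not (p.requires_grad or p._parents):
                    continue
                if id(p) in grads:
                    grads[id(p)] += pg
                else:
                    grads[id(p)] = pg

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        out._backward = lambda g: (
            _unbroadcast(g, self.shape),
            _unbroadcast(g, other.shape),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        out._backward = lambda g: (
            _unbroadcast(g * other.data, self.shape),
            _unbroadcast(g * self.data, other.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _node(self.data / other.data, (self, other))
        out._backward = lambda g: (
            _unbroadcast(g / other.data, self.shape),
            _unbroadcast(-g * self.data / (other.data**2), other.shape),
        )
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = _node(self.data**p, (self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def exp(self):
        out = _node(np.exp(self.data), (self,))
        out._backward = lambda g: (g * out.data,)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        out = _node(np.sqrt(self.data), (self,))
        out._backward = lambda g: (g * 0.5 / np.maximum(out.data, 1e-12),)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = _node(s, (self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = _node(self.data * s, (self,))
        out._backward = lambda g: (g * s * (1.0 + self.data * (1.0 - s)),)
        return out

    def maximum(self, other):
        other = _as_tensor(other)
        out = _node(np.maximum(self.data, other.data), (self, other))
        mask = self.data >= other.data
        out._backward = lambda g: (
            _unbroadcast(g * mask, self.shape),
            _unbroadcast(g * ~mask, other.shape),
        )
        return out

    def minimum(self, other):
        other = _as_tensor(other)
        out = _node(np.minimum(self.data, other.data), (self, other))
        mask = self.data <= other.data
        out._backward = lambda g: (
            _unbroadcast(g * mask, self.shape),
            _unbroadcast(g * ~mask, other.shape),
        )
        return out

    def clamp(self, lo: float, hi: float):
        return self.maximum(lo).minimum(hi)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).astype(np.float32),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).astype(np.float32),)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = _node(out_data, (self,))

        def bwd(g):
            full = out_data if keepdims or axis is None else np.expand_dims(
                out_data, axis if isinstance(axis, tuple) else (axis,)
            )
            gfull = g if keepdims or axis is None else np.expand_dims(
                g, axis if isinstance(axis, tuple) else (axis,)
            )
            mask = (self.data == full).astype(np.float32)
            ax = (
                tuple(range(self.ndim))
                if axis is None
                else (axis if isinstance(axis, tuple) else (axis,))
            )
            count = mask.sum(axis=ax, keepdims=True)
            return (gfull * mask / count,)

        out._backward = bwd
        return out

    # ---------------------------------------------------------- shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))

        def bwd(g):
            dx = np.zeros_like(self.data)
            np.add.at(dx, idx, g)
            return (dx,)

        out._backward = bwd
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    t = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        t._parents = parents
    return t


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


# ------------------------------------------------------------------ conv2d


def _window_view(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    n, c, h, w = xp.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """Grouped 2-d cross-correlation; NCHW layout, square kernel/stride/pad."""
    n, cin, h, w = x.shape
    cout, cin_g, kh, kw = weight.shape
    if cin_g * groups != cin or cout % groups:
        raise ValueError("channel/group mismatch")
    cog = cout // groups

    if kh == 1 and kw == 1 and stride == 1 and padding == 0:
        # fast path: a 1x1 convolution is a per-group matmul over pixels
        xg = x.data.reshape(n, groups, cin_g, h * w)
        wg = weight.data.reshape(groups, cog, cin_g)
        out_data = np.einsum("gok,ngkl->ngol", wg, xg, optimize=True).reshape(
            n, cout, h, w
        )
        if bias is not None:
            out_data += bias.data.reshape(1, -1, 1, 1)
        parents = (x, weight) if bias is None else (x, weight, bias)
        out = _node(out_data, parents)

        def bwd(g):
            gy = g.reshape(n, groups, cog, h * w)
            dw = np.einsum("ngol,ngkl->gok", gy, xg, optimize=True).reshape(
                weight.shape
            )
            dx = np.einsum("gok,ngol->ngkl", wg, gy, optimize=True).reshape(x.shape)
            if bias is None:
                return dx, dw
            return dx, dw, g.sum(axis=(0, 2, 3))

        out._backward = bwd
        return out

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    view = _window_view(xp, kh, kw, stride)
    ho, wo = view.shape[4], view.shape[5]
    cols = np.ascontiguousarray(view.transpose(0, 1, 2, 3, 4, 5)).reshape(
        n, groups, cin_g * kh * kw, ho * wo
    )
    wg = weight.data.reshape(groups, cog, cin_g * kh * kw)
    out_data = np.einsum("gok,ngkl->ngol", wg, cols, optimize=True).reshape(
        n, cout, ho, wo
    )
    if bias is not None:
        out_data += bias.data.reshape(1, -1, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _node(out_data, parents)

    def bwd(g):
        gy = g.reshape(n, groups, cog, ho * wo)
        dw = np.einsum("ngol,ngkl->gok", gy, cols, optimize=True).reshape(weight.shape)
        dcols = np.einsum("gok,ngol->ngkl", wg, gy, optimize=True).reshape(
            n, cin, kh, kw, ho, wo
        )
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[
                    :, :, i, j
                ]
        dx = (
            dxp[:, :, padding : padding + h, padding : padding + w]
            if padding
            else dxp
        )
        if bias is None:
            return dx, dw
        return dx, dw, g.sum(axis=(0, 2, 3))

    out._backward = bwd
    return out


def max_pool2d(x: Tensor, k: int, stride: int = 1, padding: int | None = None) -> Tensor:
    """Max pooling with 'same'-style padding by default (used by SPP)."""
    if padding is None:
        padding = k // 2
    n, c, h, w = x.shape
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    view = _window_view(xp, k, k, stride)
    ho, wo = view.shape[4], view.shape[5]
    cols = view.reshape(n, c, k * k, ho, wo)
    arg = cols.argmax(axis=2)
    out = _node(cols.max(axis=2), (x,))

    def bwd(g):
        dcols = np.zeros((n, c, k * k, ho, wo), dtype=np.float32)
        np.put_along_axis(dcols, arg[:, :, None], g[:, :, None], axis=2)
        dcols = dcols.reshape(n, c, k, k, ho, wo)
        dxp = np.zeros_like(xp, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[
                    :, :, i, j
                ]
        return (dxp[:, :, padding : padding + h, padding : padding + w],)

    out._backward = bwd
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = _node(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,))
    out._backward = lambda g: (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)
    return out


def space_to_depth2(x: Tensor) -> Tensor:
    """2x2 space-to-depth: (n, c, h, w) -> (n, 4c, h/2, w/2)."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("spatial dims must be even")
    parts = [
        x.data[:, :, ::2, ::2],
        x.data[:, :, 1::2, ::2],
        x.data[:, :, ::2, 1::2],
        x.data[:, :, 1::2, 1::2],
    ]
    out = _node(np.concatenate(parts, axis=1), (x,))

    def bwd(g):
        dx = np.zeros_like(x.data)
        gs = np.split(g, 4, axis=1)
        dx[:, :, ::2, ::2] = gs[0]
        dx[:, :, 1::2, ::2] = gs[1]
        dx[:, :, ::2, 1::2] = gs[2]
        dx[:, :, 1::2, 1::2] = gs[3]
        return (dx,)

    out._backward = bwd
    return out


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.03,
    eps: float = 1e-4,
) -> Tensor:
    """Per-channel batch normalization with running-statistic tracking."""
    c = x.shape[1]
    gshape = (1, c, 1, 1)
    if training:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
        running_mean += momentum * (m - running_mean)
        running_var += momentum * (v - running_var)
        std = np.sqrt(v + eps).reshape(gshape)
        xhat = (x.data - m.reshape(gshape)) / std
        out = _node(gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape), (x, gamma, beta))
        count = x.data.size / c

        def bwd(g):
            dbeta = g.sum(axis=(0, 2, 3))
            dgamma = (g * xhat).sum(axis=(0, 2, 3))
            dx = (gamma.data.reshape(gshape) / std) * (
                g
                - dbeta.reshape(gshape) / count
                - xhat * dgamma.reshape(gshape) / count
            )
            return dx.astype(np.float32), dgamma, dbeta

        out._backward = bwd
        return out
    std = np.sqrt(running_var + eps).reshape(gshape)
    xhat = (x.data - running_mean.reshape(gshape)) / std
    out = _node(gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape), (x, gamma, beta))

    def bwd_eval(g):
        return (
            (g * gamma.data.reshape(gshape) / std).astype(np.float32),
            (g * xhat).sum(axis=(0, 2, 3)),
            g.sum(axis=(0, 2, 3)),
        )

    out._backward = bwd_eval
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise stable ``max(z,0) - z*y + log(1 + exp(-|z|))``."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float32)
    out = _node(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))), (logits,))
    s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    out._backward = lambda g: (g * (s - y),)
    return out


def softmax(x: Tensor, axis: int) -> Tensor:
    """Softmax along ``axis`` (shift-invariant; the max is treated as constant)."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
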