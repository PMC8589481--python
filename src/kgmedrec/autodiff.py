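"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core the package's trainable models (translation
embeddings, skip-gram, GRU encoder, residual image encoder, multitask
recommender) are built on.  It implements exactly the operations those
models need — broadcast arithmetic, matmul, common nonlinearities,
reductions, reshaping, row gathering for embedding tables, 2-D convolution
and pooling — with dense float gradients and a topological-order backward
pass.  Everything is deterministic: no op consults global state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2d", "SGD", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None
        self.name = name

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data, name: str = "") -> "Tensor":
        return Tensor(data, requires_grad=True, name=name)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self.name!r})"

    # -- autodiff plumbing ----------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** (-1.0)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def bwd(g):
            # supported shapes: (...,i,k)@(...,k,j), (k,)@(k,j), (i,k)@(k,)
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if a.ndim > 1 else g * b
                elif a.ndim == 1:
                    ga = g @ b.T
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if b.ndim > 1 else a * g
                elif b.ndim == 1:
                    gb = a.T @ g
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), bwd)

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0.0))

        return self._make(out_data, (self,), bwd)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis=axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def logsumexp(self, axis=-1, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        s = np.exp(self.data - m).sum(axis=axis, keepdims=True)
        out_data = (m + np.log(s)).squeeze(axis=axis) if not keepdims else m + np.log(s)

        def bwd(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis=axis)
            soft = np.exp(self.data - m) / s
            self._accum(g * soft)

        return self._make(out_data, (self,), bwd)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return self._make(out_data, (self,), bwd)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(out_data, (self,), bwd)

    @property
    def T(self):
        return self.transpose()

    def gather(self, idx):
        """Row lookup (embedding gather); grad scatter-adds into the table."""
        idx = np.asarray(idx)
        out_data = self.data[idx]

        def bwd(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                np.add.at(self.grad, idx, g)

        return self._make(out_data, (self,), bwd)


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# convolution / pooling primitives (im2col based)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return np.ascontiguousarray(cols.reshape(b, c * kh * kw, ho * wo)), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad):
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    xg = np.zeros((b, c, hp, wp))
    cols = cols.reshape(b, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            xg[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    return xg[:, :, pad:pad + h, pad:pad + w] if pad else xg


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution: x (B,C,H,W), weight (O,C,kh,kw), bias (O,)."""
    o, c, kh, kw = weight.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)  # (B, C*kh*kw, Ho*Wo)
    wmat = weight.data.reshape(o, -1)
    out_data = np.einsum("ok,bkp->bop", wmat, cols).reshape(-1, o, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gmat = g.reshape(g.shape[0], o, -1)  # (B, O, Ho*Wo)
        if weight.requires_grad:
            gw = np.einsum("bop,bkp->ok", gmat, cols).reshape(weight.shape)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("ok,bop->bkp", wmat, gmat)
            x._accum(_col2im(gcols, x.data.shape, kh, kw, stride, pad))

    out = Tensor(out_data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = bwd
    return out


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k max pooling with stride k; spatial dims must divide k."""
    b, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    xr = x.data.reshape(b, c, h // k, k, w // k, k)
    out_data = xr.max(axis=(3, 5))
    mask = xr == out_data[:, :, :, None, :, None]
    # under ties, split the gradient evenly so total mass is preserved
    counts = mask.sum(axis=(3, 5), keepdims=True)

    def bwd(g):
        if x.requires_grad:
            gexp = (mask / counts) * g[:, :, :, None, :, None]
            x._accum(gexp.reshape(b, c, h, w))

    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class SGD:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
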