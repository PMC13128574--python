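"""A compact reverse-mode automatic-differentiation engine over numpy arrays.

The segmentation network in this package runs on the CPU and needs only a
small set of differentiable primitives: broadcasting arithmetic, a few
pointwise nonlinearities, reductions, shape manipulation, dense matrix
products, 3D (optionally depthwise) convolution, separable linear
interpolation, and the selective-scan recurrence (a custom node built in
:mod:`anisoseg.blocks` on top of the numba kernels).  Each primitive records
a backward closure; :meth:`Tensor.backward` walks the graph in reverse
topological order and accumulates gradients into ``Tensor.grad``.

Gradients of every primitive are exercised by finite-difference tests, which
is the correctness contract that matters here; throughput only has to be
adequate for small CPU-scale training runs.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

from .exceptions import DimensionError

__all__ = ["Tensor", "concat", "conv3d", "axis_interp", "interp_matrix", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise DimensionError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate state eagerly: backward closures form
                # reference cycles that would otherwise wait for the gc
                node._backward = None
                node._parents = ()
                node.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda a, b, g: g, lambda a, b, g: g)

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda a, b, g: g * b, lambda a, b, g: g * a)

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda a, b, g: g, lambda a, b, g: -g)

    def __rsub__(self, other):
        return _wrap(other) - self

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda a, b, g: g / b, lambda a, b, g: -g * a / (b * b))

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __neg__(self):
        return _unary(self, np.negative, lambda x, y, g: -g)

    def __pow__(self, p: float):
        return _unary(self, lambda x: np.power(x, p),
                      lambda x, y, g: g * p * np.power(x, p - 1))

    # -- pointwise --------------------------------------------------------
    def exp(self):
        return _unary(self, np.exp, lambda x, y, g: g * y)

    def log(self):
        return _unary(self, np.log, lambda x, y, g: g / x)

    def sigmoid(self):
        def f(x):
            return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(x.dtype)
        return _unary(self, f, lambda x, y, g: g * y * (1 - y))

    def softplus(self):
        def f(x):
            return (np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0)).astype(x.dtype)

        def df(x, y, g):
            s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                         np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
            return g * s.astype(x.dtype)
        return _unary(self, f, df)

    def silu(self):
        return self * self.sigmoid()

    def clamp(self, lo: float | None = None, hi: float | None = None):
        def f(x):
            return np.clip(x, lo, hi)

        def df(x, y, g):
            m = np.ones_like(x)
            if lo is not None:
                m = m * (x >= lo)
            if hi is not None:
                m = m * (x <= hi)
            return g * m
        return _unary(self, f, df)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        x = self.data
        out = Tensor(x.sum(axis=axis, keepdims=keepdims))
        if self.requires_grad and _grad_enabled:
            out.requires_grad = True
            out._parents = (self,)

            def bw(g):
                gg = g
                if not keepdims and axis is not None:
                    gg = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, x.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor(self.data.reshape(shape))
        if self.requires_grad and _grad_enabled:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda g: self._accum(g.reshape(src))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes))
        if self.requires_grad and _grad_enabled:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def take(self, idx: np.ndarray, axis: int):
        """Permute (or gather) along `axis` with an integer index array."""
        idx = np.asarray(idx)
        out = Tensor(np.take(self.data, idx, axis=axis))
        if self.requires_grad and _grad_enabled:
            out.requires_grad = True
            out._parents = (self,)

            def bw(g):
                gg = np.zeros_like(self.data)
                sl = [slice(None)] * self.data.ndim
                sl[axis] = idx
                np.add.at(gg, tuple(sl), g)
                self._accum(gg)
            out._backward = bw
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key])
        if self.requires_grad and _grad_enabled:
            out.requires_grad = True
            out._parents = (self,)

            def bw(g):
                gg = np.zeros_like(self.data)
                gg[key] += g
                self._accum(gg)
            out._backward = bw
        return out

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other: "Tensor"):
        a, b = self, _wrap(other)
        out = Tensor(np.matmul(a.data, b.data))
        if (a.requires_grad or b.requires_grad) and _grad_enabled:
            out.requires_grad = True
            out._parents = tuple(p for p in (a, b) if p.requires_grad)

            def bw(g):
                if a.requires_grad:
                    ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                    a._accum(_unbroadcast(ga, a.data.shape))
                if b.requires_grad:
                    gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                    b._accum(_unbroadcast(gb, b.data.shape))
            out._backward = bw
        return out

    __matmul__ = matmul


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unary(t: Tensor, f, df) -> Tensor:
    out = Tensor(f(t.data))
    if t.requires_grad and _grad_enabled:
        out.requires_grad = True
        out._parents = (t,)
        out._backward = lambda g: t._accum(df(t.data, out.data, g))
    return out


def _binary(a: Tensor, b, f, dfa, dfb) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(f(a.data, b.data))
    if (a.requires_grad or b.requires_grad) and _grad_enabled:
        out.requires_grad = True
        out._parents = tuple(p for p in (a, b) if p.requires_grad)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(dfa(a.data, b.data, g), a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(dfb(a.data, b.data, g), b.data.shape))
        out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors) and _grad_enabled:
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)
        out._backward = bw
    return out


# -- 3D convolution -------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: Sequence[int] = (1, 1, 1), depthwise: bool = False) -> Tensor:
    """Same-padded 3D convolution over (B, C, D, H, W) with odd kernels.

    `w` is (Cout, Cin, kd, kh, kw), or (C, 1, kd, kh, kw) when depthwise.
    Output extent per axis is ceil(in / stride).  Implemented as a sum of
    shifted strided slices times kernel taps, which keeps memory flat and
    makes the backward pass a mirrored scatter-add.
    """
    x, w = _wrap(x), _wrap(w)
    kd, kh, kw = w.data.shape[2:]
    if kd % 2 == 0 or kh % 2 == 0 or kw % 2 == 0:
        raise DimensionError("conv3d requires odd kernel extents")
    sd, sh, sw = stride
    B, Cin, D, H, W = x.data.shape
    pd, ph, pw = kd // 2, kh // 2, kw // 2
    Do, Ho, Wo = -(-D // sd), -(-H // sh), -(-W // sw)
    Cout = w.data.shape[0]
    if not depthwise and w.data.shape[1] != Cin:
        raise DimensionError(f"conv3d weight expects {w.data.shape[1]} input channels, got {Cin}")
    if depthwise and (w.data.shape[0] != Cin or w.data.shape[1] != 1):
        raise DimensionError("depthwise conv3d weight must be (C, 1, kd, kh, kw)")

    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    out = np.zeros((B, Cout, Do, Ho, Wo), dtype=x.data.dtype)
    offsets = [(i, j, k) for i in range(kd) for j in range(kh) for k in range(kw)]

    def _slice(i, j, k):
        return (slice(None), slice(None),
                slice(i, i + (Do - 1) * sd + 1, sd),
                slice(j, j + (Ho - 1) * sh + 1, sh),
                slice(k, k + (Wo - 1) * sw + 1, sw))

    for i, j, k in offsets:
        xs = xp[_slice(i, j, k)]
        if depthwise:
            out += xs * w.data[:, 0, i, j, k][None, :, None, None, None]
        else:
            wk = w.data[:, :, i, j, k]                       # (Cout, Cin)
            m = xs.reshape(B, Cin, -1)
            out += np.matmul(wk[None], m).reshape(B, Cout, Do, Ho, Wo)
    if b is not None:
        out += _wrap(b).data[None, :, None, None, None]

    res = Tensor(out)
    parents = [p for p in (x, w) if p.requires_grad]
    bt = _wrap(b) if b is not None else None
    if bt is not None and bt.requires_grad:
        parents.append(bt)
    if parents and _grad_enabled:
        res.requires_grad = True
        res._parents = tuple(parents)

        def bw(g):
            if bt is not None and bt.requires_grad:
                bt._accum(g.sum(axis=(0, 2, 3, 4)))
            gxp = np.zeros_like(xp) if x.requires_grad else None
            gw = np.zeros_like(w.data) if w.requires_grad else None
            gm = g.reshape(B, Cout, -1)
            for i, j, k in offsets:
                xs = xp[_slice(i, j, k)]
                if depthwise:
                    if gw is not None:
                        gw[:, 0, i, j, k] += (g * xs).sum(axis=(0, 2, 3, 4))
                    if gxp is not None:
                        gxp[_slice(i, j, k)] += g * w.data[:, 0, i, j, k][None, :, None, None, None]
                else:
                    wk = w.data[:, :, i, j, k]
                    m = xs.reshape(B, Cin, -1)
                    if gw is not None:
                        gw[:, :, i, j, k] += np.matmul(gm, m.transpose(0, 2, 1)).sum(axis=0)
                    if gxp is not None:
                        gxs = np.matmul(wk.T[None], gm).reshape(B, Cin, Do, Ho, Wo)
                        gxp[_slice(i, j, k)] += gxs
            if gw is not None:
                w._accum(gw)
            if gxp is not None:
                gx = gxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W]
                x._accum(gx)
        res._backward = bw
    return res


# -- separable linear interpolation ---------------------------------------

def interp_matrix(n_in: int, n_out: int, dtype=np.float32) -> np.ndarray:
    """Dense 1D linear-interpolation matrix (n_out, n_in), endpoint-aligned.

    Constants are preserved exactly and affine ramps stay affine.
    """
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(src).astype(int)
    lo = np.minimum(lo, n_in - 2)
    frac = src - lo
    m[np.arange(n_out), lo] = 1.0 - frac
    m[np.arange(n_out), lo + 1] = frac
    return m


def axis_interp(x: Tensor, mat: np.ndarray, axis: int) -> Tensor:
    """Apply a fixed linear map `mat` (n_out, n_in) along `axis` of x."""
    x = _wrap(x)
    mat = np.asarray(mat, dtype=x.data.dtype)

    def apply(a, m):
        moved = np.moveaxis(a, axis, -1)
        out = moved @ m.T
        return np.moveaxis(out, -1, axis)

    out = Tensor(apply(x.data, mat))
    if x.requires_grad and _grad_enabled:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = lambda g: x._accum(apply(g, mat.T))
    return out
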