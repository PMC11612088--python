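"""Reverse-mode automatic differentiation over numpy arrays.

A small tensor engine sufficient for the convolutional attention networks in
this package: broadcasting arithmetic, batched matmul, softmax, N-dimensional
stride-1 dilated convolution, 2x transposed convolution, 2x max pooling,
nearest-neighbour upsampling and batch normalisation, each with an explicit
backward rule.  Floating-point dtype follows the input arrays (parameters are
float32; float64 inputs stay float64), so numerical oracles can be run at
double precision through the same code path used for training.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["Tensor", "astensor", "concat", "softmax", "softplus", "matmul"]


def _as_array(data):
    a = np.asarray(data)
    if a.dtype.kind in "iub":
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- introspection -----------------------------------------------------
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

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            # copy: g may alias an upstream gradient shared with a sibling node
            self.grad = np.array(g, dtype=np.promote_types(self.data.dtype, np.float32))
        else:
            self.grad += g

    # -- arithmetic ---------------------------------------------------------
    # python scalars take a dedicated path: wrapping them in a float64 array
    # would silently promote float32 activations
    def __add__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data + self.data.dtype.type(other), _prev=(self,))

            def backward(g):
                if self.requires_grad:
                    self._accumulate(g)
        else:
            other = astensor(other)
            out = Tensor(self.data + other.data, _prev=(self, other))

            def backward(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            s = self.data.dtype.type(other)
            out = Tensor(self.data * s, _prev=(self,))

            def backward(g):
                if self.requires_grad:
                    self._accumulate(g * s)
        else:
            other = astensor(other)
            out = Tensor(self.data * other.data, _prev=(self, other))

            def backward(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-astensor(other))

    def __rsub__(self, other):
        return (-self) + other

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = astensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / (other.data ** 2), other.data.shape))

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(src))

        out._backward = backward
        return out

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    def swapaxes(self, a, b):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(axes)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def backward(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data, dtype=g.dtype)
                np.add.at(buf, idx, g)
                self._accumulate(buf)

        out._backward = backward
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        src_shape = self.data.shape

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, src_shape).copy())
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % len(src_shape) for a in axes)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                self._accumulate(np.broadcast_to(g, src_shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- pointwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = backward
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = backward
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = backward
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        out._backward = backward
        return out

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def detach(self):
        return Tensor(self.data)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(np.matmul(a.data, b.data), _prev=(a, b))

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = backward
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = astensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, _prev=(x,))

    def backward(g):
        if x.requires_grad:
            gs = g * s
            x._accumulate(gs - s * gs.sum(axis=axis, keepdims=True))

    out._backward = backward
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), overflow-safe; gradient is sigmoid(x)."""
    x = astensor(x)
    d = x.data
    val = np.maximum(d, 0) + np.log1p(np.exp(-np.abs(d)))
    out = Tensor(val, _prev=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g / (1.0 + np.exp(-np.clip(d, -60, 60))))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Spatial operators (N spatial dimensions, channels-first layout: (N, C, *S))
# ---------------------------------------------------------------------------

def conv_nd(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1,
            padding: int | None = None) -> Tensor:
    """Stride-1 cross-correlation of (N,C_in,*S) with (C_out,C_in,*K).

    Implemented as one GEMM per kernel tap, which keeps memory flat for 3D
    volumes.  `padding` defaults to dilation*(K//2) per axis, i.e. "same"
    output shape for odd kernels.
    """
    x, w = astensor(x), astensor(w)
    nd = x.ndim - 2
    ksizes = w.shape[2:]
    if padding is None:
        padding = tuple(dilation * (k // 2) for k in ksizes)
    elif np.isscalar(padding):
        padding = (int(padding),) * nd
    n, cin = x.shape[:2]
    cout = w.shape[0]
    if w.shape[1] != cin:
        raise ValueError(f"conv weight expects {w.shape[1]} input channels, got {cin}")
    pad_width = ((0, 0), (0, 0)) + tuple((p, p) for p in padding)
    xp = np.pad(x.data, pad_width)
    out_spatial = tuple(xp.shape[2 + i] - dilation * (ksizes[i] - 1) for i in range(nd))
    npix = int(np.prod(out_spatial))
    dtype = np.promote_types(x.dtype, w.dtype)
    out_data = np.zeros((n, cout, npix), dtype=dtype)
    taps = list(itertools.product(*[range(k) for k in ksizes]))
    tap_slices = []
    for t in taps:
        sl = (slice(None), slice(None)) + tuple(
            slice(t[i] * dilation, t[i] * dilation + out_spatial[i]) for i in range(nd)
        )
        tap_slices.append(sl)
        xs = xp[sl].reshape(n, cin, npix)
        wt = w.data[(slice(None), slice(None)) + t]  # (cout, cin)
        out_data += np.matmul(wt[None], xs)
    out_data = out_data.reshape((n, cout) + out_spatial)
    if b is not None:
        b = astensor(b)
        out_data = out_data + b.data.reshape((1, cout) + (1,) * nd)
        prev = (x, w, b)
    else:
        prev = (x, w)
    out = Tensor(out_data, _prev=prev)

    def backward(g):
        g2 = g.reshape(n, cout, npix)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0,) + tuple(range(2, g.ndim))))
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for t, sl in zip(taps, tap_slices):
            xs = xp[sl].reshape(n, cin, npix)
            if w.requires_grad:
                gw = np.einsum("nop,ncp->oc", g2, xs, optimize=True)
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
                w.grad[(slice(None), slice(None)) + t] += gw.astype(w.data.dtype, copy=False)
            if gxp is not None:
                wt = w.data[(slice(None), slice(None)) + t]
                gx = np.matmul(wt.T[None], g2).reshape((n, cin) + out_spatial)
                gxp[sl] += gx
        if gxp is not None:
            crop = (slice(None), slice(None)) + tuple(
                slice(p, xp.shape[2 + i] - p) for i, p in enumerate(padding)
            )
            x._accumulate(gxp[crop])

    out._backward = backward
    return out


def conv_transpose2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2: doubles every spatial axis.

    Weight layout (C_in, C_out, *2); each input pixel paints one 2^nd block.
    """
    x, w = astensor(x), astensor(w)
    nd = x.ndim - 2
    n, cin = x.shape[:2]
    cout = w.shape[1]
    spatial = x.shape[2:]
    out_spatial = tuple(2 * s for s in spatial)
    npix = int(np.prod(spatial))
    dtype = np.promote_types(x.dtype, w.dtype)
    out_data = np.zeros((n, cout) + out_spatial, dtype=dtype)
    x2 = x.data.reshape(n, cin, npix)
    taps = list(itertools.product(*([range(2)] * nd)))
    tap_slices = {}
    for t in taps:
        wt = w.data[(slice(None), slice(None)) + t]  # (cin, cout)
        piece = np.matmul(wt.T[None], x2).reshape((n, cout) + spatial)
        sl = (slice(None), slice(None)) + tuple(slice(t[i], None, 2) for i in range(nd))
        out_data[sl] = piece
        tap_slices[t] = sl
    if b is not None:
        b = astensor(b)
        out_data += b.data.reshape((1, cout) + (1,) * nd)
        prev = (x, w, b)
    else:
        prev = (x, w)
    out = Tensor(out_data, _prev=prev)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0,) + tuple(range(2, g.ndim))))
        for t in taps:
            gp = g[tap_slices[t]].reshape(n, cout, npix)
            if w.requires_grad:
                gw = np.einsum("nop,ncp->co", gp, x2, optimize=True)
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
                w.grad[(slice(None), slice(None)) + t] += gw.astype(w.data.dtype, copy=False)
            if x.requires_grad:
                wt = w.data[(slice(None), slice(None)) + t]
                gx = np.matmul(wt[None], gp).reshape((n, cin) + spatial)
                x._accumulate(gx)

    out._backward = backward
    return out


def _window_permute(ndim_spatial: int):
    # (N, C, s1, 2, s2, 2, ...) -> (N, C, s1, s2, ..., 2, 2, ...)
    axes = [0, 1]
    axes += [2 + 2 * i for i in range(ndim_spatial)]
    axes += [3 + 2 * i for i in range(ndim_spatial)]
    return axes


def maxpool2(x: Tensor) -> Tensor:
    """2x max pooling along every spatial axis (requires even extents)."""
    x = astensor(x)
    nd = x.ndim - 2
    n, c = x.shape[:2]
    spatial = x.shape[2:]
    if any(s % 2 for s in spatial):
        raise ValueError(f"maxpool2 requires even spatial extents, got {spatial}")
    half = tuple(s // 2 for s in spatial)
    shape = (n, c) + tuple(v for s in half for v in (s, 2))
    perm = _window_permute(nd)
    r = x.data.reshape(shape).transpose(perm)
    r = r.reshape((n, c) + half + (2 ** nd,))
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, _prev=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        buf = np.zeros((n, c) + half + (2 ** nd,), dtype=g.dtype)
        np.put_along_axis(buf, idx[..., None], g[..., None], axis=-1)
        buf = buf.reshape((n, c) + half + (2,) * nd)
        inv = np.argsort(perm)
        x._accumulate(buf.transpose(inv).reshape(x.data.shape))

    out._backward = backward
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor on every spatial axis."""
    x = astensor(x)
    nd = x.ndim - 2
    data = x.data
    for ax in range(2, 2 + nd):
        data = np.repeat(data, factor, axis=ax)
    out = Tensor(data, _prev=(x,))
    spatial = x.shape[2:]

    def backward(g):
        if not x.requires_grad:
            return
        n, c = x.shape[:2]
        shape = (n, c) + tuple(v for s in spatial for v in (s, factor))
        perm = _window_permute(nd)
        r = g.reshape(shape).transpose(perm).reshape((n, c) + spatial + (factor ** nd,))
        x._accumulate(r.sum(axis=-1))

    out._backward = backward
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
              running_var: np.ndarray, training: bool, momentum: float = 0.1,
              eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation; running stats updated in place."""
    x = astensor(x)
    nd = x.ndim - 2
    axes = (0,) + tuple(range(2, x.ndim))
    cshape = (1, x.shape[1]) + (1,) * nd
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(cshape)) * inv.reshape(cshape)
    out_data = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)
    out = Tensor(out_data, _prev=(x, gamma, beta))
    m = x.data.size / x.shape[1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(cshape)
            if training:
                term = gxhat - gxhat.mean(axis=axes, keepdims=True) \
                    - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
                x._accumulate(term * inv.reshape(cshape))
            else:
                x._accumulate(gxhat * inv.reshape(cshape))

    out._backward = backward
    return out
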