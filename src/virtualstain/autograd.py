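"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's networks are small encoder–decoder CNNs trained at desk
scale, so a compact tape-based engine suffices: a :class:`Tensor` wraps an
``ndarray``, records its parents and a backward closure, and
:meth:`Tensor.backward` walks the tape in reverse topological order.
Convolutions are im2col/col2im based and carry exact gradients; everything
else is elementwise or a reshape/reduction with standard adjoints.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "upsample_nearest2x",
    "default_dtype",
    "use_dtype",
]

#: compute dtype; float32 keeps desk-scale training fast, float64 is used
#: by tests that compare against high-precision oracles
_DTYPE = np.float32


def default_dtype():
    return _DTYPE


@contextlib.contextmanager
def use_dtype(dtype):
    """Temporarily switch the engine's compute dtype."""
    global _DTYPE
    prev = _DTYPE
    _DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DTYPE = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (adjoint of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    # ---------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep tapes overflow Python recursion
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the tape so intermediate buffers can be reclaimed
        for node in topo:
            if node is not self:
                node._parents = ()
                node._backward = None

    def _accum(self, grad: np.ndarray):
        if not self.requires_grad and self._backward is None:
            return
        if self.grad is None:
            # may alias the caller's buffer; accumulation below never
            # mutates in place, so aliasing is safe
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def _bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def _bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = _bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def _bwd(g):
            a, b = self.data, other.data
            if self.requires_grad or self._backward is not None:
                self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
            if other.requires_grad or other._backward is not None:
                other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        out._backward = _bwd
        return out

    # ------------------------------------------------------------ shape/slices
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g.reshape(old))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = _bwd
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def _bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------- elementwise
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(
            np.where(self.data > 0, self.data, slope * self.data),
            self.requires_grad,
            (self,),
        )
        out._backward = lambda g: self._accum(g * np.where(self.data > 0, 1.0, slope))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - t**2))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def softplus(self):
        # log(1 + e^x), stable form x⁺ + log1p(e^{-|x|})
        sp = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        out = Tensor(sp, self.requires_grad, (self,))
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out._backward = lambda g: self._accum(g * sig)
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))

        def _bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        out._backward = _bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = _bwd
    return out


# --------------------------------------------------------------------- conv2d
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) → (N, Ho*Wo, C*kh*kw) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N,C,Ho,Wo,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col` — scatter-add patches back to image."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    img = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            img[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, :, :, i, j
            ]
    if pad:
        img = img[:, :, pad : hp - pad, pad : wp - pad]
    return img


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation of (N,C,H,W) with weight (O,C,kh,kw)."""
    x, weight = as_tensor(x), as_tensor(weight)
    n = x.data.shape[0]
    o, c, kh, kw = weight.data.shape
    if x.data.shape[1] != c:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[1]}, weight expects {c}"
        )
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    w_mat = weight.data.reshape(o, -1)
    out_d = cols @ w_mat.T  # (N, Ho*Wo, O)
    if bias is not None:
        out_d = out_d + bias.data.reshape(1, 1, o)
    out_d = out_d.transpose(0, 2, 1).reshape(n, o, ho, wo)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_d, any(p.requires_grad for p in parents), parents)

    def _bwd(g):
        g2 = g.reshape(n, o, ho * wo).transpose(0, 2, 1)  # (N, HoWo, O)
        if weight.requires_grad or weight._backward is not None:
            gw = np.einsum("nlo,nlk->ok", g2, cols)
            weight._accum(gw.reshape(weight.data.shape))
        if bias is not None:
            bias._accum(g2.sum(axis=(0, 1)))
        gcols = g2 @ w_mat  # (N, HoWo, C*kh*kw)
        x._accum(_col2im(gcols, x.data.shape, kh, kw, stride, padding))

    out._backward = _bwd
    return out


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed convolution; weight (C_in, O, kh, kw); Ho=(H−1)s+k−2p."""
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.data.shape
    ci, o, kh, kw = weight.data.shape
    if c != ci:
        raise ValueError(f"conv_transpose2d channel mismatch: {c} vs {ci}")
    ho = (h - 1) * stride + kh - 2 * padding
    wo = (w - 1) * stride + kw - 2 * padding
    w_mat = weight.data.reshape(ci, o * kh * kw)
    xcols = x.data.reshape(n, c, h * w).transpose(0, 2, 1)  # (N, HW, C)
    cols = xcols @ w_mat  # (N, HW, O*kh*kw)
    out_d = _col2im(cols, (n, o, ho, wo), kh, kw, stride, padding)
    if bias is not None:
        out_d = out_d + bias.data.reshape(1, o, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_d, any(p.requires_grad for p in parents), parents)

    def _bwd(g):
        gcols, _, _ = _im2col(g, kh, kw, stride, padding)  # (N, HW, O*kh*kw)
        if weight.requires_grad or weight._backward is not None:
            gw = np.einsum("nlc,nlk->ck", xcols, gcols)
            weight._accum(gw.reshape(weight.data.shape))
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2, 3)))
        gx = (gcols @ w_mat.T).transpose(0, 2, 1).reshape(n, c, h, w)
        x._accum(gx)

    out._backward = _bwd
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2× spatial upsampling of (N,C,H,W)."""
    x = as_tensor(x)
    up = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(up, x.requires_grad, (x,))
    n, c, h, w = x.data.shape

    def _bwd(g):
        g = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        x._accum(g)

    out._backward = _bwd
    return out
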