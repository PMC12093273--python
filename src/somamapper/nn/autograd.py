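"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the soma classification and segmentation
networks need: broadcasting arithmetic, matmul, reshape/transpose/roll,
ReLU/sigmoid/exp/log, reductions, concatenation, padding, slicing, an
embedding lookup (for relative-position bias tables) and N-dimensional
strided convolution.  Gradients are accumulated by topological-order
backpropagation from a scalar loss.

All arrays are float32 unless stated otherwise.  The engine is intentionally
small; it is validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv_nd", "conv_transpose2x_3d", "embedding_lookup"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
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
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        return self._make(e, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def roll(self, shift, axis) -> "Tensor":
        """Cyclic shift; gradient rolls back by the negated shift."""
        shift = tuple(np.atleast_1d(shift))
        axis = tuple(np.atleast_1d(axis))

        def backward(g):
            if self.requires_grad:
                self._accum(np.roll(g, tuple(-s for s in shift), axis))

        return self._make(np.roll(self.data, shift, axis), (self,), backward)

    def pad(self, pad_width) -> "Tensor":
        """Zero padding; pad_width as for np.pad."""
        pw = tuple(tuple(p) for p in pad_width)
        sl = tuple(slice(b, self.data.shape[i] + b) for i, (b, _a) in enumerate(pw))

        def backward(g):
            if self.requires_grad:
                self._accum(g[sl])

        return self._make(np.pad(self.data, pw), (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def embedding_lookup(table: Tensor, index: np.ndarray) -> Tensor:
    """table[index] with scatter-add gradient; index is a constant int array."""
    index = np.asarray(index)
    out_data = table.data[index]

    def backward(g):
        if table.requires_grad:
            full = np.zeros_like(table.data)
            np.add.at(full, index, g)
            table._accum(full)

    return table._make(out_data, (table,), backward)


# -- convolution --------------------------------------------------------------


def _windows(x: np.ndarray, kernel: tuple[int, ...], stride: int) -> np.ndarray:
    """Sliding windows of x (N,C,*spatial) -> (N,C,*out_spatial,*kernel)."""
    nd = len(kernel)
    view = np.lib.stride_tricks.sliding_window_view(x, kernel, axis=tuple(range(2, 2 + nd)))
    if stride > 1:
        sl = (slice(None), slice(None)) + (slice(None, None, stride),) * nd
        view = view[sl]
    return view


_LETTERS = "xyz"


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
            padding: int = 0) -> Tensor:
    """N-dimensional cross-correlation.

    x: (N, C, *spatial) with 2 or 3 spatial dims; w: (O, C, *kernel);
    b: (O,) or None.  Zero padding, integer stride shared across axes.
    """
    nd = x.ndim - 2
    kernel = w.shape[2:]
    xp = x.data
    if padding:
        pw = ((0, 0), (0, 0)) + ((padding, padding),) * nd
        xp = np.pad(xp, pw)
    sp = _LETTERS[:nd]
    kl = "ijk"[:nd]
    win = _windows(xp, kernel, stride)  # (N,C,*out,*k)
    out_data = np.einsum(f"nc{sp}{kl},oc{kl}->no{sp}", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data.reshape((1, -1) + (1,) * nd)

    def backward(g):
        if w.requires_grad:
            gw = np.einsum(f"nc{sp}{kl},no{sp}->oc{kl}", win, g, optimize=True)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
        if x.requires_grad:
            x._accum(_conv_input_grad(g, w.data, x.data.shape, stride, padding))

    parents = (x, w) if b is None else (x, w, b)
    return x._make(out_data, parents, backward)


def _conv_input_grad(g: np.ndarray, w: np.ndarray, x_shape: tuple[int, ...],
                     stride: int, padding: int) -> np.ndarray:
    """Gradient of conv_nd w.r.t. its input (= transposed convolution)."""
    nd = len(x_shape) - 2
    kernel = w.shape[2:]
    sp = _LETTERS[:nd]
    kl = "ijk"[:nd]
    # Dilate the output gradient by the stride, then full-correlate with the
    # spatially flipped kernel (channels swapped).
    if stride > 1:
        dil_shape = (g.shape[0], g.shape[1]) + tuple(
            (s - 1) * stride + 1 for s in g.shape[2:]
        )
        gd = np.zeros(dil_shape, dtype=g.dtype)
        sl = (slice(None), slice(None)) + (slice(None, None, stride),) * nd
        gd[sl] = g
    else:
        gd = g
    pad_amt = tuple(k - 1 for k in kernel)
    pw = ((0, 0), (0, 0)) + tuple((p, p) for p in pad_amt)
    gd = np.pad(gd, pw)
    w_flip = w[(slice(None), slice(None)) + (slice(None, None, -1),) * nd]
    win = _windows(gd, kernel, 1)
    gx_full = np.einsum(f"no{sp}{kl},oc{kl}->nc{sp}", win, w_flip, optimize=True)
    # gx_full covers the padded input extent (possibly short of it when the
    # last window did not reach the edge); crop/embed to the true input shape.
    padded = tuple(x_shape[2 + i] + 2 * padding for i in range(nd))
    gx = np.zeros(x_shape[:2] + padded, dtype=g.dtype)
    sl = (slice(None), slice(None)) + tuple(slice(0, s) for s in gx_full.shape[2:])
    gx[sl] = gx_full
    if padding:
        inner = (slice(None), slice(None)) + tuple(
            slice(padding, padding + x_shape[2 + i]) for i in range(nd)
        )
        gx = gx[inner]
    return gx


def conv_transpose2x_3d(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed 3D convolution with kernel 2, stride 2 (exact 2x upsampling).

    x: (N, C, H, W, D); w: (C, O, 2, 2, 2); output (N, O, 2H, 2W, 2D).
    Non-overlapping, so forward/backward are plain einsum reshapes.
    """
    n, c, h, wd, d = x.shape
    o = w.shape[1]
    y = np.einsum("ncxyz,coijk->noxiyjzk", x.data, w.data, optimize=True)
    y = y.reshape(n, o, 2 * h, 2 * wd, 2 * d)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1, 1)

    def backward(g):
        gr = g.reshape(n, o, h, 2, wd, 2, d, 2).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        if x.requires_grad:
            gx = np.einsum("noxyzijk,coijk->ncxyz", gr, w.data, optimize=True)
            x._accum(gx)
        if w.requires_grad:
            gw = np.einsum("noxyzijk,ncxyz->coijk", gr, x.data, optimize=True)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    return x._make(y, parents, backward)
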