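"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the progression and super-resolution
networks need: broadcast arithmetic, matmul, element-wise nonlinearities,
reductions, slicing/reshape/concat, element-wise min/max, stride-1 "same"
convolution in 2D/3D, 2x average pooling and 2x nearest-neighbour
upsampling.  Everything is float64 and single-threaded, so runs are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "minimum", "maximum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_pending")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ----- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

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

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ----- backprop ---------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node._accum(g)
                continue
            node._backward(g)  # type: ignore[misc]
            # _backward stores parent grads through node._stash set below
            for p, pg in node._pending:  # type: ignore[attr-defined]
                if p._backward is None and p._parents == ():
                    p._accum(pg)
                else:
                    key = id(p)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            del node._pending  # type: ignore[attr-defined]

    # ----- arithmetic -------------------------------------------------------------
    def _binary(self, other, fwd, bwd) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = fwd(self.data, other.data)

        def backward(g: np.ndarray) -> None:
            ga, gb = bwd(g, self.data, other.data)
            pending = []
            if self.requires_grad:
                pending.append((self, _unbroadcast(ga, self.data.shape)))
            if other.requires_grad:
                pending.append((other, _unbroadcast(gb, other.data.shape)))
            out._pending = pending  # type: ignore[attr-defined]

        out = Tensor._make(data, (self, other), backward)
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return Tensor(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b, lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return Tensor(other).__truediv__(self)

    def __neg__(self):
        return self * -1.0

    def __pow__(self, p: float):
        return self._unary(lambda a: a ** p, lambda g, a, y: g * p * a ** (p - 1))

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data @ other.data

        def backward(g: np.ndarray) -> None:
            pending = []
            if self.requires_grad:
                pending.append((self, g @ other.data.T))
            if other.requires_grad:
                pending.append((other, self.data.T @ g))
            out._pending = pending  # type: ignore[attr-defined]

        out = Tensor._make(data, (self, other), backward)
        return out

    # ----- unary ops --------------------------------------------------------------
    def _unary(self, fwd, bwd) -> "Tensor":
        data = fwd(self.data)

        def backward(g: np.ndarray) -> None:
            out._pending = [(self, bwd(g, self.data, data))]  # type: ignore[attr-defined]

        out = Tensor._make(data, (self,), backward)
        return out

    def exp(self):
        return self._unary(np.exp, lambda g, a, y: g * y)

    def log(self):
        return self._unary(np.log, lambda g, a, y: g / a)

    def tanh(self):
        return self._unary(np.tanh, lambda g, a, y: g * (1.0 - y * y))

    def sigmoid(self):
        def fwd(a):
            out = np.empty_like(a)
            pos = a >= 0
            out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
            ea = np.exp(a[~pos])
            out[~pos] = ea / (1.0 + ea)
            return out

        return self._unary(fwd, lambda g, a, y: g * y * (1.0 - y))

    def leaky_relu(self, slope: float = 0.2):
        return self._unary(
            lambda a: np.where(a >= 0, a, slope * a),
            lambda g, a, y: g * np.where(a >= 0, 1.0, slope),
        )

    def clip(self, lo: float, hi: float):
        return self._unary(
            lambda a: np.clip(a, lo, hi),
            lambda g, a, y: g * ((a >= lo) & (a <= hi)),
        )

    # ----- shape ops --------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return self._unary(lambda a: a.reshape(shape),
                           lambda g, a, y: g.reshape(old))

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            out._pending = [(self, full)]  # type: ignore[attr-defined]

        out = Tensor._make(data, (self,), backward)
        return out

    # ----- reductions -------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g: np.ndarray) -> None:
            if axis is None:
                full = np.broadcast_to(g, shape).copy()
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                full = np.broadcast_to(g2, shape).copy()
            out._pending = [(self, full)]  # type: ignore[attr-defined]

        out = Tensor._make(data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ----- structured ops ---------------------------------------------------------
    def conv(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """Stride-1 'same' N-d convolution (2D or 3D, odd kernels).

        self: (N, C, *spatial); weight: (O, C, *kernel); bias: (O,).
        """
        nd = weight.data.ndim - 2
        k = weight.data.shape[2]
        if weight.data.shape[2:] != (k,) * nd or k % 2 == 0:
            raise ValueError("kernels must be cubic with odd side")
        p = k // 2
        pad = ((0, 0), (0, 0)) + ((p, p),) * nd
        spec = {2: ("nchwij,ocij->nohw", "nchwij,nohw->ocij", "nohwij,ocij->nchw"),
                3: ("ncdhwijk,ocijk->nodhw", "ncdhwijk,nodhw->ocijk",
                    "nodhwijk,ocijk->ncdhw")}[nd]
        axes = tuple(range(2, 2 + nd))
        xp = np.pad(self.data, pad)
        win = sliding_window_view(xp, (k,) * nd, axis=axes)
        data = np.einsum(spec[0], win, weight.data, optimize=True)
        data += bias.data.reshape((1, -1) + (1,) * nd)

        def backward(g: np.ndarray) -> None:
            pending = []
            if weight.requires_grad:
                pending.append((weight, np.einsum(spec[1], win, g, optimize=True)))
            if bias.requires_grad:
                pending.append((bias, g.sum(axis=(0,) + axes)))
            if self.requires_grad:
                gp = np.pad(g, pad)
                gwin = sliding_window_view(gp, (k,) * nd, axis=axes)
                flip = (slice(None), slice(None)) + (slice(None, None, -1),) * nd
                pending.append(
                    (self, np.einsum(spec[2], gwin, weight.data[flip], optimize=True)))
            out._pending = pending  # type: ignore[attr-defined]

        out = Tensor._make(data, (self, weight, bias), backward)
        return out

    def avg_pool2(self) -> "Tensor":
        """2x2 average pooling on (N, C, H, W); H, W must be even."""
        n, c, h, w = self.data.shape
        data = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

        def backward(g: np.ndarray) -> None:
            full = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
            out._pending = [(self, full)]  # type: ignore[attr-defined]

        out = Tensor._make(data, (self,), backward)
        return out

    def upsample2(self) -> "Tensor":
        """2x nearest-neighbour upsampling on (N, C, H, W)."""
        data = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)
        n, c, h, w = self.data.shape

        def backward(g: np.ndarray) -> None:
            full = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
            out._pending = [(self, full)]  # type: ignore[attr-defined]

        out = Tensor._make(data, (self,), backward)
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        parts = np.split(g, splits, axis=axis)
        out._pending = [(t, p) for t, p in zip(tensors, parts)  # type: ignore[attr-defined]
                        if t.requires_grad]

    out = Tensor._make(data, tensors, backward)
    return out


def _minmax(a: Tensor, b: Tensor, fn) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)
    data = fn(a.data, b.data)
    take_a = fn is np.minimum
    mask = (a.data <= b.data) if take_a else (a.data >= b.data)

    def backward(g: np.ndarray) -> None:
        pending = []
        if a.requires_grad:
            pending.append((a, _unbroadcast(g * mask, a.data.shape)))
        if b.requires_grad:
            pending.append((b, _unbroadcast(g * ~mask, b.data.shape)))
        out._pending = pending  # type: ignore[attr-defined]

    out = Tensor._make(data, (a, b), backward)
    return out


def minimum(a, b) -> Tensor:
    """Element-wise minimum; on ties the gradient flows to the first input."""
    return _minmax(a, b, np.minimum)


def maximum(a, b) -> Tensor:
    """Element-wise maximum; on ties the gradient flows to the first input."""
    return _minmax(a, b, np.maximum)
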