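"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operations the dual-view synergy network needs:
dense affine maps, elementwise nonlinearities, concatenation, row
gather/scatter and segment reductions (for graph attention over ragged
mini-batches of molecular graphs), and segment softmax.

Gradients are accumulated into ``Tensor.grad`` by :func:`backward`,
which performs a topological sort of the recorded tape. The engine is
deliberately small: no broadcasting rules beyond those exercised here,
no higher-order derivatives, float64 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "segment_max",
    "segment_mean",
    "segment_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = _make(self.data + other.data, self, other)

        def bwd(g):
            if self.requires_grad:
                _accum(self, _unbroadcast(g, self.data.shape))
            if other.requires_grad:
                _accum(other, _unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (other * -1.0)

    def __mul__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            out = _make(self.data * other, self)

            def bwd_s(g):
                if self.requires_grad:
                    _accum(self, g * other)

            out._backward = bwd_s
            return out
        other = _as_tensor(other)
        out = _make(self.data * other.data, self, other)

        def bwd(g):
            if self.requires_grad:
                _accum(self, _unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                _accum(other, _unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = _make(self.data @ other.data, self, other)

        def bwd(g):
            if self.requires_grad:
                _accum(self, g @ other.data.T)
            if other.requires_grad:
                _accum(other, self.data.T @ g)

        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------------
    def relu(self) -> "Tensor":
        out = _make(np.maximum(self.data, 0.0), self)
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                _accum(self, g * mask)

        out._backward = bwd
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out = _make(np.where(self.data > 0, self.data, slope * self.data), self)
        fac = np.where(self.data > 0, 1.0, slope)

        def bwd(g):
            if self.requires_grad:
                _accum(self, g * fac)

        out._backward = bwd
        return out

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = _make(val, self)

        def bwd(g):
            if self.requires_grad:
                _accum(self, g * val)

        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = _make(np.log(self.data), self)

        def bwd(g):
            if self.requires_grad:
                _accum(self, g / self.data)

        out._backward = bwd
        return out

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), self)

        def bwd(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _accum(self, np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = _make(self.data.reshape(*shape), self)

        def bwd(g):
            if self.requires_grad:
                _accum(self, g.reshape(self.data.shape))

        out._backward = bwd
        return out

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, *parents: Tensor) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = parents
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64)
    else:
        t.grad = t.grad + g


# -- structural operations ----------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), *tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                _accum(t, g[tuple(idx)])

    out._backward = bwd
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``x[index]``; backward scatter-adds into the source rows."""
    index = np.asarray(index, dtype=np.intp)
    out = _make(x.data[index], x)

    def bwd(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, index, g)
            _accum(x, acc)

    out._backward = bwd
    return out


def segment_sum(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given per-row ids."""
    segments = np.asarray(segments, dtype=np.intp)
    data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, segments, x.data)
    out = _make(data, x)

    def bwd(g):
        if x.requires_grad:
            _accum(x, g[segments])

    out._backward = bwd
    return out


def segment_mean(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    segments = np.asarray(segments, dtype=np.intp)
    counts = np.bincount(segments, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    s = segment_sum(x, segments, num_segments)
    inv = (1.0 / counts).reshape((num_segments,) + (1,) * (x.data.ndim - 1))
    return s * Tensor(inv)


def segment_max(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Per-segment elementwise max; gradient flows to the argmax rows."""
    segments = np.asarray(segments, dtype=np.intp)
    data = np.full((num_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(data, segments, x.data)
    out = _make(data, x)
    # winner mask: row i contributes where it attains the segment max
    winners = x.data == data[segments]
    # break ties: keep only the first winner per (segment, feature) slot
    order = np.argsort(segments, kind="stable")
    first = np.zeros_like(winners)
    taken = np.zeros((num_segments,) + x.data.shape[1:], dtype=bool)
    for i in order:
        w = winners[i] & ~taken[segments[i]]
        first[i] = w
        taken[segments[i]] |= w

    def bwd(g):
        if x.requires_grad:
            _accum(x, g[segments] * first)

    out._backward = bwd
    return out


def segment_softmax(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of ``x`` normalized within each segment (per trailing slot).

    Used for attention coefficients: rows sharing a segment id form one
    neighborhood and their coefficients sum to 1. Numerically stabilized
    by subtracting the per-segment max (a constant shift under softmax).
    """
    segments = np.asarray(segments, dtype=np.intp)
    mx = np.full((num_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(mx, segments, x.data)
    shifted = np.exp(x.data - mx[segments])
    denom = np.zeros_like(mx)
    np.add.at(denom, segments, shifted)
    alpha = shifted / denom[segments]
    out = _make(alpha, x)

    def bwd(g):
        if not x.requires_grad:
            return
        # d softmax: alpha * (g - sum_seg(alpha * g))
        dot = np.zeros_like(mx)
        np.add.at(dot, segments, alpha * g)
        _accum(x, alpha * (g - dot[segments]))

    out._backward = bwd
    return out
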