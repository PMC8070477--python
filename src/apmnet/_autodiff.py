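"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape of :class:`Tensor` nodes supporting exactly the operations the
network needs: dense matmul, broadcast add/mul, ReLU, row gather,
segment sum (the sparse-graph aggregation primitive), batched
matrix-vector products (edge-conditioned messages), reshape, and the
smooth-L1 loss. Gradients are accumulated by a topological backward
sweep; everything runs in float64 on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "relu", "matmul", "gather", "segment_sum",
           "bmv", "smooth_l1_loss", "gradcheck"]


class Tensor:
    """A numpy array plus gradient slot and backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.value.shape

    # -- graph bookkeeping -------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this (typically scalar) tensor."""
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
            grad = np.ones_like(self.value)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return _add(self, as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return _add(self, _scale(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return _add(as_tensor(other), _scale(self, -1.0))

    def __mul__(self, other):
        return _mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __rmatmul__(self, other):
        return matmul(as_tensor(other), self)

    def reshape(self, *shape):
        return _reshape(self, shape)

    def sum(self, axis=None):
        return _sum(self, axis)

    def mean(self):
        n = self.value.size
        return _scale(_sum(self, None), 1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(value, parents, backward) -> Tensor:
    out = Tensor(value, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.value.shape))
    return _node(a.value + b.value, (a, b), backward)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.value, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.value, b.value.shape))
    return _node(a.value * b.value, (a, b), backward)


def _scale(a: Tensor, c: float) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g * c)
    return _node(a.value * c, (a,), backward)


def _reshape(a: Tensor, shape) -> Tensor:
    old = a.value.shape

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(old))
    return _node(a.value.reshape(shape), (a,), backward)


def _sum(a: Tensor, axis) -> Tensor:
    def backward(g):
        if a.requires_grad:
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.value.shape).copy()
                              if np.ndim(g) else np.full_like(a.value, g))
            else:
                a._accumulate(np.broadcast_to(
                    np.expand_dims(g, axis), a.value.shape).copy())
    return _node(a.value.sum(axis=axis), (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.value.T)
        if b.requires_grad:
            b._accumulate(a.value.T @ g)
    return _node(a.value @ b.value, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = a.value > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)
    return _node(a.value * mask, (a,), backward)


def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``a[idx]``; gradient scatters back with accumulation."""
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        if a.requires_grad:
            buf = np.zeros_like(a.value)
            np.add.at(buf, idx, g)
            a._accumulate(buf)
    return _node(a.value[idx], (a,), backward)


def segment_sum(a: Tensor, seg_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets given per-row ids."""
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    out = np.zeros((num_segments,) + a.value.shape[1:], dtype=np.float64)
    np.add.at(out, seg_ids, a.value)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[seg_ids])
    return _node(out, (a,), backward)


def bmv(mats: Tensor, vecs: Tensor) -> Tensor:
    """Batched matrix-vector product: out[e] = mats[e] @ vecs[e].

    ``mats`` is (m, d, d), ``vecs`` is (m, d); returns (m, d).
    """
    def backward(g):
        if mats.requires_grad:
            mats._accumulate(g[:, :, None] * vecs.value[:, None, :])
        if vecs.requires_grad:
            vecs._accumulate(np.einsum("eij,ei->ej", mats.value, g))
    return _node(np.einsum("eij,ej->ei", mats.value, vecs.value),
                 (mats, vecs), backward)


def smooth_l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean smooth-L1 (Huber, beta=1): 0.5 r^2 if |r|<1 else |r|-0.5."""
    target = np.asarray(target, dtype=np.float64)
    r = pred.value - target
    small = np.abs(r) < 1.0
    per = np.where(small, 0.5 * r * r, np.abs(r) - 0.5)
    n = r.size

    def backward(g):
        if pred.requires_grad:
            dr = np.where(small, r, np.sign(r))
            pred._accumulate(g * dr / n)
    return _node(per.mean(), (pred,), backward)


def gradcheck(fn, params: list[Tensor], eps: float = 1e-6,
              atol: float = 1e-5) -> float:
    """Compare analytic gradients of scalar ``fn(params)`` with central
    finite differences. Returns the max absolute deviation found."""
    for p in params:
        p.zero_grad()
    out = fn()
    out.backward()
    worst = 0.0
    for p in params:
        analytic = p.grad if p.grad is not None else np.zeros_like(p.value)
        flat = p.value.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn().value
            flat[i] = orig - eps
            lo = fn().value
            flat[i] = orig
            num = (hi - lo) / (2 * eps)
            worst = max(worst, abs(num - analytic.reshape(-1)[i]))
    if worst > atol:
        raise AssertionError(f"gradcheck failed: max deviation {worst:.3e}")
    return worst
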