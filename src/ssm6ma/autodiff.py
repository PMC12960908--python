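"""Tape-based reverse-mode automatic differentiation on NumPy arrays.

The model in :mod:`ssm6ma.network` needs exact analytic gradients for a small
set of operations (affine maps, a per-position convolution, a sequential
state-space scan, layer normalization, softmax, elementwise nonlinearities).
This module provides a compact reverse-mode engine over ``numpy.ndarray``
data: every operation records its parents and a closure that propagates the
upstream gradient; :meth:`Tensor.backward` walks the tape in reverse
topological order.

Two operations are fused for speed — the position-specific convolution and
the selective scan — because at sequence length ~41 the per-step graph
overhead would otherwise dominate. Their backward passes are hand-derived
and checked against finite differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "stack",
    "softmax",
    "layer_norm",
    "embedding",
    "pos_conv",
    "ssm_scan",
    "dropout",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
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
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative post-order to avoid recursion limits on long tapes
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    # -- op construction helper -------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other, self.dtype)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other, self.dtype)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)

    # -- elementwise nonlinearities ----------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def silu(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * s * (1.0 + self.data * (1.0 - s)))

        return Tensor._make(self.data * s, (self,), backward)

    def softplus(self) -> "Tensor":
        # log(1 + e^x), computed stably
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            self._accumulate(g / (1.0 + np.exp(-self.data)))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]

        def backward(g):
            gg = g / n
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(self.data.mean(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        def backward(g):
            self._accumulate(g.reshape(self.data.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, key) -> "Tensor":
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        return Tensor._make(self.data[key], (self,), backward)


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


# -- composite / fused operations ------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(part)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        x._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return Tensor._make(s, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def backward(g):
        if gamma.requires_grad:
            axes = tuple(range(g.ndim - 1))
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            axes = tuple(range(g.ndim - 1))
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2))

    return Tensor._make(xhat * gamma.data + beta.data, (x, gamma, beta),
                        backward)


def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``table[indices]`` with gradient scatter-add to the table."""
    idx = np.asarray(indices)
    if idx.min() < 0 or idx.max() >= table.data.shape[0]:
        raise IndexError("embedding index out of range")

    def backward(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx.ravel(), g.reshape(-1, g.shape[-1]))
        table._accumulate(full)

    return Tensor._make(table.data[idx], (table,), backward)


def pos_conv(weights: Tensor, x: Tensor) -> Tensor:
    """Position-specific convolution.

    ``weights`` has shape (L, F, K, M) — an independent bank of F filters of
    width K over M channels at every sequence position — or (1, F, K, M) for
    the weight-tied (shared) variant. ``x`` has shape (B, L, M). The input is
    zero-padded by K//2 rows on both ends, so output row i sees input rows
    i-K//2 .. i+K//2. Returns shape (B, L, F).
    """
    Lw, F, K, M = weights.data.shape
    B, L, Mx = x.data.shape
    if Mx != M:
        raise ValueError(f"channel mismatch: weights M={M}, input M={Mx}")
    if Lw not in (1, L):
        raise ValueError(f"weights cover {Lw} positions, input has {L}")
    if K % 2 != 1:
        raise ValueError("window size K must be odd")
    pad = K // 2
    xp = np.zeros((B, L + 2 * pad, M), dtype=x.data.dtype)
    xp[:, pad:pad + L] = x.data
    # windowed copy: xw[l, b, k*M + m] = xp[b, l + k, m]
    sB, sL, sM = xp.strides
    xw = np.lib.stride_tricks.as_strided(
        xp, shape=(L, B, K, M), strides=(sL, sB, sL, sM))
    xw = xw.reshape(L, B, K * M)
    wr = weights.data.reshape(Lw, F, K * M).transpose(0, 2, 1)  # (Lw, KM, F)
    out = np.matmul(xw, wr)  # (L, B, F), broadcasting over Lw == 1

    def backward(g):
        gT = g.transpose(1, 0, 2)  # (L, B, F)
        if weights.requires_grad:
            gw = np.matmul(xw.transpose(0, 2, 1), gT)  # (L, KM, F)
            if Lw == 1:
                gw = gw.sum(axis=0, keepdims=True)
            weights._accumulate(
                gw.transpose(0, 2, 1).reshape(Lw, F, K, M))
        if x.requires_grad:
            gx = np.matmul(gT, wr.transpose(0, 2, 1) if Lw == L
                           else np.broadcast_to(wr.transpose(0, 2, 1),
                                                (L, F, K * M)))
            gx = gx.reshape(L, B, K, M)
            gxp = np.zeros((B, L + 2 * pad, M), dtype=g.dtype)
            for k in range(K):
                gxp[:, k:k + L] += gx[:, :, k].transpose(1, 0, 2)
            x._accumulate(gxp[:, pad:pad + L])

    return Tensor._make(out.transpose(1, 0, 2), (weights, x), backward)


def ssm_scan(abar: Tensor, bbar: Tensor, c: Tensor, g_in: Tensor) -> Tensor:
    """Per-channel linear state recurrence with input-dependent parameters.

    For every channel f the state h_t in R^S follows

        h_t = abar_t * h_{t-1} + bbar_t * g_t[f],   h_0 = 0
        z_t[f] = <c_t, h_t>

    where ``abar``, ``bbar``, ``c`` are (B, L, S) — shared across channels —
    and ``g_in`` is (B, L, F). Returns z of shape (B, L, F). The scan is
    causal: z_t depends only on g_1..g_t. The backward pass replays the
    recurrence in reverse (backprop through time) using the stored states.
    """
    from ._kernels import scan_backward, scan_forward

    A = np.ascontiguousarray(abar.data)
    Bb = np.ascontiguousarray(bbar.data)
    C = np.ascontiguousarray(c.data)
    G = np.ascontiguousarray(g_in.data)
    B, L, S = A.shape
    F = G.shape[2]
    hs = np.empty((B, L, F, S), dtype=G.dtype)
    z = np.empty((B, L, F), dtype=G.dtype)
    scan_forward(A, Bb, C, G, hs, z)

    def backward(grad):
        dA = np.empty_like(A)
        dBb = np.empty_like(Bb)
        dC = np.empty_like(C)
        dG = np.empty_like(G)
        scan_backward(A, Bb, C, G, hs, np.ascontiguousarray(grad),
                      dA, dBb, dC, dG)
        if abar.requires_grad:
            abar._accumulate(dA)
        if bbar.requires_grad:
            bbar._accumulate(dBb)
        if c.requires_grad:
            c._accumulate(dC)
        if g_in.requires_grad:
            g_in._accumulate(dG)

    return Tensor._make(z, (abar, bbar, c, g_in), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    mask = mask.astype(x.data.dtype)

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)
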