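"""Compact reverse-mode automatic differentiation on NumPy arrays.

This module is the numerical substrate for the differentiable operators in
this package (covariance pooling, the dual-task recognition/restoration heads,
and the training loops). It implements a single :class:`Tensor` type wrapping
an ``np.ndarray`` together with a vector-Jacobian-product (VJP) graph, plus
the small set of primitives the pipeline needs: broadcasting arithmetic,
matmul, reductions, shape ops, 2-D convolution via im2col, a symmetric
eigendecomposition with the standard analytic VJP, and a fused
softmax-cross-entropy.

Design notes
------------
* Gradients are accumulated only into *leaf* tensors (tensors with no
  parents) that have ``requires_grad=True``; intermediate gradients live in a
  per-call dictionary, so several ``backward()`` calls on different losses
  sharing one forward graph compose additively. The staged multi-loss
  training procedure relies on this.
* Everything is float64. The package targets desk-scale numerical fidelity
  (oracle agreement to 1e-6, finite-difference checks), not GPU throughput.
* ``eigh`` uses the standard spectral VJP with coefficients
  ``F_ij = 1/(lam_j - lam_i)``; it is valid for simple spectra, which is the
  regime the covariance pipeline operates in after regularization.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "eigh",
    "log_softmax",
    "pad2d",
    "softmax",
    "softmax_cross_entropy",
]


def _as_array(data) -> Array:
    a = np.asarray(data, dtype=np.float64)
    return a


class Tensor:
    """An N-d array node in a reverse-mode autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        self.data: Array = _as_array(data)
        self.grad: Array | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._vjps: tuple[Callable[[Array], Array] | None, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data: Array, parents: Sequence["Tensor"],
              vjps: Sequence[Callable[[Array], Array] | None]) -> "Tensor":
        out = Tensor(data)
        req = any(p.requires_grad for p in parents)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._vjps = tuple(v if p.requires_grad else None
                              for p, v in zip(parents, vjps))
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- backward pass --------------------------------------------------------

    def backward(self, grad: Array | None = None) -> None:
        """Accumulate d(self)/d(leaf) into every reachable leaf's ``.grad``.

        Multiple calls (e.g. one per loss term) accumulate; call
        ``zero_grad`` on leaves between optimizer steps.
        """
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = _as_array(grad)
        # iterative topological sort (graphs can be deep)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, Array] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                if node.requires_grad:
                    if node.grad is None:
                        node.grad = np.zeros_like(node.data)
                    node.grad += g
                continue
            for p, vjp in zip(node._parents, node._vjps):
                if vjp is None or not p.requires_grad:
                    continue
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- operator sugar -------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent: float):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- method sugar for common ops ------------------------------------------

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    def relu(self):
        return relu(self)

    def exp(self):
        return exp(self)

    def log(self):
        return log(self)

    def sqrt(self):
        return sqrt(self)

    @property
    def T(self):
        return transpose(self, None)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- broadcasting helper -------------------------------------------------------

def _unbroadcast(g: Array, shape: tuple[int, ...]) -> Array:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- elementwise / broadcasting primitives -------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data
    return Tensor._make(out, (a, b), (
        lambda g: _unbroadcast(g, a.data.shape),
        lambda g: _unbroadcast(g, b.data.shape),
    ))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data
    return Tensor._make(out, (a, b), (
        lambda g: _unbroadcast(g * b.data, a.data.shape),
        lambda g: _unbroadcast(g * a.data, b.data.shape),
    ))


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** exponent
    return Tensor._make(out, (a,), (
        lambda g: g * exponent * a.data ** (exponent - 1.0),
    ))


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return Tensor._make(out, (a,), (lambda g: g * out,))


def log(a) -> Tensor:
    a = as_tensor(a)
    out = np.log(a.data)
    return Tensor._make(out, (a,), (lambda g: g / a.data,))


def log1p(a) -> Tensor:
    a = as_tensor(a)
    out = np.log1p(a.data)
    return Tensor._make(out, (a,), (lambda g: g / (1.0 + a.data),))


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out = np.sqrt(a.data)
    return Tensor._make(out, (a,), (lambda g: g * 0.5 / out,))


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out = a.data * mask
    return Tensor._make(out, (a,), (lambda g: g * mask,))


# -- reductions ----------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g: Array) -> Array:
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy() if np.ndim(g) == 0 \
                else np.full(a.data.shape, g)
        g2 = g
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.data.ndim for ax in axes)
            g2 = np.expand_dims(g, axes)
        return np.broadcast_to(g2, a.data.shape).copy()

    return Tensor._make(np.asarray(out, dtype=np.float64), (a,), (vjp,))


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = 1
        for ax in axes:
            n *= a.data.shape[ax % a.data.ndim]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# -- shape ops -----------------------------------------------------------------

def reshape(a, shape: tuple[int, ...]) -> Tensor:
    a = as_tensor(a)
    out = a.data.reshape(shape)
    orig = a.data.shape
    return Tensor._make(out, (a,), (lambda g: g.reshape(orig),))


def transpose(a, axes: tuple[int, ...] | None = None) -> Tensor:
    a = as_tensor(a)
    out = np.transpose(a.data, axes)
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))
    return Tensor._make(out, (a,), (lambda g: np.transpose(g, inv),))


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = as_tensor(a)
    axes = list(range(a.data.ndim))
    axes[ax1], axes[ax2] = axes[ax2], axes[ax1]
    return transpose(a, tuple(axes))


def concat(tensors: Iterable, axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor._make(out, ts, tuple(make_vjp(i) for i in range(len(ts))))


def pad2d(a, padding: int) -> Tensor:
    """Zero-pad the two trailing spatial axes of an (..., H, W) tensor."""
    a = as_tensor(a)
    if padding == 0:
        return a
    p = int(padding)
    width = [(0, 0)] * (a.data.ndim - 2) + [(p, p), (p, p)]
    out = np.pad(a.data, width)
    sl = (Ellipsis, slice(p, out.shape[-2] - p), slice(p, out.shape[-1] - p))
    return Tensor._make(out, (a,), (lambda g: g[sl],))


# -- linear algebra ------------------------------------------------------------

def matmul(a, b) -> Tensor:
    """Matrix product of two tensors with ndim >= 2 (batched over leading axes)."""
    a, b = as_tensor(a), as_tensor(b)
    if a.data.ndim < 2 or b.data.ndim < 2:
        raise ValueError("matmul requires ndim >= 2 operands; reshape first")
    out = a.data @ b.data

    def vjp_a(g: Array) -> Array:
        return _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)

    def vjp_b(g: Array) -> Array:
        return _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)

    return Tensor._make(out, (a, b), (vjp_a, vjp_b))


def eigh(a) -> tuple[Tensor, Tensor]:
    """Symmetric eigendecomposition with eigenvalues in *descending* order.

    Returns ``(lam, U)`` with ``a = U @ diag(lam) @ U^T`` (batched over leading
    axes). The VJP assumes the input is symmetric and returns a symmetrized
    gradient; repeated eigenvalues make the eigenvector VJP ill-defined (as in
    every autodiff framework) but all spectral functions built downstream are
    basis-independent.
    """
    a = as_tensor(a)
    w, v = np.linalg.eigh(a.data)
    # descending order
    w = w[..., ::-1].copy()
    v = v[..., ::-1].copy()

    def _sym(m: Array) -> Array:
        return 0.5 * (m + np.swapaxes(m, -1, -2))

    def vjp_w(g: Array) -> Array:
        # U diag(g) U^T
        return _sym(np.matmul(v * g[..., None, :], np.swapaxes(v, -1, -2)))

    def vjp_v(g: Array) -> Array:
        diff = w[..., None, :] - w[..., :, None]  # lam_j - lam_i
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(np.abs(diff) > 1e-12, 1.0 / diff, 0.0)
        inner = np.matmul(np.swapaxes(v, -1, -2), g)
        core = f * inner
        return _sym(np.matmul(np.matmul(v, core), np.swapaxes(v, -1, -2)))

    lam = Tensor._make(w, (a,), (vjp_w,))
    u = Tensor._make(v, (a,), (vjp_v,))
    return lam, u


# -- convolution ---------------------------------------------------------------

def _im2col_indices(C: int, H: int, W: int, KH: int, KW: int,
                    stride: int, padding: int):
    OH = (H + 2 * padding - KH) // stride + 1
    OW = (W + 2 * padding - KW) // stride + 1
    i0 = np.repeat(np.arange(KH), KW)
    i0 = np.tile(i0, C)
    i1 = stride * np.repeat(np.arange(OH), OW)
    j0 = np.tile(np.arange(KW), KH * C)
    j1 = stride * np.tile(np.arange(OW), OH)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)  # (C*KH*KW, OH*OW)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    k = np.repeat(np.arange(C), KH * KW).reshape(-1, 1)
    return k, i, j, OH, OW


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation: x (B,C,H,W), weight (Cout,C,KH,KW), bias (Cout,)."""
    x, weight = as_tensor(x), as_tensor(weight)
    B, C, H, W = x.data.shape
    Cout, Cin, KH, KW = weight.data.shape
    if Cin != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cin}")
    p, s = int(padding), int(stride)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    k, i, j, OH, OW = _im2col_indices(C, H, W, KH, KW, s, p)
    cols = xp[:, k, i, j]                      # (B, C*KH*KW, OH*OW)
    wmat = weight.data.reshape(Cout, -1)       # (Cout, C*KH*KW)
    out = np.matmul(wmat, cols)                # (B, Cout, OH*OW)
    out = out.reshape(B, Cout, OH, OW)
    if bias is not None:
        bias = as_tensor(bias)
        out = out + bias.data.reshape(1, Cout, 1, 1)

    def vjp_x(g: Array) -> Array:
        gcols = np.matmul(wmat.T, g.reshape(B, Cout, OH * OW))  # (B,C*KH*KW,OH*OW)
        gxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        np.add.at(gxp, (slice(None), k, i, j), gcols)
        return gxp[:, :, p:p + H, p:p + W] if p else gxp

    def vjp_w(g: Array) -> Array:
        gmat = np.matmul(g.reshape(B, Cout, OH * OW),
                         np.swapaxes(cols, 1, 2)).sum(axis=0)  # (Cout, C*KH*KW)
        return gmat.reshape(Cout, Cin, KH, KW)

    parents: list[Tensor] = [x, weight]
    vjps: list = [vjp_x, vjp_w]
    if bias is not None:
        parents.append(bias)
        vjps.append(lambda g: g.sum(axis=(0, 2, 3)))
    return Tensor._make(out, parents, vjps)


# -- softmax family ------------------------------------------------------------

def log_softmax(logits, axis: int = -1) -> Tensor:
    z = as_tensor(logits)
    shift = Tensor(np.max(z.data, axis=axis, keepdims=True))  # constant shift
    zs = z - shift
    return zs - log(tsum(exp(zs), axis=axis, keepdims=True))


def softmax(logits, axis: int = -1) -> Tensor:
    return exp(log_softmax(logits, axis=axis))


def softmax_cross_entropy(logits, labels: Array) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels.

    logits: (B, N) or (N,); labels: (B,) int array or scalar int.
    """
    z = as_tensor(logits)
    data = z.data
    squeeze = data.ndim == 1
    if squeeze:
        data = data[None, :]
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    B, N = data.shape
    if labels.shape[0] != B:
        raise ValueError("softmax_cross_entropy: batch size mismatch")
    if labels.min() < 0 or labels.max() >= N:
        raise ValueError(f"label out of range [0, {N})")
    shifted = data - data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=1))
    losses = lse - shifted[np.arange(B), labels]
    out = losses.mean()

    def vjp(g: Array) -> Array:
        p = np.exp(shifted)
        p /= p.sum(axis=1, keepdims=True)
        p[np.arange(B), labels] -= 1.0
        gz = (float(g) / B) * p
        return gz[0] if squeeze else gz

    return Tensor._make(np.asarray(out), (z,), (vjp,))
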