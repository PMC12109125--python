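"""Reverse-mode automatic differentiation on NumPy arrays.

A small define-by-run tape: each :class:`Tensor` wraps an ``ndarray`` and
remembers the operation that produced it as a closure mapping the upstream
gradient to gradients for its parents.  Only the operations the network in
this package needs are provided (elementwise arithmetic, batched matmul,
shape ops, 2-D convolution/pooling, batch/layer normalisation, softmax,
dropout).  Convolution is evaluated as one im2col matrix product per call so
the heavy lifting stays inside BLAS.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "conv2d",
    "maxpool2d",
    "batchnorm",
    "layernorm",
    "softmax",
    "dropout",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (evaluation mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``g`` back to ``shape`` after NumPy broadcasting."""
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


class Tensor:
    """An ndarray plus the tape bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward_fn: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward_fn):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward_fn = backward_fn
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- backward engine ----------------------------------------------------

    def backward(self, grad: np.ndarray | None = None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            gs = node._backward_fn(node.grad)
            for p, g in zip(node._parents, gs):
                if g is None or not p.requires_grad:
                    continue
                g = np.asarray(g, dtype=p.data.dtype)
                if p.grad is None:
                    p.grad = g
                else:
                    p.grad = p.grad + g
            if node is not self:
                node.grad = None  # free intermediate gradients early

    # -- elementwise arithmetic --------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._wrap(other)
        return Tensor._result(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._result(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor._result(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor._result(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __pow__(self, p: float):
        return Tensor._result(
            self.data**p, (self,), lambda g: (g * p * self.data ** (p - 1),)
        )

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape),)

        return Tensor._result(data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._result(
            np.where(mask, self.data, 0.0), (self,), lambda g: (g * mask,)
        )

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._result(y, (self,), lambda g: (g * y * (1.0 - y),))

    def exp(self):
        y = np.exp(self.data)
        return Tensor._result(y, (self,), lambda g: (g * y,))

    def log(self):
        return Tensor._result(np.log(self.data), (self,), lambda g: (g / self.data,))

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._result(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._result(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(self.shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._result(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        def bwd(g):
            out = np.zeros(self.shape, dtype=g.dtype)
            np.add.at(out, idx, g)  # accumulates over repeated fancy indices
            return (out,)

        return Tensor._result(self.data[idx], (self,), bwd)

    def matmul(self, other: "Tensor"):
        other = self._wrap(other)
        a, b = self.data, other.data
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul requires both operands to have ndim >= 2")

        def bwd(g):
            ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
            gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return (ga, gb)

        return Tensor._result(a @ b, (self, other), bwd)

    __matmul__ = matmul

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# free functions


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._result(data, tuple(tensors), bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, NHWC layout, square stride/padding (im2col + GEMM).

    Weights keep the conventional (out, in, kh, kw) shape; internally the
    patch matrix is laid out (kh, kw, C) so gathers copy contiguous channel
    runs and the GEMM emits a contiguous NHWC output with no transpose.
    """
    B, H, W, C = x.shape
    O, Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    s, p = stride, padding
    if p:
        xp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=x.data.dtype)
        xp[:, p : p + H, p : p + W, :] = x.data
    else:
        xp = x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    patchify = s == kh == kw and p == 0 and H % s == 0 and W % s == 0
    if patchify:
        # non-overlapping windows: pure reshape/transpose, cheap gather
        cols = np.ascontiguousarray(
            xp.reshape(B, Ho, kh, Wo, kw, C).transpose(0, 1, 3, 2, 4, 5)
        ).reshape(B * Ho * Wo, kh * kw * C)
    else:
        # (B, Ho, Wo, C, kh, kw) view -> (B, Ho, Wo, kh, kw, C) -> patch matrix
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            B * Ho * Wo, kh * kw * C
        )
    wmat = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0)).reshape(kh * kw * C, O)
    out = cols @ wmat
    if b is not None:
        out += b.data
    out = out.reshape(B, Ho, Wo, O)

    def bwd(g):
        gmat = g.reshape(B * Ho * Wo, O)
        gw = (cols.T @ gmat).reshape(kh, kw, C, O).transpose(3, 2, 0, 1)
        gb = None if b is None else gmat.sum(axis=0)
        gx = None
        if x.requires_grad:
            dcols = (gmat @ wmat.T).reshape(B, Ho, Wo, kh, kw, C)
            if patchify:
                gx = np.ascontiguousarray(
                    dcols.transpose(0, 1, 3, 2, 4, 5)
                ).reshape(B, H, W, C)
            else:
                dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=g.dtype)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, i : i + s * Ho : s, j : j + s * Wo : s, :] += dcols[
                            :, :, :, i, j, :
                        ]
                gx = dxp[:, p : p + H, p : p + W, :] if p else dxp
        grads = (gx, gw) if b is None else (gx, gw, gb)
        return grads

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(out, parents, bwd)


def maxpool2d(x: Tensor, kernel: int = 2, stride: int = 2, padding: int = 0) -> Tensor:
    """Max pooling, NHWC layout."""
    B, H, W, C = x.shape
    k, s, p = kernel, stride, padding
    xp = (
        np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0)), constant_values=-np.inf)
        if p
        else x.data
    )
    Ho = (xp.shape[1] - k) // s + 1
    Wo = (xp.shape[2] - k) // s + 1
    win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
    # (B, Ho, Wo, C, k, k) -> max over the window
    flat = win.reshape(B, Ho, Wo, C, k * k)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        dxp = np.zeros_like(xp, dtype=g.dtype)
        di, dj = np.unravel_index(arg, (k, k))
        bi, oi, oj, ci = np.indices(arg.shape, sparse=False)
        np.add.at(dxp, (bi, oi * s + di, oj * s + dj, ci), g)
        return (dxp[:, p : p + H, p : p + W, :] if p else dxp,)

    return Tensor._result(np.ascontiguousarray(out), (x,), bwd)


def batchnorm(
    x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Train-mode batch normalisation per channel over (B, H, W), NHWC.

    Returns the normalised tensor plus the batch mean/variance so the caller
    can maintain running statistics.
    """
    axes = (0, 1, 2)
    n = int(np.prod([x.data.shape[a] for a in axes]))
    s1 = x.data.sum(axis=axes, dtype=np.float64)
    s2 = np.einsum("bhwc,bhwc->c", x.data, x.data, dtype=np.float64)
    mu = (s1 / n).astype(x.dtype)
    var = np.maximum(s2 / n - (s1 / n) ** 2, 0.0).astype(x.dtype)
    invstd = (1.0 / np.sqrt(var + eps)).astype(x.dtype)
    xhat = x.data * invstd
    xhat -= mu * invstd
    out = xhat * gamma.data
    out += beta.data

    def bwd(g):
        ggamma = np.einsum("bhwc,bhwc->c", g, xhat)
        gbeta = g.sum(axis=axes)
        gx = None
        if x.requires_grad:
            dxhat = g * gamma.data
            t1 = dxhat.sum(axis=axes)
            t2 = np.einsum("bhwc,bhwc->c", dxhat, xhat)
            gx = (invstd / n) * (n * dxhat - t1 - xhat * t2)
        return (gx, ggamma, gbeta)

    return Tensor._result(out, (x, gamma, beta), bwd), mu, var


def batchnorm_eval(
    x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray, var: np.ndarray, eps: float = 1e-5
) -> Tensor:
    invstd = 1.0 / np.sqrt(var + eps)
    scale = (gamma.data * invstd).astype(x.dtype)
    shift = (beta.data - mean * gamma.data * invstd).astype(x.dtype)
    out = x.data * scale + shift

    def bwd(g):
        gx = g * scale if x.requires_grad else None
        ggamma = np.einsum("bhwc,bhwc->c", g, (x.data - mean) * invstd)
        gbeta = g.sum(axis=(0, 1, 2))
        return (gx, ggamma, gbeta)

    return Tensor._result(out, (x, gamma, beta), bwd)


def layernorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * invstd
    out = gamma.data * xhat + beta.data
    n = x.shape[-1]

    def bwd(g):
        red = tuple(range(g.ndim - 1))
        ggamma = (g * xhat).sum(axis=red)
        gbeta = g.sum(axis=red)
        gx = None
        if x.requires_grad:
            dxhat = g * gamma.data
            t1 = dxhat.sum(axis=-1, keepdims=True)
            t2 = (dxhat * xhat).sum(axis=-1, keepdims=True)
            gx = (invstd / n) * (n * dxhat - t1 - xhat * t2)
        return (gx, ggamma, gbeta)

    return Tensor._result(out, (x, gamma, beta), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        return (y * (g - (g * y).sum(axis=axis, keepdims=True)),)

    return Tensor._result(y, (x,), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if p <= 0:
        return x
    keep = (rng.random(x.shape) >= p).astype(x.dtype)
    scale = 1.0 / (1.0 - p)
    return Tensor._result(
        x.data * keep * scale, (x,), lambda g: (g * keep * scale,)
    )
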