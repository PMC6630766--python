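"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for every operation, a
closure that propagates the upstream gradient to the operation's inputs.
``Tensor.backward`` walks the recorded graph in reverse topological order.
Only the operations needed by the segmentation network are provided:
2-D convolution (im2col), batch normalisation, ReLU/sigmoid, broadcast
add/multiply, channel concatenation, separable bilinear resizing, global
average pooling, and the soft Dice loss.

Gradients are accumulated into ``Tensor.grad`` as plain arrays; there is no
higher-order differentiation. A module-level switch (:func:`no_grad`)
disables graph construction for inference so intermediate buffers are freed
eagerly.
"""

from __future__ import annotations

import contextlib
import math
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

_grad_enabled: bool = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # -- convenience -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    def accumulate_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            grad = np.ones_like(self.data)
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.accumulate_grad(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` over axes that were broadcast to reach ``g.shape``."""
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g: np.ndarray) -> None:
        a.accumulate_grad(_unbroadcast(g, a.data.shape))
        b.accumulate_grad(_unbroadcast(g, b.data.shape))

    return _make(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def backward(g: np.ndarray) -> None:
        a.accumulate_grad(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate_grad(_unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g: np.ndarray) -> None:
        x.accumulate_grad(g * mask)

    return _make(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    s = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(x.data))),
                 np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))

    def backward(g: np.ndarray) -> None:
        x.accumulate_grad(g * s * (1.0 - s))

    return _make(s, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.accumulate_grad(g[tuple(idx)])

    return _make(out, tuple(tensors), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C, 1, 1) mean over the spatial axes."""
    n_px = x.data.shape[2] * x.data.shape[3]
    out = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g: np.ndarray) -> None:
        x.accumulate_grad(np.broadcast_to(g / n_px, x.data.shape).copy())

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
    return cols.reshape(n, c * k * k, ho * wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int | None = None) -> Tensor:
    """NCHW convolution (cross-correlation) with square kernels.

    ``padding`` defaults to ``k // 2`` which preserves the spatial side for
    stride 1 and halves an even side exactly for stride 2 (odd kernels).
    """
    co, ci, k, k2 = w.data.shape
    if k != k2:
        raise ValueError("square kernels only")
    if x.data.shape[1] != ci:
        raise ValueError(f"expected {ci} input channels, got {x.data.shape[1]}")
    pad = k // 2 if padding is None else padding
    stride = int(stride)
    n, _, h, wd = x.data.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (wd + 2 * pad - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols = _im2col(xp, k, stride, ho, wo)              # (N, Ci*k*k, Ho*Wo)
    wm = w.data.reshape(co, ci * k * k)
    out = np.matmul(wm, cols).reshape(n, co, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1)

    def backward(g: np.ndarray) -> None:
        g2 = g.reshape(n, co, ho * wo)
        w.accumulate_grad(np.einsum("nof,nkf->ok", g2, cols,
                                    optimize=True).reshape(w.data.shape))
        if b is not None:
            b.accumulate_grad(g.sum(axis=(0, 2, 3)))
        gcols = np.matmul(wm.T, g2).reshape(n, ci, k, k, ho, wo)
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += gcols[:, :, i, j]
        gx = gxp[:, :, pad:pad + h, pad:pad + wd] if pad else gxp
        x.accumulate_grad(gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    In training mode, batch statistics are used and the running buffers are
    updated in place with exponential moving averages.
    """
    c = x.data.shape[1]
    g4 = gamma.data.reshape(1, c, 1, 1)
    b4 = beta.data.reshape(1, c, 1, 1)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n_el = x.data.size // c
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        # unbiased variance in the running buffer, as is conventional
        running_var += momentum * var * (n_el / max(n_el - 1, 1))
    else:
        mean = running_mean
        var = running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * invstd.reshape(1, c, 1, 1)
    out = xhat * g4 + b4

    def backward(g: np.ndarray) -> None:
        gamma.accumulate_grad((g * xhat).sum(axis=(0, 2, 3)))
        beta.accumulate_grad(g.sum(axis=(0, 2, 3)))
        gxh = g * g4
        if training:
            n_el = x.data.size // c
            s1 = gxh.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (invstd.reshape(1, c, 1, 1) / n_el) * (n_el * gxh - s1 - xhat * s2)
        else:
            gx = gxh * invstd.reshape(1, c, 1, 1)
        x.accumulate_grad(gx)

    return _make(out, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# resizing
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel-center convention,
    edges clamped). Rows sum to one, so constants are reproduced exactly."""
    a = np.zeros((n_out, n_in), dtype=np.float64)
    scale = n_in / n_out
    for o in range(n_out):
        c = (o + 0.5) * scale - 0.5
        c = min(max(c, 0.0), n_in - 1.0)
        i0 = int(math.floor(c))
        i1 = min(i0 + 1, n_in - 1)
        t = c - i0
        a[o, i0] += 1.0 - t
        a[o, i1] += t
    return a


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of an (N, C, H, W) tensor.

    Implemented as two dense matrix products so the backward pass is the
    exact adjoint of the forward interpolation.
    """
    _, _, h, w = x.data.shape
    if (h, w) == (out_h, out_w):
        # identity resize: pass through (keeps the graph simple)
        def backward_id(g: np.ndarray) -> None:
            x.accumulate_grad(g)
        return _make(x.data, (x,), backward_id)
    ah = _interp_matrix(h, out_h).astype(x.data.dtype)
    aw = _interp_matrix(w, out_w).astype(x.data.dtype)
    out = np.matmul(np.matmul(ah, x.data), aw.T)

    def backward(g: np.ndarray) -> None:
        x.accumulate_grad(np.matmul(np.matmul(ah.T, g), aw))

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def soft_dice_loss(p: Tensor, target: np.ndarray, smooth_eps: float = 1e-6) -> Tensor:
    """Negative soft Dice, averaged over the batch.

    For each sample, ``-2 * sum(p*g) / (sum(p) + sum(g) + smooth_eps)``;
    the value lies in [-1, 0].
    """
    g = np.asarray(target, dtype=p.data.dtype)
    if g.shape != p.data.shape:
        raise ValueError(f"shape mismatch: {p.data.shape} vs {g.shape}")
    n = p.data.shape[0]
    pf = p.data.reshape(n, -1)
    gf = g.reshape(n, -1)
    inter = (pf * gf).sum(axis=1)
    denom = pf.sum(axis=1) + gf.sum(axis=1) + smooth_eps
    per_sample = -2.0 * inter / denom
    out = np.asarray(per_sample.mean(), dtype=p.data.dtype)

    def backward(gr: np.ndarray) -> None:
        # d/dp_i of (-2 I / D) = (-2 g_i + 2 I / D) / D
        coeff = ((-2.0 * gf + (2.0 * inter / denom)[:, None])
                 / denom[:, None]) / n
        p.accumulate_grad(np.asarray(gr) * coeff.reshape(p.data.shape))

    return _make(out, (p,), backward)
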