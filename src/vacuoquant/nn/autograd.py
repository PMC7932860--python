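"""A compact reverse-mode automatic differentiation engine on numpy arrays.

Implements exactly the operations the package's two networks need: stride-1
same-padded 2-D convolution, 2x2 max pooling, 2x nearest-neighbor upsampling,
channel concatenation, residual addition, ReLU, sigmoid, global average
pooling, dense layers, soft-dice and softmax cross-entropy losses.  All
feature tensors are laid out (N, C, H, W).

Convolutions are computed as tensordot contractions over sliding windows
(`numpy.lib.stride_tricks.sliding_window_view`), which routes the bulk of the
arithmetic through BLAS.  Downsampling is done exclusively by pooling so that
every convolution is stride 1, keeping the backward pass a plain full
correlation with the flipped kernel.

Gradients propagate through a recorded graph of parent links; ``backward``
performs an iterative topological sort so deep networks do not hit the
recursion limit.  Correctness is pinned by finite-difference gradient checks
in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "conv2d",
    "maxpool2",
    "upsample2",
    "concat_channels",
    "relu",
    "sigmoid",
    "global_avg_pool",
    "linear",
    "soft_dice_loss",
    "softmax_cross_entropy",
    "softmax",
]


class Tensor:
    """A numpy array plus gradient and a backward closure."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad", "name")

    def __init__(self, data, parents=(), requires_grad=False, name=""):
        self.data = np.asarray(data)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, seed_grad=None):
        """Backpropagate from this tensor; scalar tensors seed with 1."""
        if seed_grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar tensor")
            seed_grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(seed_grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad for t in tensors)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, same-padded 2-D convolution (cross-correlation).

    x: (N, C, H, W); w: (O, C, k, k) with odd k; b: (O,) or None.
    """
    k = w.data.shape[-1]
    p = k // 2
    xd = x.data
    if p:
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
    else:
        xp = xd
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    out = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))  # (N, H, W, O)
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        out += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    res = Tensor(out, parents=parents)
    if res.requires_grad:

        def _backward(grad):
            # grad: (N, O, H, W)
            if w.requires_grad:
                dw = np.tensordot(win, grad, axes=([0, 2, 3], [0, 2, 3]))  # (C,k,k,O)
                w._accumulate(np.ascontiguousarray(dw.transpose(3, 0, 1, 2)))
            if b is not None and b.requires_grad:
                b._accumulate(grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                if p:
                    gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p)))
                else:
                    gp = grad
                gwin = sliding_window_view(gp, (k, k), axis=(2, 3))  # (N,O,H,W,k,k)
                wf = w.data[:, :, ::-1, ::-1]  # (O, C, k, k)
                dx = np.tensordot(gwin, wf, axes=([1, 4, 5], [0, 2, 3]))  # (N,H,W,C)
                x._accumulate(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))

        res._backward = _backward
    return res


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling; spatial dimensions must be even. Ties split the gradient."""
    n, c, h, w = x.data.shape
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = r.max(axis=(3, 5))
    res = Tensor(out, parents=(x,))
    if res.requires_grad:

        def _backward(grad):
            mask = r == out[:, :, :, None, :, None]
            counts = mask.sum(axis=(3, 5), keepdims=True)
            g = mask * (grad[:, :, :, None, :, None] / counts)
            x._accumulate(g.reshape(n, c, h, w))

        res._backward = _backward
    return res


def upsample2(x: Tensor) -> Tensor:
    """2x nearest-neighbor upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    res = Tensor(out, parents=(x,))
    if res.requires_grad:
        n, c, h, w = x.data.shape

        def _backward(grad):
            x._accumulate(grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        res._backward = _backward
    return res


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    out = np.concatenate([a.data, b.data], axis=1)
    res = Tensor(out, parents=(a, b))
    if res.requires_grad:
        split = a.data.shape[1]

        def _backward(grad):
            if a.requires_grad:
                a._accumulate(grad[:, :split])
            if b.requires_grad:
                b._accumulate(grad[:, split:])

        res._backward = _backward
    return res


def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise addition of same-shape tensors (residual connections)."""
    res = Tensor(a.data + b.data, parents=(a, b))
    if res.requires_grad:

        def _backward(grad):
            if a.requires_grad:
                a._accumulate(grad)
            if b.requires_grad:
                b._accumulate(grad)

        res._backward = _backward
    return res


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)
    res = Tensor(out, parents=(x,))
    if res.requires_grad:

        def _backward(grad):
            x._accumulate(grad * (x.data > 0))

        res._backward = _backward
    return res


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    res = Tensor(out, parents=(x,))
    if res.requires_grad:

        def _backward(grad):
            x._accumulate(grad * out * (1.0 - out))

        res._backward = _backward
    return res


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    n, c, h, w = x.data.shape
    res = Tensor(x.data.mean(axis=(2, 3)), parents=(x,))
    if res.requires_grad:

        def _backward(grad):
            x._accumulate(
                np.broadcast_to(grad[:, :, None, None] / (h * w), (n, c, h, w)).copy()
            )

        res._backward = _backward
    return res


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Dense layer: x (N, F) @ w (F, O) + b (O,)."""
    res = Tensor(x.data @ w.data + b.data, parents=(x, w, b))
    if res.requires_grad:

        def _backward(grad):
            if w.requires_grad:
                w._accumulate(x.data.T @ grad)
            if b.requires_grad:
                b._accumulate(grad.sum(axis=0))
            if x.requires_grad:
                x._accumulate(grad @ w.data.T)

        res._backward = _backward
    return res


def soft_dice_loss(probs: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 − soft dice between predicted probabilities and a binary target.

    Computed over the whole batch jointly; directly optimizes the evaluation
    metric for segmentation.
    """
    t = np.asarray(target, dtype=probs.data.dtype)
    p = probs.data
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    value = 1.0 - (2.0 * inter + eps) / (denom + eps)
    res = Tensor(np.asarray(value, dtype=p.dtype), parents=(probs,))
    if res.requires_grad:

        def _backward(grad):
            s = denom + eps
            d = -(2.0 * t * s - (2.0 * inter + eps)) / (s * s)
            probs._accumulate(d * grad)

        res._backward = _backward
    return res


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis (plain numpy helper)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of a softmax over logits (N, K) vs integer labels (N,)."""
    labels = np.asarray(labels, dtype=np.int64)
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    eps = 1e-12
    value = -np.log(probs[np.arange(n), labels] + eps).mean()
    res = Tensor(np.asarray(value, dtype=logits.data.dtype), parents=(logits,))
    if res.requires_grad:

        def _backward(grad):
            g = probs.copy()
            g[np.arange(n), labels] -= 1.0
            logits._accumulate((g / n).astype(logits.data.dtype) * grad)

        res._backward = _backward
    return res
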