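"""Parameterized layers and the Adam optimizer for the CNN engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, linear

__all__ = ["Conv", "Dense", "BatchNorm", "Module", "Adam"]


class Module:
    """Minimal parameter container; subclasses populate ``self._all`` layers."""

    _all: list = []

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self._all:
            params.extend(layer.parameters())
        return params

    def buffers(self) -> list[np.ndarray]:
        bufs: list[np.ndarray] = []
        for layer in self._all:
            bufs.extend(getattr(layer, "buffers", list)())
        return bufs

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()] + self.buffers()

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        buffers = self.buffers()
        if len(arrays) != len(params) + len(buffers):
            raise ValueError(
                f"expected {len(params) + len(buffers)} arrays, got {len(arrays)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)
        for buf, a in zip(buffers, arrays[len(params):]):
            if buf.shape != a.shape:
                raise ValueError(f"buffer shape mismatch: {buf.shape} vs {a.shape}")
            buf[...] = a


class Conv:
    """3x3 (or 1x1) same-padded convolution with He-normal initialization."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3,
                 dtype=np.float32):
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)).astype(dtype),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]


class Dense:
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / in_f)
        self.w = Tensor(rng.normal(0.0, std, size=(in_f, out_f)).astype(dtype), requires_grad=True)
        self.b = Tensor(np.zeros(out_f, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.w, self.b)

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]


class BatchNorm:
    """Per-channel batch normalization over (N, H, W) with running statistics.

    Training mode normalizes by the batch moments and updates exponential
    running averages; evaluation mode normalizes by the stored averages, so
    inference on a single image is deterministic and batch-independent.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 gamma_init: float = 1.0, dtype=np.float32):
        self.gamma = Tensor(np.full(channels, gamma_init, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        axes = (0, 2, 3)
        if train:
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.data.dtype)
        mean = mean.astype(x.data.dtype)
        xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        res = Tensor(out, parents=(x, self.gamma, self.beta))
        if res.requires_grad:
            gamma, beta = self.gamma, self.beta
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

            def _backward(grad):
                if gamma.requires_grad:
                    gamma._accumulate((grad * xhat).sum(axis=axes))
                if beta.requires_grad:
                    beta._accumulate(grad.sum(axis=axes))
                if x.requires_grad:
                    if train:
                        g_mean = grad.mean(axis=axes)
                        gx_mean = (grad * xhat).mean(axis=axes)
                        dx = (
                            gamma.data[None, :, None, None]
                            * inv_std[None, :, None, None]
                            * (
                                grad
                                - g_mean[None, :, None, None]
                                - xhat * gx_mean[None, :, None, None]
                            )
                        )
                    else:
                        dx = (
                            gamma.data[None, :, None, None]
                            * inv_std[None, :, None, None]
                            * grad
                        )
                    x._accumulate(dx.astype(x.data.dtype))

            res._backward = _backward
        return res

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]


class Adam:
    """Adam with bias correction; state kept per parameter tensor."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = np.asarray(p.grad, dtype=np.float64)
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            update = self.lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)
            p.data = (p.data - update).astype(p.data.dtype)
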