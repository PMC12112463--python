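"""Minimal NumPy neural-network layers with explicit backward passes.

This is the compute core the detection blocks are built on: 2-D convolution
(stride / padding / dilation / groups), max and average pooling, batch
normalization, ReLU and sigmoid, each implemented as a small stateful layer
exposing ``forward`` and ``backward``. Convolutions use im2col patch
extraction (one slice copy per kernel tap) feeding a single BLAS matmul, and
the backward pass mirrors it with col2im slice accumulation, so everything
stays vectorized at desk scale.

Conventions follow the common deep-learning layout: feature maps are rank-4
floating arrays (batch, channels, height, width) — layers preserve the
caller's dtype, so float32 halves memory traffic when double precision is
not needed; convolution weights are
(out_channels, in_channels/groups, kh, kw); "convolution" means
cross-correlation, as in every mainstream framework.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "Param",
    "conv2d",
    "Conv2d",
    "BatchNorm2d",
    "MaxPool2d",
    "AvgPool2d",
    "ReLU",
    "SGD",
    "sigmoid",
    "bce_with_logits",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(float)
        self.data = data
        self.grad = np.zeros_like(self.data)

    def astype(self, dtype) -> "Param":
        self.data = self.data.astype(dtype)
        self.grad = self.grad.astype(dtype)
        return self

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _conv_out_size(n: int, k: int, stride: int, padding: int, dilation: int) -> int:
    eff = dilation * (k - 1) + 1
    return (n + 2 * padding - eff) // stride + 1


def _im2col(
    x: np.ndarray, kh: int, kw: int, stride: int, padding: int, dilation: int
) -> Tuple[np.ndarray, Tuple[int, int]]:
    b, c, h, w = x.shape
    ho = _conv_out_size(h, kh, stride, padding, dilation)
    wo = _conv_out_size(w, kw, stride, padding, dilation)
    if ho < 1 or wo < 1:
        raise ValueError(f"input {h}x{w} too small for kernel {kh}x{kw} (dilation {dilation})")
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = np.empty((b, c, kh, kw, ho, wo), dtype=x.dtype)
    for u in range(kh):
        for v in range(kw):
            cols[:, :, u, v] = xp[
                :,
                :,
                u * dilation : u * dilation + (ho - 1) * stride + 1 : stride,
                v * dilation : v * dilation + (wo - 1) * stride + 1 : stride,
            ]
    return cols, (ho, wo)


def _col2im(
    dcols: np.ndarray,
    x_shape: Tuple[int, int, int, int],
    stride: int,
    padding: int,
    dilation: int,
) -> np.ndarray:
    b, c, h, w = x_shape
    _, _, kh, kw, ho, wo = dcols.shape
    dxp = np.zeros((b, c, h + 2 * padding, w + 2 * padding), dtype=dcols.dtype)
    for u in range(kh):
        for v in range(kw):
            dxp[
                :,
                :,
                u * dilation : u * dilation + (ho - 1) * stride + 1 : stride,
                v * dilation : v * dilation + (wo - 1) * stride + 1 : stride,
            ] += dcols[:, :, u, v]
    if padding:
        return dxp[:, :, padding:-padding, padding:-padding]
    return dxp


def conv2d(
    x: np.ndarray,
    weight: np.ndarray,
    bias: Optional[np.ndarray] = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
) -> np.ndarray:
    """Stateless 2-D cross-correlation (the forward path of :class:`Conv2d`)."""
    y, _ = _conv2d_forward(x, weight, bias, stride, padding, dilation, groups)
    return y


def _conv2d_forward(x, weight, bias, stride, padding, dilation, groups):
    b, c, _, _ = x.shape
    o, cg, kh, kw = weight.shape
    if c != cg * groups:
        raise ValueError(f"channel mismatch: input has {c}, weight expects {cg * groups}")
    if o % groups:
        raise ValueError("out_channels must be divisible by groups")
    cols, (ho, wo) = _im2col(x, kh, kw, stride, padding, dilation)
    # (b, g, cg, kh, kw, ho, wo) -> (g, cg*kh*kw, b*ho*wo)
    cols_g = cols.reshape(b, groups, cg, kh, kw, ho, wo)
    mat = cols_g.transpose(1, 2, 3, 4, 0, 5, 6).reshape(groups, cg * kh * kw, b * ho * wo)
    wmat = weight.reshape(groups, o // groups, cg * kh * kw)
    out = np.matmul(wmat, mat)  # (g, o/g, b*ho*wo)
    y = out.reshape(groups, o // groups, b, ho, wo).transpose(2, 0, 1, 3, 4).reshape(b, o, ho, wo)
    if bias is not None:
        y = y + bias.reshape(1, o, 1, 1)
    cache = (x.shape, mat, wmat, (b, ho, wo), (kh, kw), stride, padding, dilation, groups, cg, o)
    return y, cache


def _conv2d_backward(dy, cache):
    x_shape, mat, wmat, (b, ho, wo), (kh, kw), stride, padding, dilation, groups, cg, o = cache
    dy_g = (
        dy.reshape(b, groups, o // groups, ho, wo)
        .transpose(1, 2, 0, 3, 4)
        .reshape(groups, o // groups, b * ho * wo)
    )
    dw = np.matmul(dy_g, mat.transpose(0, 2, 1)).reshape(o, cg, kh, kw)
    db = dy.sum(axis=(0, 2, 3))
    dmat = np.matmul(wmat.transpose(0, 2, 1), dy_g)  # (g, cg*kh*kw, b*ho*wo)
    dcols = (
        dmat.reshape(groups, cg, kh, kw, b, ho, wo)
        .transpose(4, 0, 1, 2, 3, 5, 6)
        .reshape(b, groups * cg, kh, kw, ho, wo)
    )
    dx = _col2im(dcols, x_shape, stride, padding, dilation)
    return dx, dw, db


class Conv2d:
    """2-D convolution layer with He-normal initialization."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        rng = rng or np.random.default_rng()
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Param(
            rng.normal(0.0, scale, (out_channels, in_channels // groups, kernel_size, kernel_size))
        )
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, self._cache = _conv2d_forward(
            x,
            self.weight.data,
            self.bias.data if self.bias is not None else None,
            self.stride,
            self.padding,
            self.dilation,
            self.groups,
        )
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx, dw, db = _conv2d_backward(dy, self._cache)
        self.weight.grad += dw
        if self.bias is not None:
            self.bias.grad += db
        return dx

    def params(self) -> List[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def forward(self, x: np.ndarray, mode: str = "batch_stats") -> np.ndarray:
        if mode == "batch_stats":
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        elif mode == "running_stats":
            mean, var = self.running_mean, self.running_var
        else:
            raise ValueError(f"unknown BN mode {mode!r}")
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, mode)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, mode = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if mode == "running_stats":
            return dy * g * inv[None, :, None, None]
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        return (
            inv[None, :, None, None]
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        )

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]


class MaxPool2d:
    """Max pooling; padding uses -inf so it never wins the max."""

    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        self.k, self.stride, self.padding = kernel_size, stride, padding
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.padding
        b, c, h, w = x.shape
        ho = _conv_out_size(h, k, s, p, 1)
        wo = _conv_out_size(w, k, s, p, 1)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        taps = np.stack(
            [
                xp[:, :, u : u + (ho - 1) * s + 1 : s, v : v + (wo - 1) * s + 1 : s]
                for u in range(k)
                for v in range(k)
            ],
            axis=-1,
        )
        idx = taps.argmax(axis=-1)
        self._cache = (x.shape, idx, (ho, wo))
        return np.take_along_axis(taps, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.padding
        x_shape, idx, (ho, wo) = self._cache
        b, c, h, w = x_shape
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for t in range(k * k):
            u, v = divmod(t, k)
            mask = idx == t
            dxp[:, :, u : u + (ho - 1) * s + 1 : s, v : v + (wo - 1) * s + 1 : s] += dy * mask
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp

    def params(self) -> List[Param]:
        return []


class AvgPool2d:
    """Average pooling (no padding)."""

    def __init__(self, kernel_size: int, stride: int):
        self.k, self.stride = kernel_size, stride
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        b, c, h, w = x.shape
        ho = _conv_out_size(h, k, s, 0, 1)
        wo = _conv_out_size(w, k, s, 0, 1)
        y = np.zeros((b, c, ho, wo), dtype=x.dtype)
        for u in range(k):
            for v in range(k):
                y += x[:, :, u : u + (ho - 1) * s + 1 : s, v : v + (wo - 1) * s + 1 : s]
        self._cache = (x.shape, (ho, wo))
        return y / (k * k)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        x_shape, (ho, wo) = self._cache
        dx = np.zeros(x_shape, dtype=dy.dtype)
        share = dy / (k * k)
        for u in range(k):
            for v in range(k):
                dx[:, :, u : u + (ho - 1) * s + 1 : s, v : v + (wo - 1) * s + 1 : s] += share
        return dx

    def params(self) -> List[Param]:
        return []


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self) -> List[Param]:
        return []


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, pos_weight: float = 1.0
) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits).

    ``pos_weight`` multiplies the positive-target term, the usual correction
    when positives are rare (e.g. objectness maps in detection).
    """
    p = sigmoid(logits)
    # numerically stable: softplus(x) = max(x,0) + log(1+exp(-|x|))
    softplus_x = np.maximum(logits, 0) + np.log1p(np.exp(-np.abs(logits)))
    loss = pos_weight * targets * (softplus_x - logits) + (1.0 - targets) * softplus_x
    n = logits.size
    grad = (pos_weight * targets * (p - 1.0) + (1.0 - targets) * p) / n
    return float(loss.mean()), grad


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: List[Param], lr: float = 0.01, momentum: float = 0.937):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v
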