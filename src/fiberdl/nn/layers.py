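"""Minimal CPU neural-network layers with explicit backpropagation.

Everything the restoration networks need — strided convolutions (im2col),
nearest-neighbour upsampling, instance normalisation, the usual pointwise
nonlinearities and dropout — implemented directly on NumPy arrays in NCHW
layout.  Each layer exposes ``forward(x, train)`` / ``backward(grad)`` and
lists its parameters as :class:`Param` objects so an optimiser can update
them in place.  Initialisation is fully determined by the generator passed
to the constructor, which is what makes whole-network checksums repeatable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "Upsample2x",
    "InstanceNorm",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Dropout",
    "Sequential",
]


class Param:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (C*k*k, N*oh*ow) patch matrix for a single GEMM."""
    N, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (H + 2 * pad - k) // stride + 1
    ow = (W + 2 * pad - k) // stride + 1
    cols = np.empty((C, k, k, N, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = x[
                :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
            ].transpose(1, 0, 2, 3)
    return cols.reshape(C * k * k, N * oh * ow)


def _col2im(
    cols: np.ndarray, x_shape: tuple[int, ...], k: int, stride: int, pad: int,
    out_hw: tuple[int, int],
) -> np.ndarray:
    """Scatter-add adjoint of :func:`_im2col`."""
    N, C, H, W = x_shape
    oh, ow = out_hw
    view = cols.reshape(C, k, k, N, oh, ow)
    xp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += view[
                :, i, j
            ].transpose(1, 0, 2, 3)
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with bias, im2col + GEMM."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
        init_std: float = 0.02,
        dtype: np.dtype = np.float64,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        w = rng.normal(0.0, init_std, size=(out_ch, in_ch, k, k)).astype(dtype)
        self.W = Param(w, "conv.W")
        self.b = Param(np.zeros(out_ch, dtype=dtype), "conv.b")
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        oh = (H + 2 * p - k) // s + 1
        ow = (W + 2 * p - k) // s + 1
        cols = _im2col(x, k, s, p)
        Wm = self.W.data.reshape(self.out_ch, C * k * k)
        out = (Wm @ cols).reshape(self.out_ch, N, oh, ow).transpose(1, 0, 2, 3)
        out = out + self.b.data[None, :, None, None]
        if train:
            self._cache = (x.shape, cols, (oh, ow))
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols, out_hw = self._cache  # type: ignore[misc]
        N = x_shape[0]
        oh, ow = out_hw
        g2 = np.ascontiguousarray(grad.transpose(1, 0, 2, 3)).reshape(
            self.out_ch, N * oh * ow
        )
        self.W.grad += (g2 @ cols.T).reshape(self.W.data.shape)
        self.b.grad += g2.sum(axis=1)
        Wm = self.W.data.reshape(self.out_ch, -1)
        dcols = Wm.T @ g2
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, out_hw)

    def params(self) -> list[Param]:
        return [self.W, self.b]


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return (
            grad[:, :, 0::2, 0::2]
            + grad[:, :, 1::2, 0::2]
            + grad[:, :, 0::2, 1::2]
            + grad[:, :, 1::2, 1::2]
        )


class InstanceNorm(Layer):
    """Per-sample, per-channel normalisation with learnable affine terms."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype: np.dtype = np.float64):
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype), "in.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "in.beta")
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache  # type: ignore[misc]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        m = xhat.shape[2] * xhat.shape[3]
        return (
            inv / m * (m * g - g.sum(axis=(2, 3), keepdims=True)
                       - xhat * (g * xhat).sum(axis=(2, 3), keepdims=True))
        )

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        self.alpha = alpha
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.alpha * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.alpha * grad)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(alpha=0.0)


class Tanh(Layer):
    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.tanh(x)
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (1.0 - self._out**2)


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class Dropout(Layer):
    """Inverted dropout; the stochastic 'z' input of the generator.

    Active only when ``train`` is True *and* the layer's generator is set;
    inference is deterministic (the mask is skipped, activations unscaled).
    """

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        self._mask = mask
        return x * mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out
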