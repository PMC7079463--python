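"""Trainable layers with explicit forward/backward passes.

Every layer caches what its backward pass needs on ``self``; a training step
is therefore forward -> loss -> backward -> optimizer.step, one batch at a
time, exactly as the training loop drives it.  Arrays are NCHW float64.
"""

from __future__ import annotations

import numpy as np

from . import functional as F


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, train: bool = True):
        return self.forward(x, train=train)


class Conv2d(Layer):
    def __init__(self, in_channels, out_channels, kernel, stride=1, pad=0, *, rng):
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.w = Param(rng.normal(0.0, scale, (out_channels, in_channels, kernel, kernel)))
        self.b = Param(np.zeros(out_channels))
        self.stride, self.pad = stride, pad

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x_shape = x.shape
        y, cols = F.conv_forward(x, self.w.value, self.b.value, self.stride, self.pad)
        self._cols = cols if train else None
        return y

    def backward(self, dy):
        self.w.grad += F.conv_backward_weight(self._cols, dy, self.w.value.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return F.conv_backward_data(dy, self.w.value, self._x_shape, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Stride-2 3x3 transpose convolution (pad 1, output padding 1): doubles H and W."""

    def __init__(self, in_channels, out_channels, kernel=3, stride=2, pad=1,
                 output_pad=1, *, rng):
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        # stored as (Cin, Cout, k, k): the kernel of the adjoint convolution
        self.w = Param(rng.normal(0.0, scale, (in_channels, out_channels, kernel, kernel)))
        self.b = Param(np.zeros(out_channels))
        self.kernel, self.stride, self.pad, self.output_pad = kernel, stride, pad, output_pad

    def params(self):
        return [self.w, self.b]

    def out_size(self, size: int) -> int:
        return (size - 1) * self.stride - 2 * self.pad + self.kernel + self.output_pad

    def forward(self, x, train=True):
        n, cin, h, w = x.shape
        ho, wo = self.out_size(h), self.out_size(w)
        cout = self.w.value.shape[1]
        y = F.conv_backward_data(x, self.w.value, (n, cout, ho, wo), self.stride, self.pad)
        y += self.b.value[None, :, None, None]
        self._x = x if train else None
        return y

    def backward(self, dy):
        dx, cols = F.conv_forward(dy, self.w.value.reshape(
            self.w.value.shape), None, self.stride, self.pad)
        # weight grad: correlate the (large) output grad with the (small) input
        self.w.grad += F.conv_backward_weight(cols, self._x, self.w.value.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return dx


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; ties resolve to the first maximum."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool needs even spatial dims, got {h}x{w}")
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        self._idx = r.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dr, self._idx[..., None], dy[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)


class UpsampleNearest2(Layer):
    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        # numerically stable piecewise form
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._y = out
        return out

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class BatchNorm2d(Layer):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        return self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        axes = (0, 2, 3)
        xhat = self._xhat
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        return (dxhat - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m) / self._std


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
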