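"""Minimal NumPy neural-network engine used by :mod:`nucleoscatter.cnn_regressor`.

Implements exactly the layer types the regression architecture needs —
3x3 same-padding convolution (+ ReLU), 2x2 max pooling (floor), batch
normalization over channels, flatten, dense, dropout — together with Adam and
mean-squared-error loss.  Everything is float32 and channels-first (NCHW, so
image rows stay contiguous during im2col); convolutions run as batched BLAS
matmuls over im2col buffers.

No autograd: each layer implements an explicit backward pass.  This keeps the
engine small, dependency-free, and fast enough on a single CPU for the dataset
sizes used here.
"""

from __future__ import annotations

import numpy as np

from . import _nn_kernels as K

F32 = np.float32


class Layer:
    """Base layer: stateless by default, no parameters."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def state(self) -> list[np.ndarray]:
        """Arrays that must be checkpointed (trainable params + BN stats)."""
        return self.params()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, 'same' zero padding, fused ReLU.

    Weights are stored as ``(c_out, c_in * 9)`` so the forward pass is one
    batched matmul against the im2col buffer ``(batch, c_in * 9, H * W)``.
    """

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 first_layer: bool = False):
        self.c_in, self.c_out = c_in, c_out
        self.first_layer = first_layer  # skip input-gradient computation
        self.w = glorot_uniform(rng, (c_out, 9 * c_in), 9 * c_in, 9 * c_out)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, h, w = x.shape
        cols = K.im2col(np.ascontiguousarray(x, dtype=F32))
        y = np.matmul(self.w, cols)  # (b, c_out, h*w)
        y += self.b[:, None]
        np.maximum(y, 0.0, out=y)
        if training:
            self._cols = cols
            self._relu_mask = y > 0
            self._in_shape = x.shape
        return y.reshape(b, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, h, w = dy.shape
        dy2 = dy.reshape(b, self.c_out, h * w) * self._relu_mask
        np.matmul(dy2, self._cols.transpose(0, 2, 1)).sum(axis=0, out=self.dw)
        self.db[...] = dy2.sum(axis=(0, 2))
        if self.first_layer:
            return np.zeros(self._in_shape, dtype=F32)
        dcols = np.matmul(self.w.T, dy2)  # (b, 9*c_in, h*w)
        return K.col2im(dcols, self.c_in, h, w)


class MaxPool2(Layer):
    """2x2 max pooling with floor semantics (trailing odd row/col dropped)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y, idx = K.pool2_forward(x)
        if training:
            self._idx = idx
            self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return K.pool2_backward(np.ascontiguousarray(dy, dtype=F32),
                                self._idx, self._in_shape)


class BatchNorm(Layer):
    """Batch normalization over the channel axis of an NCHW tensor."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    def grads(self) -> list[np.ndarray]:
        return [self.dgamma, self.dbeta]

    def state(self) -> list[np.ndarray]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = F32(self.momentum)
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + F32(self.eps))
        shape = (1, -1, 1, 1)
        x_hat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        if training:
            self._x_hat = x_hat
            self._inv_std = inv_std
        return self.gamma.reshape(shape) * x_hat + self.beta.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        shape = (1, -1, 1, 1)
        x_hat, inv_std = self._x_hat, self._inv_std
        self.dgamma[...] = (dy * x_hat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        t1 = dy * self.gamma.reshape(shape)
        dx = inv_std.reshape(shape) * (
            t1
            - t1.mean(axis=axes).reshape(shape)
            - x_hat * (t1 * x_hat).mean(axis=axes).reshape(shape)
        )
        return dx.astype(F32, copy=False)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class Dense(Layer):
    """Fully connected layer with optional fused ReLU."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 relu: bool = True):
        self.w = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.relu = relu

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = x @ self.w + self.b
        if self.relu:
            np.maximum(y, 0.0, out=y)
        if training:
            self._x = x
            self._mask = y > 0 if self.relu else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * self._mask
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return (dy @ self.w.T).astype(F32, copy=False)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float,
                 beta2: float, epsilon: float):
        self.params = params
        self.lr, self.beta1, self.beta2, self.epsilon = lr, beta1, beta2, epsilon
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1.0 - b1) * g
            v[...] = b2 * v + (1.0 - b2) * g * g
            p -= F32(lr_t) * m / (np.sqrt(v) + F32(self.epsilon))


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred.astype(np.float64) - target) ** 2))
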