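"""Minimal numpy neural-network engine for 1D spectral convolution.

Implements exactly the layer vocabulary the classifier needs — 1D
convolution (same padding, stride 1), batch normalisation, ReLU/Swish,
3-wide max pooling, dropout, dense layers and channel concatenation — with
hand-written backpropagation.  Arrays are channels-last: ``(batch, length,
channels)`` for convolutional layers, ``(batch, features)`` after
flattening.  Weight initialisation is the truncated LeCun normal
(sd = sqrt(1/fan_in), resampling beyond two standard deviations).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def stable_sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def truncated_normal(
    rng: np.random.Generator, shape: tuple[int, ...], sd: float
) -> np.ndarray:
    """Normal(0, sd) draws with values beyond 2 sd resampled."""
    x = rng.normal(0.0, sd, size=shape)
    bad = np.abs(x) > 2.0 * sd
    while bad.any():
        x[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(x) > 2.0 * sd
    return x


class Param:
    """Trainable array with an accumulated gradient.

    ``regularized`` marks kernels that enter the l2 penalty (biases and
    batch-norm scale/shift do not).
    """

    __slots__ = ("value", "grad", "regularized")

    def __init__(self, value: np.ndarray, regularized: bool = False):
        self.value = value
        self.grad = np.zeros_like(value)
        self.regularized = regularized

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, training=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


def _pad_amounts(kernel: int) -> tuple[int, int]:
    left = (kernel - 1) // 2
    return left, kernel - 1 - left


class Conv1D(Layer):
    """Same-padded, stride-1 cross-correlation along the spectral axis."""

    def __init__(self, in_channels: int, filters: int, kernel: int, rng: np.random.Generator):
        fan_in = kernel * in_channels
        self.kernel = kernel
        self.in_channels = in_channels
        self.filters = filters
        self.w = Param(
            truncated_normal(rng, (kernel * in_channels, filters), np.sqrt(1.0 / fan_in)),
            regularized=True,
        )
        self.b = Param(np.zeros(filters))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        batch, length, _ = x.shape
        left, right = _pad_amounts(self.kernel)
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        # windows: (batch, length, channels, kernel) -> (batch, length, kernel*channels)
        windows = sliding_window_view(xp, self.kernel, axis=1)
        cols = windows.transpose(0, 1, 3, 2).reshape(batch, length, -1)
        self._cols = cols
        self._in_shape = x.shape
        return cols @ self.w.value + self.b.value

    def backward(self, dy):
        batch, length, _ = self._in_shape
        cols2 = self._cols.reshape(batch * length, -1)
        dy2 = dy.reshape(batch * length, self.filters)
        self.w.grad += cols2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        dcols = (dy @ self.w.value.T).reshape(batch, length, self.kernel, self.in_channels)
        left, right = _pad_amounts(self.kernel)
        dxp = np.zeros((batch, length + left + right, self.in_channels))
        for j in range(self.kernel):
            dxp[:, j : j + length, :] += dcols[:, :, j, :]
        return dxp[:, left : left + length, :]


class MaxPool1D(Layer):
    """Same-padded, stride-1 max pooling (window 3 in the inception module)."""

    def __init__(self, size: int = 3):
        self.size = size

    def forward(self, x, training=False, rng=None):
        batch, length, channels = x.shape
        left, right = _pad_amounts(self.size)
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)), constant_values=-np.inf)
        windows = sliding_window_view(xp, self.size, axis=1)  # (B, L, C, size)
        self._arg = windows.argmax(axis=3)
        self._in_shape = x.shape
        return windows.max(axis=3)

    def backward(self, dy):
        batch, length, channels = self._in_shape
        left, right = _pad_amounts(self.size)
        dxp = np.zeros((batch, length + left + right, channels))
        for j in range(self.size):
            dxp[:, j : j + length, :] += dy * (self._arg == j)
        return dxp[:, left : left + length, :]


class BatchNorm(Layer):
    """Per-channel batch normalisation over (batch, length), applied before
    activation.  Trainable scale and shift; running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False, rng=None):
        axes = (0, 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = x.shape[0] * x.shape[1]
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        axes = (0, 1)
        dgamma = (dy * self._xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        if not self._training:
            return dy * self.gamma.value / self._std
        return (self.gamma.value / self._std) * (
            dy - dbeta / self._m - self._xhat * dgamma / self._m
        )


class Activation(Layer):
    def __init__(self, kind: str):
        if kind not in ("relu", "swish"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, training=False, rng=None):
        self._x = x
        if self.kind == "relu":
            return np.maximum(0.0, x)
        self._sig = stable_sigmoid(x)
        return x * self._sig

    def backward(self, dy):
        if self.kind == "relu":
            return dy * (self._x > 0)
        sig = self._sig
        return dy * (sig + self._x * sig * (1.0 - sig))


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1), got {p}")
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = Param(
            truncated_normal(rng, (in_dim, out_dim), np.sqrt(1.0 / in_dim)),
            regularized=True,
        )
        self.b = Param(np.zeros(out_dim))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class InceptionModule(Layer):
    """Parallel 1x1 / 1x3 / 1x5 convolutions plus a pooled-and-projected
    branch, each followed by batch norm and activation, concatenated
    channel-wise.  Same padding and unit stride keep the spectral length
    unchanged, so concatenation is always well-defined."""

    def __init__(self, in_channels: int, f1: int, f3: int, f5: int, fp: int,
                 activation: str, rng: np.random.Generator):
        self.branches: list[list[Layer]] = [
            [Conv1D(in_channels, f1, 1, rng), BatchNorm(f1), Activation(activation)],
            [Conv1D(in_channels, f3, 3, rng), BatchNorm(f3), Activation(activation)],
            [Conv1D(in_channels, f5, 5, rng), BatchNorm(f5), Activation(activation)],
            [MaxPool1D(3), Conv1D(in_channels, fp, 1, rng), BatchNorm(fp), Activation(activation)],
        ]
        self.out_channels = f1 + f3 + f5 + fp

    def params(self):
        return [p for branch in self.branches for layer in branch for p in layer.params()]

    def forward(self, x, training=False, rng=None):
        outputs = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h, training=training, rng=rng)
            outputs.append(h)
        self._splits = np.cumsum([o.shape[2] for o in outputs])[:-1]
        return np.concatenate(outputs, axis=2)

    def backward(self, dy):
        dx = None
        for branch, dpart in zip(self.branches, np.split(dy, self._splits, axis=2)):
            d = dpart
            for layer in reversed(branch):
                d = layer.backward(d)
            dx = d if dx is None else dx + d
        return dx


class Network:
    """Backbone (inception stack + dense head) plus a single-logit output
    layer.  ``forward_features`` returns the penultimate activations that
    feed the SVM head; ``forward_logits`` adds the output neuron."""

    def __init__(self, feature_layers: list[Layer], output_layer: Dense):
        self.feature_layers = feature_layers
        self.output_layer = output_layer

    def params(self) -> list[Param]:
        out = [p for layer in self.feature_layers for p in layer.params()]
        out.extend(self.output_layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def forward_features(self, x, training=False, rng=None):
        h = x
        for layer in self.feature_layers:
            h = layer.forward(h, training=training, rng=rng)
        return h

    def forward_logits(self, x, training=False, rng=None):
        h = self.forward_features(x, training=training, rng=rng)
        return self.output_layer.forward(h, training=training, rng=rng)[:, 0]

    def backward(self, dlogits):
        d = self.output_layer.backward(dlogits[:, None])
        for layer in reversed(self.feature_layers):
            d = layer.backward(d)
        return d

    def zero_grads(self):
        for p in self.params():
            p.grad[...] = 0.0
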