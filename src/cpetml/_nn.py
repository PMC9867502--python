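"""Minimal seeded neural-network layers on numpy.

Supports exactly what the CPET models need: 1-D convolution (plain and
transposed), average pooling, batch normalization, dense layers, dropout,
the usual activations, Adam, and softmax/sigmoid cross-entropy losses with
hand-written backprop.  Everything is float64 and driven by an explicit
``numpy.random.Generator``, so a fixed seed gives bitwise-identical training
runs.

Shapes: convolutional tensors are ``(batch, time, channels)``; dense tensors
are ``(batch, features)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "Conv1D", "ConvTranspose1D", "AvgPool1D", "BatchNorm",
    "Dropout", "Flatten", "Relu", "LeakyRelu", "Sigmoid", "Tanh",
    "Sequential", "Adam", "softmax", "softmax_cross_entropy",
    "sigmoid", "sigmoid_bce_with_logits", "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        b = np.zeros(n_out)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x, training=False):
        self._x = x
        W, b = self.params
        return x @ W + b

    def backward(self, dout):
        W, _ = self.params
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ W.T


def _im2col(x, k: int, stride: int):
    """(N, T, C) -> (N, T_out, k*C) patch matrix."""
    n, t, c = x.shape
    t_out = (t - k) // stride + 1
    s0, s1, s2 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, shape=(n, t_out, k, c), strides=(s0, s1 * stride, s1, s2))
    return cols.reshape(n, t_out, k * c)


class Conv1D(Layer):
    """1-D convolution over (batch, time, channels).

    padding: 'valid' or 'same' (stride 1 only for 'same').
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: str = "valid"):
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        if padding == "same" and stride != 1:
            raise ValueError("'same' padding requires stride 1")
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in, fan_out = kernel * c_in, kernel * c_out
        W = glorot_uniform(rng, (kernel, c_in, c_out), fan_in, fan_out)
        b = np.zeros(c_out)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def _pad(self, x):
        if self.padding == "same":
            lo = (self.kernel - 1) // 2
            hi = self.kernel - 1 - lo
            return np.pad(x, ((0, 0), (lo, hi), (0, 0)))
        return x

    def forward(self, x, training=False):
        W, b = self.params
        xp = self._pad(x)
        self._x_shape = x.shape
        self._cols = _im2col(xp, self.kernel, self.stride)
        k, c_in, c_out = W.shape
        out = self._cols @ W.reshape(k * c_in, c_out) + b
        return out

    def backward(self, dout):
        W, _ = self.params
        k, c_in, c_out = W.shape
        n, t_out, _ = dout.shape
        self.grads[0][...] = np.einsum(
            "ntp,ntq->pq", self._cols, dout).reshape(k, c_in, c_out)
        self.grads[1][...] = dout.sum(axis=(0, 1))
        # scatter patch gradients back onto the (padded) input
        dcols = dout @ W.reshape(k * c_in, c_out).T  # (n, t_out, k*c_in)
        dcols = dcols.reshape(n, t_out, k, c_in)
        n_, t, c = self._x_shape
        if self.padding == "same":
            lo = (self.kernel - 1) // 2
            t_pad = t + self.kernel - 1
        else:
            lo, t_pad = 0, t
        dxp = np.zeros((n, t_pad, c_in))
        for i in range(k):
            dxp[:, i:i + t_out * self.stride:self.stride, :] += dcols[:, :, i, :]
        return dxp[:, lo:lo + t, :]


class ConvTranspose1D(Layer):
    """Transposed 1-D convolution, stride 1, length-preserving.

    Forward is the adjoint of a 'same'-padded Conv1D: each input time step
    scatters its kernel across the output, which is what upsampling GAN
    decoders use to synthesise the final (time, channels) map.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        fan_in, fan_out = kernel * c_in, kernel * c_out
        W = glorot_uniform(rng, (kernel, c_in, c_out), fan_in, fan_out)
        b = np.zeros(c_out)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x, training=False):
        W, b = self.params
        k = self.kernel
        n, t, c_in = x.shape
        self._x = x
        lo = (k - 1) // 2
        out = np.zeros((n, t + k - 1, W.shape[2]))
        for i in range(k):
            out[:, i:i + t, :] += x @ W[i]
        return out[:, lo:lo + t, :] + b

    def backward(self, dout):
        W, _ = self.params
        k = self.kernel
        n, t, c_in = self._x.shape
        lo = (k - 1) // 2
        dpad = np.zeros((n, t + k - 1, W.shape[2]))
        dpad[:, lo:lo + t, :] = dout
        dx = np.zeros_like(self._x)
        for i in range(k):
            self.grads[0][i] = np.einsum(
                "ntc,ntd->cd", self._x, dpad[:, i:i + t, :])
            dx += dpad[:, i:i + t, :] @ W[i].T
        self.grads[1][...] = dout.sum(axis=(0, 1))
        return dx


class AvgPool1D(Layer):
    """Non-overlapping average pooling over time; trailing remainder dropped."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        n, t, c = x.shape
        p = self.pool
        self._t = t
        t_out = t // p
        return x[:, :t_out * p, :].reshape(n, t_out, p, c).mean(axis=2)

    def backward(self, dout):
        n, t_out, c = dout.shape
        p = self.pool
        dx = np.zeros((n, self._t, c))
        dx[:, :t_out * p, :] = np.repeat(dout / p, p, axis=1)
        return dx


class BatchNorm(Layer):
    """Batch normalization; per-channel for conv input, per-feature for dense."""

    def __init__(self, n_features: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        gamma = np.ones(n_features)
        beta = np.zeros(n_features)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        gamma, beta = self.params
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._invstd
        self._axes = axes
        self._training = training
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return gamma * self._xhat + beta

    def backward(self, dout):
        gamma, _ = self.params
        axes = self._axes
        self.grads[0][...] = (dout * self._xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        dxhat = dout * gamma
        if not self._training:
            return dxhat * self._invstd
        m = self._m
        return (self._invstd / m) * (
            m * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes, keepdims=True))


class Dropout(Layer):
    """Inverted dropout driven by the generator handed to the layer."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Relu(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyRelu(Layer):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = sigmoid(x)
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y ** 2)


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @params.setter
    def params(self, value):  # Layer.__init__ compatibility
        pass

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    @grads.setter
    def grads(self, value):
        pass

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, onehot):
    """Mean categorical cross-entropy; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.sum(onehot * np.log(p + 1e-12)) / n
    return loss, (p - onehot) / n


def sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid_bce_with_logits(logits, targets):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    n = logits.shape[0]
    loss = np.mean(np.maximum(logits, 0) - logits * targets
                   + np.log1p(np.exp(-np.abs(logits))))
    return loss, (sigmoid(logits) - targets) / n
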