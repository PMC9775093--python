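"""A compact full-batch neural-network engine on numpy.

Implements exactly the layer types the classifiers here need — dense,
graph-convolution, LeakyReLU, dropout, batch-norm, 1-D convolution and
max-pooling — each with an explicit backward pass, plus Xavier (Glorot
uniform) initialization and the Adam optimizer. Everything is
deterministic given the ``numpy.random.Generator`` used for
initialization and dropout; training is full-batch, so there is no
minibatch ordering to control.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "GraphConv",
    "LeakyReLU",
    "Dropout",
    "BatchNorm",
    "Conv1d",
    "MaxPool1d",
    "Flatten",
    "Sequential",
    "Adam",
    "xavier_uniform",
    "softmax",
    "softmax_cross_entropy",
]


def xavier_uniform(
    fan_in: int, fan_out: int, rng: np.random.Generator, shape=None
) -> np.ndarray:
    """Glorot uniform draw: U(-a, a) with a = sqrt(6 / (fan_in + fan_out))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _leaky(z: np.ndarray, slope: float) -> np.ndarray:
    # for 0 <= slope <= 1, LeakyReLU(z) == max(z, slope*z)
    return np.maximum(z, slope * z)


def _leaky_grad(z: np.ndarray, slope: float) -> np.ndarray:
    return slope + (1.0 - slope) * (z >= 0)


class Dense(Layer):
    """Affine layer y = x W + b with Xavier-initialized W."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(xavier_uniform(d_in, d_out, rng))
        self.b = Param(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class GraphConv(Layer):
    """One graph-convolution layer: LeakyReLU(A_hat @ H @ W).

    ``A_hat`` is the symmetric-normalized adjacency of the sample graph
    and must be assigned (dense or scipy sparse) before the forward
    pass; it is data, not a parameter. Neighbor aggregation is the sum
    implied by the matrix product.
    """

    def __init__(
        self, d_in: int, d_out: int, rng: np.random.Generator, slope: float = 0.25
    ):
        self.W = Param(xavier_uniform(d_in, d_out, rng))
        self.slope = slope
        self.A_hat = None
        self._ax: np.ndarray | None = None
        self._z: np.ndarray | None = None

    def params(self):
        return [self.W]

    def forward(self, x, training):
        if self.A_hat is None:
            raise ValueError("GraphConv.A_hat must be set before forward")
        if self.A_hat.shape[0] != x.shape[0]:
            raise ValueError(
                f"adjacency is {self.A_hat.shape[0]} nodes but input has "
                f"{x.shape[0]} samples"
            )
        self._ax = self.A_hat @ x
        self._z = self._ax @ self.W.value
        return _leaky(self._z, self.slope)

    def backward(self, grad):
        dz = grad * _leaky_grad(self._z, self.slope)
        self.W.grad += self._ax.T @ dz
        # A_hat is symmetric, so d/dH of (A H W) pulls back through A_hat
        return self.A_hat @ (dz @ self.W.value.T)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.25):
        self.slope = slope
        self._z: np.ndarray | None = None

    def forward(self, x, training):
        self._z = x
        return _leaky(x, self.slope)

    def backward(self, grad):
        return grad * _leaky_grad(self._z, self.slope)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class BatchNorm(Layer):
    """Per-feature batch normalization with learned scale/shift."""

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(d))
        self.beta = Param(np.zeros(d))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean) * inv_std
        self._cache = (x_hat, inv_std, training)
        return self.gamma.value * x_hat + self.beta.value

    def backward(self, grad):
        x_hat, inv_std, training = self._cache
        self.gamma.grad += (grad * x_hat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        g = grad * self.gamma.value
        if not training:
            return g * inv_std
        n = grad.shape[0]
        return (
            inv_std
            / n
            * (n * g - g.sum(axis=0) - x_hat * (g * x_hat).sum(axis=0))
        )


class Conv1d(Layer):
    """1-D convolution over the feature axis, 'same' zero padding.

    Input shape (n, C_in, L); output (n, C_out, L). Kernel weights are
    Xavier-initialized with fan_in = C_in*K, fan_out = C_out*K.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
    ):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        self.W = Param(
            xavier_uniform(c_in * kernel, c_out * kernel, rng, (c_out, c_in, kernel))
        )
        self.b = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None

    def forward(self, x, training):
        k, pad = self.kernel, self.kernel // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (n, C_in, L, K) sliding windows
        cols = np.lib.stride_tricks.sliding_window_view(xpad, k, axis=2)
        self._cols = cols
        out = np.tensordot(cols, self.W.value, axes=([1, 3], [1, 2]))
        return out.transpose(0, 2, 1) + self.b.value[None, :, None]

    def backward(self, grad):
        k, pad = self.kernel, self.kernel // 2
        g = grad.transpose(0, 2, 1)  # (n, L, C_out)
        self.W.grad += np.tensordot(g, self._cols, axes=([0, 1], [0, 2]))
        self.b.grad += grad.sum(axis=(0, 2))
        n, c_in, _, _ = self._cols.shape
        L = grad.shape[2]
        dxpad = np.zeros((n, c_in, L + 2 * pad))
        for kk in range(k):
            # grad at output l flows to input position l + kk (in padded coords)
            dxpad[:, :, kk : kk + L] += np.tensordot(
                grad, self.W.value[:, :, kk], axes=([1], [0])
            ).transpose(0, 2, 1)
        return dxpad[:, :, pad : pad + L]


class MaxPool1d(Layer):
    """Max pooling, kernel 2, stride 1, zero padding on the right.

    Output length equals input length; position l pools x[l] and x[l+1]
    (with a trailing zero pad).
    """

    def __init__(self):
        self._argmax: np.ndarray | None = None
        self._shape = None

    def forward(self, x, training):
        xpad = np.pad(x, ((0, 0), (0, 0), (0, 1)))
        stacked = np.stack([xpad[:, :, :-1], xpad[:, :, 1:]], axis=-1)
        self._argmax = stacked.argmax(axis=-1)
        self._shape = x.shape
        return stacked.max(axis=-1)

    def backward(self, grad):
        n, c, L = self._shape
        dx = np.zeros((n, c, L + 1))
        right = self._argmax  # 0 -> position l, 1 -> position l+1
        idx_l = np.arange(L)[None, None, :] + right
        np.add.at(
            dx,
            (
                np.arange(n)[:, None, None],
                np.arange(c)[None, :, None],
                idx_l,
            ),
            grad,
        )
        return dx[:, :, :L]


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[Param],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._buf = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2_sqrt = np.sqrt(1.0 - b2**self.t)
        for p, m, v, buf in zip(self.params, self._m, self._v, self._buf):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            # in-place moment updates (update = lr * m_hat / (sqrt(v_hat)+eps))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            np.sqrt(v, out=buf)
            buf /= bc2_sqrt
            buf += self.eps
            np.divide(m, buf, out=buf)
            buf *= self.lr / bc1
            p.value -= buf


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    one_hot: np.ndarray,
    sample_weight: np.ndarray | None = None,
    mask: np.ndarray | None = None,
):
    """Sum-reduced cross-entropy over (optionally masked/weighted) samples.

    Returns ``(loss, dlogits)``. ``mask`` is a boolean vector selecting
    the samples that contribute (e.g. the training partition in a
    transductive graph); ``sample_weight`` multiplies each sample's CE
    term. The reduction is a sum, matching losses defined as sums over
    samples, so gradients scale with the partition size (Adam's
    normalization makes training insensitive to this scale).
    """
    probs = softmax(logits)
    n = logits.shape[0]
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    if mask is not None:
        w = w * np.asarray(mask, bool)
    logp = np.log(np.clip(probs, 1e-12, None))
    per_sample = -(one_hot * logp).sum(axis=1)
    loss = float((w * per_sample).sum())
    dlogits = w[:, None] * (probs - one_hot)
    return loss, dlogits
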