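"""Minimal feed-forward neural-network layers with manual backpropagation.

Implemented on numpy because the detection models here are small (27x27
single-channel inputs, three convolution blocks, ~1e5 parameters) and need
nothing beyond dense/convolution/batch-norm/pooling layers with Adam.
Image tensors are NCHW.  Every layer exposes ``forward(x, train)`` /
``backward(grad)`` and its parameters; gradient correctness is enforced by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Dense", "Conv2d", "ConvTranspose2d", "BatchNorm",
    "ReLU", "MaxPool2d", "Dropout", "Flatten", "Reshape", "Sequential",
    "Adam", "softmax", "softmax_cross_entropy",
]


class Param:
    """A trainable tensor and its gradient accumulator."""

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class Conv2d(Layer):
    """3x3-style convolution with 'same'-capable zero padding and stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)))
        self.b = Param(np.zeros(c_out))
        self.k, self.s, self.p = kernel, stride, pad

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        # contiguous im2col matrix, reused by backward
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)) \
            .reshape(n * ho * wo, c * k * k)
        self._cols, self._xshape, self._oshape = cols, x.shape, (ho, wo)
        y = cols @ self.w.value.reshape(len(self.w.value), -1).T
        y = y.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        return y + self.b.value[None, :, None, None]

    def backward(self, grad):
        k, s, p = self.k, self.s, self.p
        n, c, h, w = self._xshape
        ho, wo = self._oshape
        gflat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)) \
            .reshape(n * ho * wo, -1)
        c_out = gflat.shape[1]
        self.w.grad += (gflat.T @ self._cols).reshape(c_out, c, k, k)
        self.b.grad += gflat.sum(axis=0)
        # (n, ho, wo, c, k, k) channel-last so the scatter-adds stay contiguous
        gwin = (gflat @ self.w.value.reshape(c_out, -1)) \
            .reshape(n, ho, wo, c, k, k)
        gxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for ki in range(k):
            for kj in range(k):
                gxp[:, ki:ki + ho * s:s, kj:kj + wo * s:s, :] += gwin[..., ki, kj]
        return gxp.transpose(0, 3, 1, 2)[:, :, p:p + h, p:p + w]


class ConvTranspose2d(Layer):
    """Transposed convolution (the adjoint of Conv2d with equal k/s/p)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 pad: int, output_pad: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.w = Param(rng.normal(0.0, scale, size=(c_in, c_out, kernel, kernel)))
        self.b = Param(np.zeros(c_out))
        self.k, self.s, self.p, self.op = kernel, stride, pad, output_pad

    def params(self):
        return [self.w, self.b]

    def out_size(self, n_in: int) -> int:
        return (n_in - 1) * self.s + self.k + self.op - 2 * self.p

    def forward(self, x, train=False):
        k, s, p = self.k, self.s, self.p
        n, c, h, w = x.shape
        self._x = x
        full_h = (h - 1) * s + k + self.op
        full_w = (w - 1) * s + k + self.op
        c_out = self.w.value.shape[1]
        # (n, h, w, c_out, k, k) channel-last for contiguous scatter-adds
        contrib = np.tensordot(x.transpose(0, 2, 3, 1), self.w.value,
                               axes=([3], [0]))
        ypad = np.zeros((n, full_h, full_w, c_out))
        for ki in range(k):
            for kj in range(k):
                ypad[:, ki:ki + h * s:s, kj:kj + w * s:s, :] += contrib[..., ki, kj]
        y = ypad.transpose(0, 3, 1, 2)[:, :, p:full_h - p, p:full_w - p]
        return y + self.b.value[None, :, None, None]

    def backward(self, grad):
        k, s, p = self.k, self.s, self.p
        n, c, h, w = self._x.shape
        full_h = (h - 1) * s + k + self.op
        full_w = (w - 1) * s + k + self.op
        gypad = np.zeros((n, grad.shape[1], full_h, full_w))
        gypad[:, :, p:full_h - p, p:full_w - p] = grad
        gwin = sliding_window_view(gypad, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        c_out = grad.shape[1]
        cols = np.ascontiguousarray(gwin.transpose(0, 2, 3, 1, 4, 5)) \
            .reshape(n * h * w, c_out * k * k)
        xflat = self._x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        self.w.grad += (xflat.T @ cols).reshape(c, c_out, k, k)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        gx = cols @ self.w.value.reshape(c, -1).T
        return gx.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=False):
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        self._cache = (xhat, inv, axes, sh, train, x.shape)
        return self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)

    def backward(self, grad):
        xhat, inv, axes, sh, train, xshape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value.reshape(sh)
        if not train:
            return g * inv.reshape(sh)
        m = np.prod([xshape[a] for a in axes])
        gm = g.mean(axis=axes).reshape(sh)
        gxm = (g * xhat).mean(axis=axes).reshape(sh)
        return inv.reshape(sh) * (g - gm - xhat * gxm)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling (trailing row/column dropped for odd sizes)."""

    def forward(self, x, train=False):
        h, w = x.shape[2], x.shape[3]
        h2, w2 = h // 2 * 2, w // 2 * 2
        s = [x[:, :, i:h2:2, j:w2:2] for i in range(2) for j in range(2)]
        y = np.maximum(np.maximum(s[0], s[1]), np.maximum(s[2], s[3]))
        # exclusive winner masks route the gradient to a single input cell
        masks = []
        taken = np.zeros(y.shape, dtype=bool)
        for si in s:
            m = (si == y) & ~taken
            taken |= m
            masks.append(m)
        self._masks, self._xshape = masks, x.shape
        return y

    def backward(self, grad):
        h, w = self._xshape[2], self._xshape[3]
        h2, w2 = h // 2 * 2, w // 2 * 2
        out = np.zeros(self._xshape)
        for (i, j), m in zip(((0, 0), (0, 1), (1, 0), (1, 1)), self._masks):
            out[:, :, i:h2:2, j:w2:2] += grad * m
        return out


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        rng = self.rng or np.random.default_rng(0)
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape

    def forward(self, x, train=False):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adaptive moment estimation optimizer."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        corr1 = 1.0 - self.b1**self.t
        corr2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(labels)
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def state_dict(model: Layer) -> dict[str, np.ndarray]:
    """Flat parameter snapshot (including batch-norm running stats)."""
    out = {}
    for i, p in enumerate(model.params()):
        out[f"param_{i}"] = p.value.copy()
    stack = [model]
    j = 0
    while stack:
        layer = stack.pop(0)
        if isinstance(layer, Sequential):
            stack = layer.layers + stack
        elif isinstance(layer, BatchNorm):
            out[f"bn_{j}_mean"] = layer.running_mean.copy()
            out[f"bn_{j}_var"] = layer.running_var.copy()
            j += 1
    return out


def load_state_dict(model: Layer, state: dict[str, np.ndarray]) -> None:
    for i, p in enumerate(model.params()):
        p.value[...] = state[f"param_{i}"]
    stack = [model]
    j = 0
    while stack:
        layer = stack.pop(0)
        if isinstance(layer, Sequential):
            stack = layer.layers + stack
        elif isinstance(layer, BatchNorm):
            layer.running_mean[...] = state[f"bn_{j}_mean"]
            layer.running_var[...] = state[f"bn_{j}_var"]
            j += 1
    return None
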