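"""Minimal NumPy CNN layer library with hand-written backpropagation.

Implements exactly the pieces the residual U-Net needs -- 2D convolution
(im2col over BLAS matmuls), stride-2 transposed convolution, batch
normalization, ReLU, dropout and the Adam optimizer.  Every layer exposes
``forward(x, train)`` and ``backward(grad)``; gradients are verified against
finite differences in the test suite.

Tensors are ``(N, C, H, W)`` arrays.  float32 is the default compute dtype;
float64 can be requested (e.g. for gradient checking).
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    """Kaiming-uniform fan-in initialization (gain for a leaky slope of sqrt(5)).

    With batch normalization after every convolution the forward scale is
    absorbed anyway; the smaller weight magnitude matters for optimization:
    Adam moves each parameter by roughly the learning rate per step, so
    smaller weights mean each step changes the normalized function more.
    """
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution with 'same'-style padding for odd k, stride 1 or 2."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        self.W = Param(_kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self._x_padded: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, xp: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
        k, s = self.kernel, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :out_h, :out_w]  # (N, C, Ho, Wo, k, k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(xp.shape[0] * out_h * out_w, -1)

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out_h = (h + 2 * p - k) // s + 1
        out_w = (w + 2 * p - k) // s + 1
        cols = self._im2col(xp, out_h, out_w)
        w_mat = self.W.value.reshape(self.W.value.shape[0], -1)
        out = cols @ w_mat.T + self.b.value
        self._x_padded = xp
        self._dims = (n, out_h, out_w)
        return out.reshape(n, out_h, out_w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, out_h, out_w = self._dims
        k, s, p = self.kernel, self.stride, self.pad
        xp = self._x_padded
        grad_mat = grad.transpose(0, 2, 3, 1).reshape(n * out_h * out_w, -1)
        cols = self._im2col(xp, out_h, out_w)
        self.W.grad += (grad_mat.T @ cols).reshape(self.W.value.shape)
        self.b.grad += grad_mat.sum(axis=0)
        dcols = grad_mat @ self.W.value.reshape(self.W.value.shape[0], -1)
        dcols = dcols.reshape(n, out_h, out_w, xp.shape[1], k, k)
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + s * out_h : s, dj : dj + s * out_w : s] += dcols[
                    :, :, :, :, di, dj
                ].transpose(0, 3, 1, 2)
        self._x_padded = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (doubles the spatial size)."""

    def __init__(self, in_ch, out_ch, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.W = Param(_kaiming_uniform(rng, (in_ch, out_ch, 2, 2), in_ch * 4, dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        n, c, h, w = x.shape
        y = np.einsum("ncij,coab->noiajb", x, self.W.value, optimize=True)
        y = y.reshape(n, self.W.value.shape[1], 2 * h, 2 * w)
        return y + self.b.value[None, :, None, None]

    def backward(self, grad):
        n, o, h2, w2 = grad.shape
        g6 = grad.reshape(n, o, h2 // 2, 2, w2 // 2, 2)
        self.W.grad += np.einsum("ncij,noiajb->coab", self._x, g6, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dx = np.einsum("noiajb,coab->ncij", g6, self.W.value, optimize=True)
        self._x = None
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, ch, momentum=0.9, eps=1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(ch, dtype=dtype))
        self.beta = Param(np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (x_hat, inv_std)
        return self.gamma.value[None, :, None, None] * x_hat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        x_hat, inv_std = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dgamma = (grad * x_hat).sum(axis=(0, 2, 3))
        dbeta = grad.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        dx = g * (
            grad
            - dbeta[None, :, None, None] / m
            - x_hat * dgamma[None, :, None, None] / m
        )
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        g = np.where(self._mask, grad, 0)
        self._mask = None
        return g


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=True):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-pixel, per-channel binary cross-entropy and its logit gradient.

    Numerically stable formulation; ``targets`` is the one-hot encoding of
    the 3-class label mask.
    """
    z, t = logits, targets
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - t) / z.size
    return float(loss.mean()), grad.astype(z.dtype)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-pixel softmax cross-entropy alternative (channel axis 1)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n_pix = z.shape[0] * z.shape[2] * z.shape[3]
    loss = -(targets * np.log(np.maximum(p, 1e-12))).sum(axis=1).mean()
    grad = (p - targets) / n_pix
    return float(loss), grad.astype(z.dtype)


LOSSES = {"bce": bce_with_logits, "softmax_ce": softmax_cross_entropy}


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
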