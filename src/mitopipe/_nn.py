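"""Minimal NumPy neural-network layers with hand-written backward passes.

All image tensors are NHWC float64. Layers cache what their backward pass
needs; ``forward`` must be called before ``backward``. Parameters are plain
ndarrays updated in place by :class:`Adam`, so training is bit-reproducible
given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


# ---------------------------------------------------------------------------
# functional primitives


def relu(z):
    """Elementwise max(0, z)."""
    return np.maximum(0.0, np.asarray(z, dtype=float))


def softmax(z, axis=-1):
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(z):
    return expit(np.asarray(z, dtype=float))


def conv2d_same(x, w, b=None):
    """Cross-correlation with same padding, stride 1.

    x: (N, H, W, Cin); w: (k, k, Cin, Cout); b: (Cout,) or None.
    """
    k = w.shape[0]
    if w.shape[1] != k:
        raise ValueError("kernel must be square")
    if x.shape[-1] != w.shape[2]:
        raise ValueError(
            f"input has {x.shape[-1]} channels but kernel expects {w.shape[2]}"
        )
    p = k // 2
    n, h, wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    out = np.zeros((n, h, wd, w.shape[3]))
    for di in range(k):
        for dj in range(k):
            out += xp[:, di:di + h, dj:dj + wd, :] @ w[di, dj]
    if b is not None:
        out += b
    return out


def _conv2d_same_backward(x, w, grad):
    k = w.shape[0]
    p = k // 2
    n, h, wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for di in range(k):
        for dj in range(k):
            patch = xp[:, di:di + h, dj:dj + wd, :]
            dw[di, dj] = np.tensordot(patch, grad, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, di:di + h, dj:dj + wd, :] += grad @ w[di, dj].T
    db = grad.sum(axis=(0, 1, 2))
    dx = dxp[:, p:p + h, p:p + wd, :] if p else dxp
    return dx, dw, db


# ---------------------------------------------------------------------------
# layer classes


class Layer:
    """Base: forward(x, train) -> y; backward(g) -> dx; parameters() pairs."""

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def parameters(self):
        return []


class Conv2D(Layer):
    """k x k same-padding convolution, optional fused ReLU."""

    counts_in_census = True

    def __init__(self, c_in, c_out, k=3, rng=None, activation=None, init_sd=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        sd = init_sd if init_sd is not None else np.sqrt(2.0 / (k * k * c_in))
        self.w = rng.normal(0.0, sd, size=(k, k, c_in, c_out))
        self.b = np.zeros(c_out)
        self.activation = activation
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        z = conv2d_same(x, self.w, self.b)
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * self._mask
        dx, self.dw[...], self.db[...] = _conv2d_same_backward(self._x, self.w, grad)
        return dx

    def parameters(self):
        return [(self.w, self.dw), (self.b, self.db)]


class SeparableConv2D(Layer):
    """Depthwise k x k filter per channel followed by 1x1 pointwise mixing."""

    counts_in_census = True

    def __init__(self, c_in, c_out, k=3, rng=None, activation=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.dw_kernel = rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(k, k, c_in))
        self.pw_kernel = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out))
        self.b = np.zeros(c_out)
        self.activation = activation
        self.g_dw = np.zeros_like(self.dw_kernel)
        self.g_pw = np.zeros_like(self.pw_kernel)
        self.g_b = np.zeros_like(self.b)

    @staticmethod
    def depthwise(x, kern):
        k = kern.shape[0]
        if x.shape[-1] != kern.shape[2]:
            raise ValueError(
                f"input has {x.shape[-1]} channels but depthwise kernel "
                f"expects {kern.shape[2]}"
            )
        p = k // 2
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.zeros_like(x, dtype=float)
        for di in range(k):
            for dj in range(k):
                out += xp[:, di:di + h, dj:dj + w, :] * kern[di, dj]
        return out

    def forward(self, x, train=False):
        self._x = x
        self._mid = self.depthwise(x, self.dw_kernel)
        z = self._mid @ self.pw_kernel + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * self._mask
        self.g_b[...] = grad.sum(axis=(0, 1, 2))
        self.g_pw[...] = np.tensordot(self._mid, grad, axes=([0, 1, 2], [0, 1, 2]))
        dmid = grad @ self.pw_kernel.T
        k = self.dw_kernel.shape[0]
        p = k // 2
        n, h, w, c = self._x.shape
        xp = np.pad(self._x, ((0, 0), (p, p), (p, p), (0, 0)))
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                patch = xp[:, di:di + h, dj:dj + w, :]
                self.g_dw[di, dj] = (patch * dmid).sum(axis=(0, 1, 2))
                dxp[:, di:di + h, dj:dj + w, :] += dmid * self.dw_kernel[di, dj]
        return dxp[:, p:p + h, p:p + w, :]

    def parameters(self):
        return [(self.dw_kernel, self.g_dw), (self.pw_kernel, self.g_pw),
                (self.b, self.g_b)]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Ties share gradient equally."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 needs even spatial dims")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        mask = xr == y[:, :, None, :, None, :]
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        self._shape = x.shape
        return y

    def backward(self, grad):
        g = grad[:, :, None, :, None, :] * self._mask
        return g.reshape(self._shape)


class ConvTranspose2(Layer):
    """2x2 stride-2 transposed convolution (doubles H and W)."""

    counts_in_census = False

    def __init__(self, c_in, c_out, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(2, 2, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        n, h, w, _ = x.shape
        out = np.zeros((n, 2 * h, 2 * w, self.w.shape[3]))
        for di in range(2):
            for dj in range(2):
                out[:, di::2, dj::2, :] = x @ self.w[di, dj]
        return out + self.b

    def backward(self, grad):
        self.db[...] = grad.sum(axis=(0, 1, 2))
        dx = np.zeros_like(self._x)
        for di in range(2):
            for dj in range(2):
                g = grad[:, di::2, dj::2, :]
                self.dw[di, dj] = np.tensordot(self._x, g, axes=([0, 1, 2], [0, 1, 2]))
                dx += g @ self.w[di, dj].T
        return dx

    def parameters(self):
        return [(self.w, self.dw), (self.b, self.db)]


class BatchNorm(Layer):
    """Per-channel batch normalisation over (N, H, W); running stats at eval."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        self._axes = axes
        self._m = np.prod([x.shape[a] for a in axes])
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        self.dgamma[...] = (grad * self._xhat).sum(axis=self._axes)
        self.dbeta[...] = grad.sum(axis=self._axes)
        if not self._train:
            return grad * self.gamma / self._std
        m = self._m
        dxhat = grad * self.gamma
        return (dxhat - dxhat.mean(axis=self._axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=self._axes)) / self._std

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def parameters(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Residual(Layer):
    """y = body(x) + shortcut(x); shortcut defaults to identity."""

    def __init__(self, body, shortcut=None):
        self.body = Sequential(body)
        self.shortcut = Sequential(shortcut) if shortcut else None

    def forward(self, x, train=False):
        y = self.body.forward(x, train=train)
        s = self.shortcut.forward(x, train=train) if self.shortcut else x
        return y + s

    def backward(self, grad):
        dx = self.body.backward(grad)
        ds = self.shortcut.backward(grad) if self.shortcut else grad
        return dx + ds

    def parameters(self):
        params = self.body.parameters()
        if self.shortcut:
            params += self.shortcut.parameters()
        return params


# ---------------------------------------------------------------------------
# losses and optimiser


def softmax_xent(logits, labels):
    """Mean cross-entropy over all leading axes; labels are int class ids.

    Returns (loss, dlogits).
    """
    p = softmax(logits, axis=-1)
    flat_p = p.reshape(-1, p.shape[-1])
    flat_y = np.asarray(labels).reshape(-1)
    n = flat_y.size
    eps = 1e-12
    loss = -np.log(flat_p[np.arange(n), flat_y] + eps).mean()
    d = flat_p.copy()
    d[np.arange(n), flat_y] -= 1.0
    return loss, (d / n).reshape(logits.shape)


def bce_with_logits(logits, targets):
    """Binary cross-entropy on raw logits. Returns (loss, dlogits)."""
    logits = np.asarray(logits, dtype=float).reshape(-1)
    t = np.asarray(targets, dtype=float).reshape(-1)
    p = expit(logits)
    eps = 1e-12
    loss = -(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)).mean()
    return loss, ((p - t) / t.size)


class Adam:
    """Adam over a model exposing parameters() -> [(param, grad), ...].

    The pair list is re-fetched each step so models may rebuild grad arrays.
    """

    def __init__(self, model, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = None
        self.v = None

    def step(self):
        pairs = self.model.parameters()
        if self.m is None:
            self.m = [np.zeros_like(p) for p, _ in pairs]
            self.v = [np.zeros_like(p) for p, _ in pairs]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for i, (p, g) in enumerate(pairs):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p -= self.lr * (self.m[i] / corr1) / (np.sqrt(self.v[i] / corr2) + self.eps)
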