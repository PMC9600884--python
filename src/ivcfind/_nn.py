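"""Minimal CPU neural-network layers with reverse-mode gradients.

Implements exactly the pieces the segmentation UNet needs — 2-D convolution
(im2col), batch normalization, leaky ReLU, 2x2 max-pool, nearest-neighbor
upsampling, inverted dropout, softmax sparse-categorical cross-entropy, and
Adam.  All arrays are ``(N, C, H, W)`` float32 unless noted.  Every layer
caches what its backward pass needs on the most recent forward call, so one
layer instance is used at most once per forward pass.
"""

from __future__ import annotations

import numpy as np

_DT = np.float32


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix for stride-1 'same' conv."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
    idx = 0
    for i in range(k):
        for j in range(k):
            cols[:, :, idx] = x[:, :, i:i + h, j:j + w]
            idx += 1
    return cols.reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, x_shape, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    cols = cols.reshape(n, c, k * k, h, w)
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    idx = 0
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + h, j:j + w] += cols[:, :, idx]
            idx += 1
    return out[:, :, pad:pad + h, pad:pad + w] if pad else out


class Layer:
    """Base: trainable arrays in ``params``, matching gradients in ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv2D(Layer):
    """Stride-1 'same' convolution, He-initialised."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        self.params["W"] = (rng.standard_normal((c_out, fan_in)) *
                            np.sqrt(2.0 / fan_in)).astype(_DT)
        self.params["b"] = np.zeros(c_out, dtype=_DT)

    def forward(self, x, train=False):
        self._x_shape = x.shape
        self._cols = _im2col(x, self.kernel, self.kernel // 2)
        n, _, h, w = x.shape
        out = np.matmul(self.params["W"], self._cols) + self.params["b"][:, None]
        return out.reshape(n, self.c_out, h, w)

    def backward(self, dout):
        n, _, h, w = dout.shape
        dflat = dout.reshape(n, self.c_out, h * w)
        self.grads["W"] = np.tensordot(dflat, self._cols, axes=([0, 2], [0, 2])).astype(_DT)
        self.grads["b"] = dflat.sum(axis=(0, 2)).astype(_DT)
        dcols = np.matmul(self.params["W"].T, dflat)
        dx = _col2im(dcols, self._x_shape, self.kernel, self.kernel // 2)
        self._cols = None
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W), with running stats for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=_DT)
        self.params["beta"] = np.zeros(channels, dtype=_DT)
        self.buffers["running_mean"] = np.zeros(channels, dtype=_DT)
        self.buffers["running_var"] = np.ones(channels, dtype=_DT)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] = (m * self.buffers["running_mean"] +
                                            (1 - m) * mean).astype(_DT)
            self.buffers["running_var"] = (m * self.buffers["running_var"] +
                                           (1 - m) * var).astype(_DT)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        self._xhat = (x - mean[:, None, None]) * self._istd[:, None, None]
        return self.params["gamma"][:, None, None] * self._xhat + \
            self.params["beta"][:, None, None]

    def backward(self, dout):
        xhat, istd = self._xhat, self._istd
        m = float(dout.shape[0] * dout.shape[2] * dout.shape[3])
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3)).astype(_DT)
        self.grads["beta"] = dout.sum(axis=(0, 2, 3)).astype(_DT)
        dxhat = dout * self.params["gamma"][:, None, None]
        # standard batch-norm gradient, fused form
        s1 = dxhat.sum(axis=(0, 2, 3))
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))
        dx = (istd[:, None, None] / m) * (
            m * dxhat - s1[:, None, None] - xhat * s2[:, None, None]
        )
        self._xhat = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.2):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x, train=False):
        self._neg = x < 0
        return np.where(self._neg, self.negative_slope * x, x)

    def backward(self, dout):
        return np.where(self._neg, self.negative_slope * dout, dout)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; gradients route to the argmax of each window."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial extents must be even for 2x2 pooling, got {(h, w)}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._x_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class NearestUpsample2D(Layer):
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout(Layer):
    """Inverted dropout; identity at inference or rate 0."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(dout.dtype)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean per-pixel softmax cross-entropy with integer labels.

    Parameters
    ----------
    logits : (N, K, H, W)
    labels : (N, H, W) integers in [0, K)

    Returns
    -------
    loss : float — mean negative log-probability of the true class.
    dlogits : same shape as ``logits`` — gradient of the mean loss.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    picked = np.take_along_axis(logp, labels[:, None], axis=1)
    loss = float(-picked.mean())
    n_pix = labels.size
    dlogits = np.exp(logp)
    np.put_along_axis(dlogits, labels[:, None],
                      np.take_along_axis(dlogits, labels[:, None], axis=1) - 1.0, axis=1)
    return loss, (dlogits / n_pix).astype(logits.dtype)


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(self, layers, learning_rate: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [ly for ly in layers if ly.params]
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for i, ly in enumerate(self.layers):
            for name, p in ly.params.items():
                self.m[i, name] = np.zeros_like(p)
                self.v[i, name] = np.zeros_like(p)

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, ly in enumerate(self.layers):
            for name, p in ly.params.items():
                g = ly.grads[name]
                m = self.m[i, name] = self.b1 * self.m[i, name] + (1 - self.b1) * g
                v = self.v[i, name] = self.b2 * self.v[i, name] + (1 - self.b2) * g * g
                p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
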