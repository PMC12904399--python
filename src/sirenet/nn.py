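"""Minimal CPU neural-network engine (numpy) for spectrogram classification.

Implements exactly what the detector needs — 2-D convolution (im2col),
batch normalization, ReLU, max/global-average pooling, dropout, linear
layers, softmax cross-entropy, the Adam optimizer and per-epoch
exponential learning-rate decay — with explicit seeding so training is
bit-reproducible on a single thread.

Tensors are ``(N, C, H, W)`` float32 throughout. Every layer exposes
``forward(x, train, rng)`` and ``backward(dout)``; parameters and their
gradients live in per-layer dicts so the optimizer can walk them.
"""

from __future__ import annotations

import numpy as np

#: working dtype; float32 halves memory traffic on activation-heavy nets
DTYPE = np.float32

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "TimeAvgFlatten",
    "Flatten",
    "Linear",
    "Dropout",
    "Sequential",
    "Residual",
    "softmax",
    "cross_entropy_with_grad",
    "Adam",
]


class Layer:
    """Base layer: parameter-free unless a subclass adds ``params``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def walk(self):
        """Yield (layer, name) pairs for every parameter tensor."""
        for name in self.params:
            yield self, name


class Conv2d(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
        *,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        # He initialization for ReLU networks
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in)).astype(DTYPE)
        if bias:
            self.params["b"] = np.zeros(out_ch, dtype=DTYPE)

    def _cols(self, x: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        # (N, C, Ho, Wo, k, k)
        view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        return view[:, :, ::s, ::s], x.shape

    def forward(self, x, train=False, rng=None):
        view, self._padded_shape = self._cols(x)
        n, c, ho, wo = view.shape[:4]
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, -1)
        self._cols_cache, self._out_hw, self._n = cols, (ho, wo), n
        out = cols @ self.params["W"].T
        if "b" in self.params:
            out = out + self.params["b"]
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, (ho, wo) = self._n, self._out_hw
        k, s = self.k, self.stride
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        self.grads["W"] = dflat.T @ self._cols_cache
        if "b" in self.params:
            self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"]).reshape(n, ho, wo, self.in_ch, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, Ho, Wo, k, k)
        dx_pad = np.zeros(self._padded_shape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dx_pad[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ]
        if self.pad:
            return dx_pad[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dx_pad


class BatchNorm2d(Layer):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(ch, dtype=DTYPE)
        self.params["beta"] = np.zeros(ch, dtype=DTYPE)
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)

    def forward(self, x, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                1 - self.momentum
            ) * self.running_mean + self.momentum * mean
            self.running_var = (
                1 - self.momentum
            ) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        m = mean[None, :, None, None]
        istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - m) * istd[None, :, None, None]
        self._istd = istd
        return (
            self.params["gamma"][None, :, None, None] * self._xhat
            + self.params["beta"][None, :, None, None]
        )

    def backward(self, dout):
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True) / n
        ) * self._istd[None, :, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """Non-overlapping 2x2 max pooling; odd trailing rows/cols dropped."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xr = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._arg = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, : h2 * 2, : w2 * 2] = dxr.reshape(n, c, h2 * 2, w2 * 2)
        return dx


class TimeAvgFlatten(Layer):
    """Average over the time axis, flatten channel x frequency.

    Unlike global average pooling this keeps frequency position, so a
    tonal ridge at 500 Hz and one at 4 kHz produce different features.
    """

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        n, c, h, w = x.shape
        return x.mean(axis=3).reshape(n, c * h)

    def backward(self, dout):
        n, c, h, w = self._shape
        d = dout.reshape(n, c, h, 1) / w
        return np.broadcast_to(d, self._shape).copy()


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        return np.broadcast_to(
            dout[:, :, None, None] / self._hw, self._shape
        ).copy()


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_out, n_in)).astype(DTYPE)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        self._mask = ((rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def walk(self):
        for layer in self.layers:
            yield from layer.walk()


class Residual(Layer):
    """y = relu(body(x) + shortcut(x)); shortcut defaults to identity."""

    def __init__(self, body: Layer, shortcut: Layer | None = None) -> None:
        super().__init__()
        self.body = body
        self.shortcut = shortcut
        self._relu = ReLU()

    def forward(self, x, train=False, rng=None):
        y = self.body.forward(x, train=train, rng=rng)
        s = x if self.shortcut is None else self.shortcut.forward(x, train=train, rng=rng)
        return self._relu.forward(y + s, train=train, rng=rng)

    def backward(self, dout):
        d = self._relu.backward(dout)
        dx_body = self.body.backward(d)
        dx_short = d if self.shortcut is None else self.shortcut.backward(d)
        return dx_body + dx_short

    def walk(self):
        yield from self.body.walk()
        if self.shortcut is not None:
            yield from self.shortcut.walk()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.maximum(p[np.arange(n), targets], 1e-300)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adam with optional per-epoch exponential LR decay (lr * gamma^epoch)."""

    def __init__(
        self,
        net: Layer,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        gamma: float = 1.0,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 < gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        self.net = net
        self.base_lr, self.lr = lr, lr
        self.b1, self.b2 = betas
        self.eps, self.gamma = eps, gamma
        self.t = 0
        # keyed by position in walk order, which is stable for a fixed net
        self._m = {i: np.zeros_like(l.params[n]) for i, (l, n) in enumerate(net.walk())}
        self._v = {k: np.zeros_like(v) for k, v in self._m.items()}

    def set_epoch(self, epoch: int) -> float:
        """Set lr = base_lr * gamma^epoch (epoch 0 = undecayed) and return it."""
        self.lr = self.base_lr * self.gamma**epoch
        return self.lr

    def step(self) -> None:
        self.t += 1
        for key, (layer, name) in enumerate(self.net.walk()):
            g = layer.grads[name]
            m = self._m[key] = self.b1 * self._m[key] + (1 - self.b1) * g
            v = self._v[key] = self.b2 * self._v[key] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
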