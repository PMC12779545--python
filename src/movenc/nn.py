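"""Minimal feed-forward neural-network engine on numpy.

Implements exactly the pieces the video models need — 2-D convolution
(stride 1, 'same' or valid padding), max pooling, batch normalization,
ReLU, linear layers, residual blocks — with hand-written backward passes
and an Adam optimizer. Layers cache what their backward pass needs, so a
training step is forward(x) -> backward(dLoss/dOut) -> optimizer.step().

All backward passes are verified against central finite differences in the
test suite. float32 is used for training; float64 inputs propagate through
unchanged, which the gradient checks rely on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = value
        self.g = np.zeros_like(value)


class Layer:
    train_mode: bool = True

    def params(self) -> list[Param]:
        return []

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Layer):
    """3x3/1x1 convolution, stride 1. padding='same' keeps spatial size."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: str = "same"):
        fan_in = in_ch * kernel * kernel
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  (out_ch, in_ch, kernel, kernel)).astype(np.float32))
        self.b = Param(np.zeros(out_ch, dtype=np.float32))
        self.k = kernel
        self.pad = (kernel - 1) // 2 if padding == "same" else 0

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self.x_shape = x.shape
        n, c, h, w = x.shape
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        # (N, C, Ho, Wo, k, k) view -> (N*Ho*Wo, C*k*k)
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        self.ho, self.wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(-1, c * self.k * self.k)
        self.cols = cols
        wm = self.w.v.reshape(self.w.v.shape[0], -1).T        # (C*k*k, out)
        out = cols @ wm + self.b.v
        return out.reshape(n, self.ho, self.wo, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c, h, w = self.x_shape
        out_ch = self.w.v.shape[0]
        gm = grad.transpose(0, 2, 3, 1).reshape(-1, out_ch)
        self.w.g += (self.cols.T @ gm).T.reshape(self.w.v.shape)
        self.b.g += gm.sum(axis=0)
        wm = self.w.v.reshape(out_ch, -1)
        gcols = (gm @ wm).reshape(n, self.ho, self.wo, c, self.k, self.k)
        gx = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=grad.dtype)
        for i in range(self.k):
            for j in range(self.k):
                gx[:, :, i:i + self.ho, j:j + self.wo] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if self.pad:
            gx = gx[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return gx


class MaxPool2d(Layer):
    """Max pooling with stride equal to the kernel; floor-mode edges.

    If an input dimension is smaller than the kernel, the kernel is clamped
    to that dimension (pooling over whatever remains), so deep stacks stay
    usable on small frames.
    """

    def __init__(self, kernel: int):
        self.k = kernel

    def forward(self, x):
        n, c, h, w = x.shape
        kh, kw = min(self.k, h), min(self.k, w)
        ho, wo = h // kh, w // kw
        self.meta = (x.shape, kh, kw, ho, wo)
        xc = x[:, :, : ho * kh, : wo * kw]
        blocks = xc.reshape(n, c, ho, kh, wo, kw).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, ho, wo, kh * kw)
        self.arg = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self.arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        (n, c, h, w), kh, kw, ho, wo = self.meta
        flat = np.zeros((n, c, ho, wo, kh * kw), dtype=grad.dtype)
        np.put_along_axis(flat, self.arg[..., None], grad[..., None], axis=-1)
        gx = np.zeros((n, c, h, w), dtype=grad.dtype)
        gx[:, :, : ho * kh, : wo * kw] = (
            flat.reshape(n, c, ho, wo, kh, kw).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ho * kh, wo * kw)
        )
        return gx


class ReLU(Layer):
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.eps = eps
        self.momentum = momentum
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        axes = (0, 2, 3)
        if self.train_mode:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        self.std = np.sqrt(var + self.eps)[None, :, None, None]
        self.xhat = (x - mean[None, :, None, None]) / self.std
        return self.gamma.v[None, :, None, None] * self.xhat + self.beta.v[None, :, None, None]

    def backward(self, grad):
        axes = (0, 2, 3)
        self.gamma.g += (grad * self.xhat).sum(axis=axes)
        self.beta.g += grad.sum(axis=axes)
        g = grad * self.gamma.v[None, :, None, None]
        if not self.train_mode:
            return g / self.std
        gm = g.mean(axis=axes)[None, :, None, None]
        gx = g - gm - self.xhat * (g * self.xhat).mean(axis=axes)[None, :, None, None]
        return gx / self.std


class Flatten(Layer):
    def forward(self, x):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.shape)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / in_dim),
                                  (in_dim, out_dim)).astype(np.float32))
        self.b = Param(np.zeros(out_dim, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self.x = x
        return x @ self.w.v + self.b.v

    def backward(self, grad):
        self.w.g += self.x.T @ grad
        self.b.g += grad.sum(axis=0)
        return grad @ self.w.v.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def set_train(self, mode: bool):
        for layer in self.layers:
            layer.set_train(mode)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Residual(Layer):
    """y = body(x) + skip(x); skip is identity or a 1x1 projection."""

    def __init__(self, body: Sequential, skip: Layer | None = None):
        self.body = body
        self.skip = skip

    def params(self):
        return self.body.params() + (self.skip.params() if self.skip else [])

    def set_train(self, mode: bool):
        self.body.set_train(mode)
        if self.skip:
            self.skip.set_train(mode)

    def forward(self, x):
        return self.body.forward(x) + (self.skip.forward(x) if self.skip else x)

    def backward(self, grad):
        g1 = self.body.backward(grad)
        g2 = self.skip.backward(grad) if self.skip else grad
        return g1 + g2


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.u = [np.zeros_like(p.v) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, u in zip(self.params, self.m, self.u):
            m[...] = self.b1 * m + (1 - self.b1) * p.g
            u[...] = self.b2 * u + (1 - self.b2) * p.g**2
            mh = m / (1 - self.b1**self.t)
            uh = u / (1 - self.b2**self.t)
            p.v -= self.lr * mh / (np.sqrt(uh) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to pred."""
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff
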