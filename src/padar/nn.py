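"""Minimal CPU neural-network layer stack with manual backprop and Adam.

Layers operate on NHWC float32/float64 arrays. Convolutions use an im2col
formulation built on ``sliding_window_view``, which is the fastest pure-numpy
route for the small VGG-style stacks used by the screening model. The stack
exposes exactly what the rest of the package needs: forward passes that cache
intermediates, backward passes that return input gradients (required for the
class-activation mapping, which differentiates a head score with respect to
the last convolutional feature map), per-parameter gradients, and an Adam
optimizer with a reduce-on-plateau learning-rate schedule.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2d(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1, NHWC."""

    def __init__(self, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = k * k * c_in
        self.k = k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _cols(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (N, H, W, C, k, k) -> (N*H*W, k*k*C) with (ki, kj, c) ordering
        n, h, w, c = x.shape
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, k * k * c)

    def forward(self, x, train=False):
        self.x_shape = x.shape
        self.cols = self._cols(x)
        n, h, w, _ = x.shape
        out = self.cols @ self.W + self.b
        return out.reshape(n, h, w, -1)

    def backward(self, grad):
        n, h, w, c_out = grad.shape
        g = grad.reshape(n * h * w, c_out)
        self.dW[...] = self.cols.T @ g
        self.db[...] = g.sum(axis=0)
        dcols = g @ self.W.T
        k, p = self.k, self.k // 2
        _, _, _, c_in = self.x_shape
        dcols = dcols.reshape(n, h, w, k, k, c_in)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c_in), dtype=grad.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki:ki + h, kj:kj + w, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, p:p + h, p:p + w, :]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, train=False):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2 (input sides must be even)."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self.mask = xr == out[:, :, None, :, None, :]
        self.in_shape = x.shape
        return out

    def backward(self, grad):
        n, h, w, c = self.in_shape
        g = grad[:, :, None, :, None, :] * self.mask
        return g.reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self.in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self.in_shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w),
                               self.in_shape).copy()


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in),
                            (d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self.x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self.x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dropout(Layer):
    """Inverted dropout; identity in inference mode (deterministic predict)."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (self.rng.random(x.shape) < keep) / keep
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def grads(self):
        return [g for lay in self.layers for g in lay.grads()]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and the gradient w.r.t. the logits.

    ``targets`` are integer class indices. The returned gradient already
    folds in the softmax Jacobian (probs - onehot) / n.
    """
    n = probs.shape[0]
    p = np.clip(probs, 1e-12, 1.0)
    loss = -np.log(p[np.arange(n), targets]).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return float(loss), dlogits / n


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class PlateauScheduler:
    """Divide the learning rate by ``factor`` after ``patience`` epochs with
    no improvement in the monitored loss, down to ``lr_floor``."""

    def __init__(self, optimizer: Adam, factor: float = 10.0,
                 patience: int = 10, lr_floor: float = 1e-8):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.lr_floor = lr_floor
        self.best = np.inf
        self.stale = 0

    def step(self, monitored_loss: float) -> bool:
        """Returns True if the learning rate was decayed this epoch."""
        if monitored_loss < self.best - 1e-9:
            self.best = monitored_loss
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience and self.opt.lr > self.lr_floor:
            self.opt.lr = max(self.opt.lr / self.factor, self.lr_floor)
            self.stale = 0
            return True
        return False
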