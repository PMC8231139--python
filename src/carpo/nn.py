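"""Minimal CPU neural-network engine used by the segmentation module.

Implements exactly the pieces a symmetric 2D U-Net needs — 3x3/1x1
convolutions, batch normalization, ReLU, 2x2 max-pooling,
nearest-neighbour upsampling — with hand-written backward passes, plus
the Adam optimizer and a multi-step learning-rate schedule.

Activations flow in channels-last layout ``(N, H, W, C)``, which keeps
the convolution inner loops as nine contiguous-slice matrix products
(one per kernel tap) instead of an im2col gather; the backward pass
accumulates input gradients into a padded buffer the same way.  The
engine supports stride-1 same-padding convolutions and factor-2 pooling
only, which is all the symmetric U-Net uses.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "UpsampleNearest2x",
    "Adam",
    "MultiStepLR",
    "softmax",
]


class Conv2d:
    """Same-padding, stride-1 convolution with bias (He-initialized).

    Weights are stored as ``(C_out, C_in, k, k)``; activations as
    ``(N, H, W, C)``.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((c_out, c_in, k, k))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    @property
    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, ci = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        if train:
            self._xp = xp
        out = np.empty((n * h * w, self.w.shape[0]), dtype=x.dtype)
        out[:] = self.b
        for a in range(k):
            for b in range(k):
                sl = xp[:, a:a + h, b:b + w, :].reshape(-1, ci)
                out += sl @ self.w[:, :, a, b].T
        return out.reshape(n, h, w, -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, co = gy.shape
        k, p = self.k, self.k // 2
        xp = self._xp
        self._xp = None
        gmat = gy.reshape(-1, co)
        self.gb += gmat.sum(axis=0, dtype=np.float32)
        gxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                sl = xp[:, a:a + h, b:b + w, :].reshape(-1, xp.shape[-1])
                self.gw[:, :, a, b] += (gmat.T @ sl).astype(np.float32)
                gxp[:, a:a + h, b:b + w, :] += (gmat @ self.w[:, :, a, b]) \
                    .reshape(n, h, w, -1)
        return gxp[:, p:p + h, p:p + w, :] if p else gxp


class BatchNorm2d:
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.run_mean = ((1 - self.momentum) * self.run_mean
                             + self.momentum * mean).astype(np.float32)
            self.run_var = ((1 - self.momentum) * self.run_var
                            + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv)
        return self.gamma * xhat + self.beta

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        self.ggamma += (gy * xhat).sum(axis=(0, 1, 2), dtype=np.float32)
        self.gbeta += gy.sum(axis=(0, 1, 2), dtype=np.float32)
        gxhat = gy * self.gamma
        gx = (gxhat - gxhat.mean(axis=(0, 1, 2), keepdims=True)
              - xhat * (gxhat * xhat).mean(axis=(0, 1, 2), keepdims=True))
        return gx * inv


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool2x2:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if train:
            self._mask = xr == out[:, :, None, :, None, :]
            self._shape = x.shape
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        g = self._mask * gy[:, :, None, :, None, :]
        # split ties evenly so the gradient of the max is conserved
        g = g / self._mask.sum(axis=(2, 4), keepdims=True)
        return g.reshape(n, h, w, c)


class UpsampleNearest2x:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = gy.shape
        return gy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam with classic (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)  # (value, grad) pairs; updated in place
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            if self.wd:
                g = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


class MultiStepLR:
    """Piecewise-constant schedule: lr_epoch = lr0 * gamma^(#milestones <= epoch)."""

    def __init__(self, lr0: float, milestones: tuple[int, ...], gamma: float = 0.1):
        if list(milestones) != sorted(set(milestones)):
            raise ValueError("milestones must be strictly increasing")
        self.lr0 = lr0
        self.milestones = tuple(milestones)
        self.gamma = gamma

    def lr_at(self, epoch: int) -> float:
        drops = sum(1 for m in self.milestones if epoch >= m)
        return self.lr0 * self.gamma ** drops
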