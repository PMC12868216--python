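"""Layer primitives with explicit forward/backward passes.

All layers operate on ``(N, C, H, W)`` float32 arrays. Convolutions are
implemented via im2col so the heavy lifting is a single matmul.
"""

from __future__ import annotations

import numpy as np


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """View a padded batch as (N, C, k, k, H, W) sliding windows (no copy)."""
    n, c, hp, wp = xp.shape
    h, w = hp - k + 1, wp - k + 1
    s = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, k, k, h, w), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )


class Conv2d:
    """Same-padded 2D convolution (stride 1), He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def param_count(self) -> int:
        return self.W.size + self.b.size

    def flops(self, h: int, w: int, n: int = 1) -> int:
        # multiply-add counted as 2 FLOPs, same-padded output
        return 2 * self.k * self.k * self.c_in * self.c_out * h * w * n

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, self.k)  # (N, C, k, k, H, W)
        n, _, _, _, h, w = cols.shape
        cols2 = cols.transpose(0, 4, 5, 1, 2, 3).reshape(n * h * w, -1)
        out = cols2 @ self.W.reshape(self.c_out, -1).T + self.b
        if train:
            self._cols = cols2
            self._x_shape = x.shape
        return np.ascontiguousarray(out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.dW[...] = (dflat.T @ self._cols).reshape(self.W.shape)
        self.db[...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(self.c_out, -1)).reshape(n, h, w, self.c_in, self.k, self.k)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # (N, C, k, k, H, W)
        p = self.k // 2
        dxp = np.zeros((n, self.c_in, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, ki, kj]
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU:
    """Leaky rectifier; the small negative slope keeps units recoverable
    under the flat gradients of batch-summed Jaccard loss."""

    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.where(x > 0, x, self.slope * x)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dout, self.slope * dout)
        self._mask = None
        return dx


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return (self.gamma[None, :, None, None] * xhat
                + self.beta[None, :, None, None]).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (inv[None, :, None, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        )
        return dx.astype(np.float32)


class MaxPool2:
    """2x2 max pooling; spatial dims must be even."""

    def __init__(self):
        self._argmask = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            self._argmask = (xr == out[:, :, :, None, :, None])
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dout.shape
        dxr = self._argmask * dout[:, :, :, None, :, None]
        # ties (rare with float activations) split gradient; normalize per window
        counts = self._argmask.sum(axis=(3, 5), keepdims=True)
        dxr = dxr / counts
        self._argmask = None
        return dxr.reshape(n, c, h2 * 2, w2 * 2)


class UpsampleNearest2:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
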