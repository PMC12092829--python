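"""Minimal CPU neural-network primitives (NumPy, float32).

Layers follow a simple contract: ``forward(x, train)`` caches what the
backward pass needs; ``backward(dy)`` returns ``dx`` and accumulates
parameter gradients in-place.  Convolutions use im2col + GEMM, which is
where essentially all compute goes, so everything stays float32 and
contiguous.  An AdamW optimizer with decoupled weight decay is included.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "v", "g")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.v = value.astype(F32)
        self.g = np.zeros_like(self.v)


class Layer:
    def params(self) -> list[Param]:
        return []

    def state_arrays(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running stats)."""
        return []


class Conv2d(Layer):
    """Same-padding 2D convolution, kernel k x k, optional bias."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 bias: bool = False, name: str = "conv"):
        self.cin, self.cout, self.k = cin, cout, k
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(f"{name}.W", rng.normal(0.0, std, size=(cin * k * k, cout)))
        self.b = Param(f"{name}.b", np.zeros(cout)) if bias else None
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        p = k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        return np.ascontiguousarray(cols, dtype=F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        y = cols @ self.W.v
        if self.b is not None:
            y += self.b.v
        if train:
            self._cols = cols
            self._xshape = x.shape
        return np.ascontiguousarray(y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k = self.k
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * w, self.cout)
        self.W.g += self._cols.T @ dyf
        if self.b is not None:
            self.b.g += dyf.sum(axis=0)
        dcols = (dyf @ self.W.v.T).reshape(n, h, w, c, k, k)
        p = k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, name: str = "bn", momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Param(f"{name}.gamma", np.ones(c))
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state_arrays(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
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
            self._cache = (xhat, inv, x.shape)
        return (self.gamma.v[None, :, None, None] * xhat
                + self.beta.v[None, :, None, None]).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.gamma.g += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.g += dy.sum(axis=(0, 2, 3))
        g = self.gamma.v[None, :, None, None]
        dxhat = dy * g
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
        self._cache = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=4)
        y = np.take_along_axis(xr, idx[..., None], axis=4)[..., 0]
        if train:
            self._idx, self._xshape = idx, x.shape
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=4)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


class ConvTranspose2(Layer):
    """2x2 transposed convolution with stride 2 (non-overlapping blocks)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 name: str = "upconv"):
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / cin)
        self.W = Param(f"{name}.W", rng.normal(0.0, std, size=(cin, cout * 4)))
        self._xf = None

    def params(self) -> list[Param]:
        return [self.W]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xf = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(n * h * w, c)
        y = (xf @ self.W.v).reshape(n, h, w, self.cout, 2, 2)
        y = y.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.cout, 2 * h, 2 * w)
        if train:
            self._xf, self._xshape = xf, x.shape
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        dyr = dy.reshape(n, self.cout, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        dyf = np.ascontiguousarray(dyr).reshape(n * h * w, self.cout * 4)
        self.W.g += self._xf.T @ dyf
        dx = (dyf @ self.W.v.T).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        self._xf = None
        return np.ascontiguousarray(dx)


class NearestUp2(Layer):
    """2x nearest-neighbor upsampling (parameter-free)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class AttentionGate(Layer):
    """Additive attention on a skip connection.

    The gating signal ``g`` (the upsampled coarser decoder feature) and the
    skip feature ``x`` are projected to an intermediate channel count,
    summed, passed through ReLU, reduced to a single channel, and squashed
    by a sigmoid; the resulting [0, 1] map multiplicatively gates ``x``.
    """

    def __init__(self, cx: int, cg: int, cint: int, rng: np.random.Generator,
                 name: str = "att"):
        self.wx = Conv2d(cx, cint, 1, rng, bias=False, name=f"{name}.wx")
        self.wg = Conv2d(cg, cint, 1, rng, bias=True, name=f"{name}.wg")
        self.psi = Conv2d(cint, 1, 1, rng, bias=True, name=f"{name}.psi")
        self.relu = ReLU()

    def params(self) -> list[Param]:
        return self.wx.params() + self.wg.params() + self.psi.params()

    def forward(self, x: np.ndarray, g: np.ndarray, train: bool) -> np.ndarray:
        q = self.relu.forward(self.wx.forward(x, train) + self.wg.forward(g, train),
                              train)
        a = 1.0 / (1.0 + np.exp(-self.psi.forward(q, train)))
        if train:
            self._x, self._a = x, a
        return (x * a).astype(F32)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x, a = self._x, self._a
        dx_direct = dy * a
        da = (dy * x).sum(axis=1, keepdims=True)
        dpsi = da * a * (1.0 - a)
        dq = self.relu.backward(self.psi.backward(dpsi.astype(F32)))
        dx_gate = self.wx.backward(dq)
        dg = self.wg.backward(dq)
        self._x = self._a = None
        return (dx_direct + dx_gate).astype(F32), dg


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.g - m)
            v += (1.0 - self.b2) * (p.g * p.g - v)
            mhat = m / bc1
            vhat = v / bc2
            p.v -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.v)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Softmax over axis 1 of an (n, C, H, W) array."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=1, keepdims=True)).astype(F32)


def softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Gradient through channel softmax: dz from p = softmax(z) and dL/dp."""
    dot = (dp * p).sum(axis=1, keepdims=True)
    return (p * (dp - dot)).astype(F32)
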