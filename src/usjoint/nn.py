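"""Minimal NumPy neural-network layers with hand-written backprop.

Implements exactly the pieces the lesion networks need: 3x3/1x1
convolutions (im2col + BLAS), batch normalization, ReLU, 2x2 max pooling,
fixed bilinear 2x upsampling, global average pooling, fully connected
layers and SGD with momentum and weight decay.

Conventions
-----------
* Tensors are ``float32`` in NCHW layout (batch, channel, row, col).
* Each layer caches what its backward pass needs during ``forward``;
  a layer instance therefore supports one forward/backward pair at a time.
* Layers are pure given their parameters: seeding the initializer RNG
  makes whole networks reproducible.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _as32(x: np.ndarray) -> np.ndarray:
    return x if x.dtype == DTYPE else x.astype(DTYPE)


class Param:
    """A learnable tensor with its gradient and momentum buffer."""

    __slots__ = ("value", "grad", "vel")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.vel = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, ksize: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for a stride-1 conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    win = np.lib.stride_tricks.sliding_window_view(xp, (ksize, ksize), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N*H*W, C*k*k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * ksize * ksize)


class Conv2d(Layer):
    """Same-padding stride-1 convolution with square kernel (3x3 or 1x1).

    Forward is im2col plus one GEMM.  Backward computes the weight
    gradient from the cached column matrix and the input gradient as a
    convolution of the output gradient with the 180-degree-rotated
    kernels — a second im2col/GEMM pair, no scatter-adds.
    """

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        self.cin, self.cout, self.ksize = cin, cout, ksize
        self.pad = ksize // 2
        fan_in = cin * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.w = Param(w)
        self.b = Param(np.zeros(cout))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        cols = _im2col(x, self.ksize, self.pad)
        y = cols @ self.w.value.T + self.b.value  # (N*H*W, Cout)
        self._cache = (cols, (n, c, h, w))
        return np.ascontiguousarray(
            y.reshape(n, h * w, self.cout).transpose(0, 2, 1)).reshape(
            n, self.cout, h, w)

    def _rotated_weights(self) -> np.ndarray:
        """(Cin, Cout*k*k) matrix of spatially flipped, channel-swapped kernels."""
        k = self.ksize
        wk = self.w.value.reshape(self.cout, self.cin, k, k)[:, :, ::-1, ::-1]
        return np.ascontiguousarray(wk.transpose(1, 0, 2, 3)).reshape(
            self.cin, self.cout * k * k)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        gy = np.ascontiguousarray(gout.transpose(0, 2, 3, 1)).reshape(
            n * h * w, self.cout)
        self.w.grad += gy.T @ cols
        self.b.grad += gy.sum(axis=0)
        # same-padded correlation of gout with rotated kernels = grad wrt input
        gcols = _im2col(gout, self.ksize, self.pad)
        gx = gcols @ self._rotated_weights().T  # (N*H*W, Cin)
        return np.ascontiguousarray(
            gx.reshape(n, h * w, c).transpose(0, 2, 1)).reshape(n, c, h, w)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean[None, :, None, None].astype(DTYPE)) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return _as32(self.gamma.value[None, :, None, None] * xhat
                     + self.beta.value[None, :, None, None])

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, (n, c, h, w) = self._cache
        m = n * h * w
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        g = gout * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        gx = (inv[None, :, None, None] / m) * (m * g - gsum - xhat * gxsum)
        return _as32(gx)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, 0)


class BatchNorm1d(Layer):
    """Batch normalization over (N, C) feature vectors."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean, var = x.mean(axis=0), x.var(axis=0)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean.astype(DTYPE)) * inv
        self._cache = (xhat, inv, x.shape[0])
        return _as32(self.gamma.value * xhat + self.beta.value)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, n = self._cache
        self.gamma.grad += (gout * xhat).sum(axis=0)
        self.beta.grad += gout.sum(axis=0)
        g = gout * self.gamma.value
        gx = (inv / n) * (n * g - g.sum(axis=0) - xhat * (g * xhat).sum(axis=0))
        return _as32(gx)


class LeakyReLU(Layer):
    """Rectifier with a small negative slope; keeps gradient flow alive in
    narrow fully connected layers."""

    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, self.slope * gout)


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size ({h}, {w}) not divisible by 2")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        gx = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(gx, self._arg[..., None], _as32(gout)[..., None], axis=-1)
        gx = gx.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(gx.reshape(n, c, h, w))


def _interp_matrix(size_in: int) -> np.ndarray:
    """Dense (2n, n) matrix for 1-D bilinear 2x upsampling (half-pixel centers)."""
    n = size_in
    out = np.zeros((2 * n, n))
    src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    lo = np.clip(np.floor(src).astype(int), 0, n - 1)
    hi = np.clip(lo + 1, 0, n - 1)
    frac = np.clip(src - lo, 0.0, 1.0)
    out[np.arange(2 * n), lo] += 1.0 - frac
    out[np.arange(2 * n), hi] += frac
    return out


class BilinearUp2x(Layer):
    """Parameter-free bilinear x2 upsampling; backward is the exact adjoint."""

    _mats: dict[int, np.ndarray] = {}

    @classmethod
    def _mat(cls, n: int) -> np.ndarray:
        m = cls._mats.get(n)
        if m is None:
            m = _interp_matrix(n).astype(DTYPE)
            cls._mats[n] = m
        return m

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        uh, uw = self._mat(h), self._mat(w)
        self._hw = (h, w)
        y = np.matmul(uh[None, None], x)        # (N, C, 2H, W)
        return np.matmul(y, uw.T[None, None])   # (N, C, 2H, 2W)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        h, w = self._hw
        uh, uw = self._mat(h), self._mat(w)
        g = np.matmul(uh.T[None, None], gout)
        return np.matmul(g, uw[None, None])


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return _as32(np.broadcast_to(gout[:, :, None, None] / (h * w), self._shape))


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin)))
        self.b = Param(np.zeros(cout))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.w.grad += gout.T @ self._x
        self.b.grad += gout.sum(axis=0)
        return _as32(gout @ self.w.value)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


class SGD:
    """SGD with classical momentum; weight decay added to the gradient.

    ``max_grad_norm`` rescales the global gradient norm when it exceeds
    the bound, guarding the narrow branches against occasional large
    minibatch gradients at high learning rates.
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, max_grad_norm: float | None = None):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.max_grad_norm = max_grad_norm

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        if self.max_grad_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in self.params))
            if total > self.max_grad_norm:
                scale = DTYPE(self.max_grad_norm / total)
                for p in self.params:
                    p.grad *= scale
        for p in self.params:
            g = p.grad + self.weight_decay * p.value
            p.vel[...] = self.momentum * p.vel + g
            p.value[...] -= self.lr * p.vel


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    zmax = z.max(axis=axis, keepdims=True)
    e = np.exp(z - zmax)
    return e / e.sum(axis=axis, keepdims=True)
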