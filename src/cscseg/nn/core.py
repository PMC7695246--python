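"""Minimal CPU neural-network primitives used by all CSC networks.

Everything is float32 numpy with hand-derived backward passes.  Activations
are stored channels-last, ``(N, H, W, C)``, so the im2col buffers feeding
the GEMM-based convolutions are built from nearly-contiguous slices — on a
single CPU this layout is what keeps desk-scale training in seconds per
epoch.  The stack is deliberately tiny: the networks in this package are
small encoder–decoder CNNs, and a dependency-free implementation keeps
training fully deterministic (seeded init, seeded dropout).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "Linear",
    "GlobalAvgPool",
]


class Param:
    """A trainable array with its gradient accumulator and a freeze flag."""

    __slots__ = ("data", "grad", "frozen", "name")

    def __init__(self, data: np.ndarray, frozen: bool = False, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.frozen = frozen
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' zero padding.

    Weights are stored as ``(k*k*Cin, Cout)`` ready for the GEMM; the
    logical kernel is recovered with :meth:`kernel`.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, *, rng: np.random.Generator,
                 bias_init: float = 0.0):
        self.k = k
        self.cin = cin
        self.cout = cout
        self.pad = k // 2
        self.W = Param(_he_init(rng, (k * k * cin, cout), cin * k * k))
        self.b = Param(np.full(cout, bias_init, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def kernel(self) -> np.ndarray:
        """Logical (k, k, Cin, Cout) view of the weights."""
        return self.W.data.reshape(self.k, self.k, self.cin, self.cout)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, p, c = self.k, self.pad, self.cin
        if k == 1:
            n, h, w, _ = x.shape
            self._cols = x.reshape(-1, c)
            self._shape = (n, h, w)
            y = self._cols @ self.W.data + self.b.data
            return y.reshape(n, h, w, self.cout)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        n, hp, wp, _ = xp.shape
        h, w = hp - 2 * p, wp - 2 * p
        cols = np.empty((n, h, w, k * k, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i * k + j, :] = xp[:, i:i + h, j:j + w, :]
        self._cols = cols.reshape(n * h * w, k * k * c)
        self._shape = (n, h, w)
        y = self._cols @ self.W.data + self.b.data
        return y.reshape(n, h, w, self.cout)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k, p, c = self.k, self.pad, self.cin
        n, h, w = self._shape
        g = gy.reshape(n * h * w, self.cout)
        self.b.grad += g.sum(axis=0)
        self.W.grad += self._cols.T @ g
        dcols = g @ self.W.data.T
        self._cols = None
        if k == 1:
            return dcols.reshape(n, h, w, c)
        dview = dcols.reshape(n, h, w, k * k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dview[:, :, :, i * k + j, :]
        return dxp[:, p:p + h, p:p + w, :] if p else dxp


class ConvTranspose2d(Layer):
    """s x s transposed convolution with stride = kernel (no overlap)."""

    def __init__(self, cin: int, cout: int, s: int = 2, *, rng: np.random.Generator):
        self.s = s
        self.cin = cin
        self.cout = cout
        self.W = Param(_he_init(rng, (cin, s * s * cout), cin))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s, o = self.s, self.cout
        n, h, w, c = x.shape
        self._x = x.reshape(n * h * w, c)
        self._shape = (n, h, w)
        y = self._x @ self.W.data  # (NHW, s*s*o)
        y = y.reshape(n, h, w, s, s, o).transpose(0, 1, 3, 2, 4, 5)
        y = np.ascontiguousarray(y).reshape(n, h * s, w * s, o)
        y += self.b.data
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        s, o, c = self.s, self.cout, self.cin
        n, h, w = self._shape
        self.b.grad += gy.reshape(-1, o).sum(axis=0)
        g = gy.reshape(n, h, s, w, s, o).transpose(0, 1, 3, 2, 4, 5)
        g = np.ascontiguousarray(g).reshape(n * h * w, s * s * o)
        self.W.grad += self._x.T @ g
        dx = g @ self.W.data.T
        self._x = None
        return dx.reshape(n, h, w, c)


class MaxPool2d(Layer):
    def __init__(self, s: int = 2):
        self.s = s

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.s
        n, h, w, c = x.shape
        xr = x.reshape(n, h // s, s, w // s, s, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(n, h // s, w // s, s * s, c)
        self._idx = xr.argmax(axis=3)
        self._shape = (n, h, w, c)
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        s = self.s
        n, h, w, c = self._shape
        gr = np.zeros((n, h // s, w // s, s * s, c), dtype=gy.dtype)
        np.put_along_axis(gr, self._idx[:, :, :, None, :], gy[:, :, :, None, :], axis=3)
        gr = gr.reshape(n, h // s, w // s, s, s, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(gr).reshape(n, h, w, c)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        ax = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean) / std
        self._xhat, self._std, self._train = xhat, std, train
        return self.gamma.data * xhat + self.beta.data

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        ax = tuple(range(gy.ndim - 1))
        self.gamma.grad += (gy * xhat).sum(axis=ax)
        self.beta.grad += gy.sum(axis=ax)
        g = self.gamma.data / std
        if not self._train:
            self._xhat = None
            return g * gy
        m1 = gy.mean(axis=ax)
        m2 = (gy * xhat).mean(axis=ax)
        dx = g * (gy - m1 - xhat * m2)
        self._xhat = None
        return dx

    # running statistics are state that must survive checkpointing
    def extra_state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_extra_state(self, st: dict[str, np.ndarray]) -> None:
        self.running_mean = st["running_mean"].copy()
        self.running_var = st["running_var"].copy()


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._mask
        self._mask = None
        return g


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        self._y = y.astype(np.float32)
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._y * (1.0 - self._y)
        self._y = None
        return g


class Dropout(Layer):
    """Inverted dropout; active only when train=True."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        g = gy * self._mask
        self._mask = None
        return g


class Linear(Layer):
    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator,
                 bias_init: float = 0.0):
        self.W = Param(_he_init(rng, (cin, cout), cin))
        self.b = Param(np.full(cout, bias_init, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        self._x = None
        return gy @ self.W.data.T


class GlobalAvgPool(Layer):
    """(N, H, W, C) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(gy[:, None, None, :], self._shape) / (h * w)
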