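"""A compact numpy neural-network engine for small detection models.

Layers implement explicit ``forward(x, train=...)`` / ``backward(dy)`` pairs
with cached activations, sufficient for the convolutional building blocks
used here: same-padded 2-D convolution (im2col + BLAS matmul), batch
normalization, SiLU, stride-1 max pooling, nearest-neighbor 2x upsampling
and channel concatenation.  Everything is float32 and fully deterministic
given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "SiLU",
    "ConvBN",
    "MaxPool2d",
    "Upsample2x",
    "Concat",
    "Add",
    "Sequential",
    "SGD",
    "sigmoid",
]


def sigmoid(x):
    return expit(x)


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # whether weight decay applies


class Module:
    def _walk_modules(self):
        """Child modules in deterministic attribute order, including ones
        nested inside lists/tuples (branch lists, bottleneck pairs)."""

        def scan(value):
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    yield from scan(item)

        for v in self.__dict__.values():
            yield from scan(v)

    def parameters(self):
        params = [v for v in self.__dict__.values() if isinstance(v, Param)]
        for child in self._walk_modules():
            params.extend(child.parameters())
        return params

    def buffers(self):
        """Non-learnable state (batch-norm running statistics), recursively."""
        bufs = []
        for child in self._walk_modules():
            bufs.extend(child.buffers())
        return bufs

    def forward(self, *xs, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, *xs, train: bool = False):
        return self.forward(*xs, train=train)


def _im2col(xp: np.ndarray, k: int, stride: int):
    """(N,C,Hp,Wp) padded input -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, hp, wp = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, shape, k: int, stride: int):
    """Scatter-add patch gradients back onto the padded input."""
    n, c, hp, wp = shape
    _, _, l = dcols.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    d = dcols.reshape(n, c, k, k, ho, wo)
    dxp = np.zeros(shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[:, :, i, j]
    return dxp


class Conv2d(Module):
    """Same-padded dense convolution (pad = k//2), optional bias."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        if cin < 1 or cout < 1:
            raise ValueError("channel counts must be positive")
        if k < 1 or k % 2 == 0:
            raise ValueError("kernel size must be odd and positive")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.weight = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.bias = Param(np.zeros(cout), decay=False) if bias else None
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2
        self._cache = None

    def forward(self, x, train: bool = False):
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        if self.k == 1 and self.stride == 1:  # pointwise: plain matmul, no im2col
            n, c, h, w = x.shape
            cols, ho, wo = np.ascontiguousarray(x).reshape(n, c, h * w), h, w
            xp_shape = x.shape
        else:
            p = self.pad
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else np.ascontiguousarray(x)
            cols, ho, wo = _im2col(xp, self.k, self.stride)
            xp_shape = xp.shape
        w2 = self.weight.value.reshape(self.cout, -1)
        y = np.matmul(w2, cols)  # (N, cout, L)
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        self._cache = (cols, xp_shape, x.shape)
        return y.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, dy):
        cols, xp_shape, x_shape = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, -1)
        self.weight.grad += np.tensordot(dyf, cols, axes=([0, 2], [0, 2])).reshape(
            self.weight.value.shape
        )
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=(0, 2))
        w2 = self.weight.value.reshape(self.cout, -1)
        dcols = np.matmul(w2.T, dyf)
        if self.k == 1 and self.stride == 1:
            return dcols.reshape(x_shape)
        dxp = _col2im(dcols, xp_shape, self.k, self.stride)
        p = self.pad
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.03):
        self.gamma = Param(np.ones(c), decay=False)
        self.beta = Param(np.zeros(c), decay=False)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, train: bool = False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv_std, train, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        if not train:
            return dy * g
        m = shape[0] * shape[2] * shape[3]
        dxhat = dy * self.gamma.value[None, :, None, None]
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return term * inv_std[None, :, None, None]


class SiLU(Module):
    def forward(self, x, train: bool = False):
        s = sigmoid(x)
        self._cache = (x, s)
        return x * s

    def backward(self, dy):
        x, s = self._cache
        return dy * (s * (1.0 + x * (1.0 - s)))


class ConvBN(Module):
    """Conv -> BatchNorm -> SiLU, the standard unit of the backbone/neck."""

    def __init__(self, cin, cout, k, stride=1, rng=None, act: bool = True):
        self.conv = Conv2d(cin, cout, k, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = SiLU() if act else None

    def forward(self, x, train: bool = False):
        y = self.bn(self.conv(x, train=train), train=train)
        return self.act(y, train=train) if self.act else y

    def backward(self, dy):
        if self.act:
            dy = self.act.backward(dy)
        return self.conv.backward(self.bn.backward(dy))


class MaxPool2d(Module):
    """Stride-1 same-padded max pooling (as used inside SPPF)."""

    def __init__(self, k: int = 5):
        self.k = k
        self.pad = k // 2
        self._cache = None

    def forward(self, x, train: bool = False):
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        n, c, hp, wp = xp.shape
        h, w = x.shape[2], x.shape[3]
        best = np.full((n, c, h, w), -np.inf, dtype=x.dtype)
        arg = np.zeros((n, c, h, w), dtype=np.int16)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            window = xp[:, :, i : i + h, j : j + w]
            better = window > best
            best = np.where(better, window, best)
            arg = np.where(better, np.int16(idx), arg)
        self._cache = (arg, xp.shape, x.shape)
        return best

    def backward(self, dy):
        arg, xp_shape, x_shape = self._cache
        k, p = self.k, self.pad
        h, w = x_shape[2], x_shape[3]
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            mask = arg == idx
            if mask.any():
                dxp[:, :, i : i + h, j : j + w] += np.where(mask, dy, 0.0)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class Upsample2x(Module):
    def forward(self, x, train: bool = False):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        n, c, h2, w2 = dy.shape
        return dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class Concat(Module):
    """Channel concatenation of any number of inputs."""

    def forward(self, *xs, train: bool = False):
        self._sizes = [x.shape[1] for x in xs]
        return np.concatenate(xs, axis=1)

    def backward(self, dy):
        out, at = [], 0
        for c in self._sizes:
            out.append(dy[:, at : at + c])
            at += c
        return out


class Add(Module):
    def forward(self, a, b, train: bool = False):
        return a + b

    def backward(self, dy):
        return [dy, dy]


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x, train: bool = False):
        for m in self.mods:
            x = m(x, train=train)
        return x

    def backward(self, dy):
        for m in reversed(self.mods):
            dy = m.backward(dy)
        return dy


class SGD:
    """SGD with momentum and decoupled-from-BN weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.937, weight_decay: float = 0.0005):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if p.decay and self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v
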