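"""Minimal CPU neural-network layers with explicit backpropagation.

Implements exactly the primitives the lifetime-regression network needs
— 2D convolution (im2col), batch normalization, SiLU/ReLU activations,
stride-1 max pooling, nearest-neighbor upsampling, concatenation — each
as a module with ``forward(x, train)`` caching whatever ``backward(g)``
needs.  Tensors are numpy arrays laid out (N, C, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)


class Module:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Module):
    """k x k convolution, 'same' padding for odd k, optional stride."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU-family nets
        self.weight = Parameter(rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.k, self.stride, self.pad = k, stride, k // 2
        self.c_in, self.c_out = c_in, c_out

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # win: (N, C, Ho, Wo, k, k)
        self._cols = win
        self._x_shape = x.shape
        out = np.einsum("nchwij,ocij->nohw", win, self.weight.data, optimize=True)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += np.einsum("nohw,nchwij->ocij", grad, self._cols, optimize=True)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        n, c, h, w = self._x_shape
        p, k, s = self.pad, self.k, self.stride
        gx = np.zeros((n, c, h + 2 * p, w + 2 * p))
        gcols = np.einsum("nohw,ocij->nchwij", grad, self.weight.data, optimize=True)
        ho, wo = grad.shape[2], grad.shape[3]
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + ho * s : s, j : j + wo * s : s] += gcols[:, :, :, :, i, j]
        return gx[:, :, p : p + h, p : p + w]


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.eps, self.momentum = eps, momentum

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std, train, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.gamma.data[None, :, None, None]
        if not train:
            return gxhat / std[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        # full batch-norm backward through batch statistics
        term1 = gxhat
        term2 = gxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (term1 - term2 - term3) / std[None, :, None, None]


class SiLU(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        sig = 1.0 / (1.0 + np.exp(-x))
        self._cache = (x, sig)
        return x * sig

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, sig = self._cache
        return grad * (sig * (1.0 + x * (1.0 - sig)))


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Module):
    """Stride-1, same-size max pooling (used by SPPF; default 5x5)."""

    def __init__(self, k: int = 5):
        self.k, self.pad = k, k // 2

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        flat = win.reshape(*win.shape[:4], k * k)
        idx = flat.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        n, c, h, w = shape
        p, k = self.pad, self.k
        gx = np.zeros((n, c, h + 2 * p, w + 2 * p))
        ii, jj = np.unravel_index(idx, (k, k))
        ny, cy, hy, wy = np.indices(idx.shape)
        np.add.at(gx, (ny, cy, hy + ii, wy + jj), grad)
        return gx[:, :, p : p + h, p : p + w]


class Upsample2x(Module):
    """Nearest-neighbor 2x spatial upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def parameters(self) -> list[Parameter]:
        return [p for m in self.mods for p in m.parameters()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for m in self.mods:
            x = m.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self.mods):
            grad = m.backward(grad)
        return grad


def cbl(c_in: int, c_out: int, k: int = 3, stride: int = 1,
        rng: np.random.Generator | None = None) -> Sequential:
    """CBL block: Conv (no bias) + BatchNorm + SiLU."""
    return Sequential(
        Conv2d(c_in, c_out, k=k, stride=stride, bias=False, rng=rng),
        BatchNorm2d(c_out),
        SiLU(),
    )


class Bottleneck(Module):
    """Residual bottleneck: CBL(1x1) -> CBL(3x3), added to the input."""

    def __init__(self, c: int, rng: np.random.Generator | None = None):
        self.body = Sequential(*cbl(c, c, k=1, rng=rng).mods, *cbl(c, c, k=3, rng=rng).mods)

    def parameters(self) -> list[Parameter]:
        return self.body.parameters()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x + self.body.forward(x, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad + self.body.backward(grad)


class C3(Module):
    """Cross-stage block: two 1x1 branches, one through ``n`` bottlenecks,
    concatenated and fused by a 1x1 CBL."""

    def __init__(self, c_in: int, c_out: int, n: int = 1,
                 rng: np.random.Generator | None = None):
        c_mid = max(2, c_out // 2)
        self.cv1 = cbl(c_in, c_mid, k=1, rng=rng)
        self.cv2 = cbl(c_in, c_mid, k=1, rng=rng)
        self.blocks = Sequential(*[Bottleneck(c_mid, rng=rng) for _ in range(n)])
        self.cv3 = cbl(2 * c_mid, c_out, k=1, rng=rng)
        self.c_mid = c_mid

    def parameters(self) -> list[Parameter]:
        return (self.cv1.parameters() + self.cv2.parameters()
                + self.blocks.parameters() + self.cv3.parameters())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        a = self.blocks.forward(self.cv1.forward(x, train), train)
        b = self.cv2.forward(x, train)
        return self.cv3.forward(np.concatenate([a, b], axis=1), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.cv3.backward(grad)
        ga, gb = g[:, : self.c_mid], g[:, self.c_mid :]
        gx = self.cv1.backward(self.blocks.backward(ga))
        gx += self.cv2.backward(gb)
        return gx


class SPPF(Module):
    """Spatial pyramid pooling (fast): 1x1 CBL, three chained 5x5 max
    pools, concatenation of all four maps, 1x1 CBL fuse."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        c_mid = max(2, c_in // 2)
        self.cv1 = cbl(c_in, c_mid, k=1, rng=rng)
        self.pools = [MaxPool2d(5), MaxPool2d(5), MaxPool2d(5)]
        self.cv2 = cbl(4 * c_mid, c_out, k=1, rng=rng)
        self.c_mid = c_mid

    def parameters(self) -> list[Parameter]:
        return self.cv1.parameters() + self.cv2.parameters()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y0 = self.cv1.forward(x, train)
        y1 = self.pools[0].forward(y0, train)
        y2 = self.pools[1].forward(y1, train)
        y3 = self.pools[2].forward(y2, train)
        return self.cv2.forward(np.concatenate([y0, y1, y2, y3], axis=1), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.cv2.backward(grad)
        c = self.c_mid
        g0, g1, g2, g3 = (g[:, i * c : (i + 1) * c] for i in range(4))
        g2 = g2 + self.pools[2].backward(g3)
        g1 = g1 + self.pools[1].backward(g2)
        g0 = g0 + self.pools[0].backward(g1)
        return self.cv1.backward(g0)


class AdamW:
    """AdamW: decoupled weight decay, bias-corrected first/second moments."""

    def __init__(self, params: list[Parameter], lr: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)
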