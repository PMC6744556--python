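"""Minimal float32 convolutional-network primitives (NumPy + numba).

This module implements exactly the layer set the fully residual U-Net
needs -- zero-padded 3x3/1x1 convolutions, ELU, inverted dropout, 2x2
average pooling, 2x2 nearest-neighbour upsampling, a fused sigmoid /
binary-cross-entropy head, and the Adam optimiser.  Tensors are laid out
NCHW in float32; the 3x3 convolution inner loops run over the contiguous
width axis, which lets numba emit vectorised FMA code on a single core.

The gradient of a zero-padded 3x3 convolution with respect to its input
is itself a zero-padded 3x3 convolution with spatially flipped, channel-
transposed weights, so the backward pass reuses the forward kernel.
All gradients are exact; the test suite checks them against central
finite differences.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F32 = np.float32


# ----------------------------------------------------------------------
# numba kernels
# ----------------------------------------------------------------------

@njit(fastmath=True, cache=True)
def _conv3x3_kernel(xp, W, b, out):
    """out[n,co] = b[co] + sum_ci conv(xp[n,ci], W[co,ci]); xp is padded.

    For each (n, y) an (Co, W) accumulator block stays L1-resident while
    the input rows stream through once per tap, so the output is written
    a single time instead of once per (ci, tap).
    """
    N, Co, H, Wd = out.shape
    Ci = xp.shape[1]
    acc = np.empty((Co, Wd), dtype=F32)
    for n in range(N):
        for y in range(H):
            for co in range(Co):
                for x in range(Wd):
                    acc[co, x] = b[co]
            for ci in range(Ci):
                for ky in range(3):
                    src = xp[n, ci, y + ky]
                    for co in range(Co):
                        w0 = W[co, ci, ky, 0]
                        w1 = W[co, ci, ky, 1]
                        w2 = W[co, ci, ky, 2]
                        a = acc[co]
                        for x in range(Wd):
                            a[x] += w0 * src[x] + w1 * src[x + 1] + w2 * src[x + 2]
            for co in range(Co):
                for x in range(Wd):
                    out[n, co, y, x] = acc[co, x]


@njit(fastmath=True, cache=True)
def _conv3x3_grad_w(xp, g, gW, gb):
    """Accumulate weight/bias gradients; xp padded input, g output grad."""
    N, Co, H, Wd = g.shape
    Ci = xp.shape[1]
    for n in range(N):
        for y in range(H):
            for co in range(Co):
                grow = g[n, co, y]
                s = F32(0.0)
                for x in range(Wd):
                    s += grow[x]
                gb[co] += s
            for ky in range(3):
                for ci in range(Ci):
                    src = xp[n, ci, y + ky]
                    for co in range(Co):
                        grow = g[n, co, y]
                        s0 = F32(0.0)
                        s1 = F32(0.0)
                        s2 = F32(0.0)
                        for x in range(Wd):
                            v = grow[x]
                            s0 += v * src[x]
                            s1 += v * src[x + 1]
                            s2 += v * src[x + 2]
                        gW[co, ci, ky, 0] += s0
                        gW[co, ci, ky, 1] += s1
                        gW[co, ci, ky, 2] += s2


@njit(fastmath=True, cache=True)
def _elu_fwd(x, y, alpha):
    n = x.size
    xf = x.ravel()
    yf = y.ravel()
    for i in range(n):
        v = xf[i]
        yf[i] = v if v > 0 else alpha * (np.exp(v) - F32(1.0))


@njit(fastmath=True, cache=True)
def _elu_bwd(x, y, g, gx, alpha):
    n = x.size
    xf = x.ravel()
    yf = y.ravel()
    gf = g.ravel()
    of = gx.ravel()
    for i in range(n):
        of[i] = gf[i] if xf[i] > 0 else gf[i] * (yf[i] + alpha)


# ----------------------------------------------------------------------
# layers
# ----------------------------------------------------------------------

class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def _pad1(x: np.ndarray) -> np.ndarray:
    """Zero-pad the two spatial axes of an NCHW tensor by one pixel."""
    N, C, H, W = x.shape
    out = np.zeros((N, C, H + 2, W + 2), dtype=F32)
    out[:, :, 1:-1, 1:-1] = x
    return out


class Conv2D:
    """Zero-padded stride-1 convolution, kernel 1 or 3, weights (Co,Ci,k,k)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, zero_init: bool = False):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        shape = (c_out, c_in, kernel, kernel)
        w = (np.zeros(shape, dtype=F32) if zero_init
             else he_uniform(rng, shape, fan_in=kernel * kernel * c_in))
        self.W = Param(w)
        self.b = Param(np.zeros(c_out, dtype=F32))
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=F32)
        N, _, H, Wd = x.shape
        if self.kernel == 1:
            xm = x.reshape(N, self.c_in, H * Wd)
            y = np.matmul(self.W.value[:, :, 0, 0], xm)
            y += self.b.value[:, None]
            self._cache = xm
            return y.reshape(N, self.c_out, H, Wd)
        xp = _pad1(x)
        out = np.empty((N, self.c_out, H, Wd), dtype=F32)
        _conv3x3_kernel(xp, self.W.value, self.b.value, out)
        self._cache = xp
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = np.ascontiguousarray(gy, dtype=F32)
        N, _, H, Wd = gy.shape
        if self.kernel == 1:
            xm = self._cache
            self._cache = None
            gm = gy.reshape(N, self.c_out, H * Wd)
            self.b.grad += gm.sum(axis=(0, 2))
            self.W.grad[:, :, 0, 0] += np.tensordot(gm, xm, axes=([0, 2], [0, 2]))
            gx = np.matmul(self.W.value[:, :, 0, 0].T, gm)
            return gx.reshape(N, self.c_in, H, Wd)
        xp = self._cache
        self._cache = None
        _conv3x3_grad_w(xp, gy, self.W.grad, self.b.grad)
        # input gradient: convolve gy with flipped, channel-transposed weights
        Wt = np.ascontiguousarray(
            self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        gp = _pad1(gy)
        gx = np.empty((N, self.c_in, H, Wd), dtype=F32)
        _conv3x3_kernel(gp, Wt, np.zeros(self.c_in, dtype=F32), gx)
        return gx


class ELU:
    def __init__(self, alpha: float = 1.0):
        self.alpha = F32(alpha)
        self._cache = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=F32)
        y = np.empty_like(x)
        _elu_fwd(x, y, self.alpha)
        self._cache = (x, y)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, y = self._cache
        self._cache = None
        gy = np.ascontiguousarray(gy, dtype=F32)
        gx = np.empty_like(gy)
        _elu_bwd(x, y, gy, gx, self.alpha)
        return gx


class Dropout:
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = F32(1.0 - self.rate)
        mask = self.rng.random(x.shape, dtype=np.float32) >= self.rate
        self._mask = mask
        return np.where(mask, x / keep, F32(0.0)).astype(F32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        keep = F32(1.0 - self.rate)
        out = np.where(self._mask, gy / keep, F32(0.0)).astype(F32, copy=False)
        self._mask = None
        return out


class AvgPool2:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        return x.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return (gy * F32(0.25)).repeat(2, axis=2).repeat(2, axis=3)


class UpsampleNN2:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        N, C, H2, W2 = gy.shape
        return gy.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))


# ----------------------------------------------------------------------
# loss and optimiser
# ----------------------------------------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    p = sigmoid(z)
    eps = F32(1e-7)
    pc = np.clip(p, eps, 1 - eps)
    loss = float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())
    gz = ((p - y) / F32(p.size)).astype(F32, copy=False)
    return loss, gz


class Adam:
    """Adam with bias correction (Keras defaults: eps 1e-7)."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.value -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(F32, copy=False)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0
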