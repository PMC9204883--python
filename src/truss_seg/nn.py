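"""Minimal CNN layer library with explicit reverse-mode gradients.

Everything the translation networks need — strided convolution, transposed
convolution, instance normalization, ReLU family, tanh, residual blocks,
Adam — implemented on numpy with a functional forward/backward contract:

    y, cache = layer.forward(x)
    dx = layer.backward(dy, cache)   # parameter grads accumulate in-place

Caches travel with the call rather than living on the layer, so one layer
may appear several times in a computation graph (a cycle-consistency pass
runs each generator twice) and be backpropagated through each occurrence
independently.  Convolutions are im2col + GEMM; every layer is exercised
by finite-difference gradient checks in the test suite.

Tensors are NCHW ``float32`` by default (``float64`` available for
gradient checking).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "relu",
    "relu_grad",
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Residual",
    "Adam",
]


def relu(v):
    """Rectified linear unit: 0 for v < 0, v for v >= 0 (elementwise)."""
    v = np.asarray(v)
    out = np.where(v < 0, 0, v)
    return out.item() if out.ndim == 0 else out


def relu_grad(v):
    """Derivative of :func:`relu`: 0 for v < 0, 1 for v >= 0."""
    v = np.asarray(v)
    out = np.where(v < 0, 0.0, 1.0)
    return out.item() if out.ndim == 0 else out


class Parameter:
    """A learnable array and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Module:
    def parameters(self) -> list[Parameter]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x):
        raise NotImplementedError

    def backward(self, dy, cache):
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, c)
        return dy


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> (N * Ho * Wo, C * k * k) patch matrix."""
    n, c, h, w = x.shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (ho, wo)


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col`: scatter-add patches back to an image."""
    n, c, h, w = xshape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[
                :, :, i, j
            ]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


class Conv2d(Module):
    """2-D convolution (cross-correlation), zero padding, optional stride."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out
        w = rng.normal(0.0, 0.02, size=(c_in * kernel * kernel, c_out))
        self.W = Parameter(w.astype(dtype), "W")
        self.b = Parameter(np.zeros(c_out, dtype=dtype), "b")

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x):
        n = x.shape[0]
        cols, (ho, wo) = _im2col(x, self.kernel, self.stride, self.pad)
        y = cols @ self.W.value + self.b.value
        y = y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)
        return y, (cols, x.shape)

    def backward(self, dy, cache):
        cols, xshape = cache
        n, _, ho, wo = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        self.W.grad += cols.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ self.W.value.T
        return _col2im(dcols, xshape, self.kernel, self.stride, self.pad)


class ConvTranspose2d(Module):
    """Fractionally-strided convolution (the conv adjoint), for upsampling.

    Output size is ``(H - 1) * stride - 2 * pad + kernel + output_pad``;
    the defaults (kernel 3, stride 2, pad 1, output_pad 1) exactly double
    spatial dimensions, inverting a stride-2 ``Conv2d``'s halving.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        stride: int = 2,
        pad: int = 1,
        output_pad: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride = kernel, stride
        self.pad, self.output_pad = pad, output_pad
        self.c_in, self.c_out = c_in, c_out
        w = rng.normal(0.0, 0.02, size=(c_in, c_out * kernel * kernel))
        self.W = Parameter(w.astype(dtype), "W")
        self.b = Parameter(np.zeros(c_out, dtype=dtype), "b")

    def parameters(self):
        return [self.W, self.b]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        s, k, p, op = self.stride, self.kernel, self.pad, self.output_pad
        return (h - 1) * s - 2 * p + k + op, (w - 1) * s - 2 * p + k + op

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        ho, wo = self._out_hw(h, w)
        xf = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        t = (xf @ self.W.value).reshape(n, h, w, self.c_out, k, k)
        t = t.transpose(0, 3, 4, 5, 1, 2)  # (N, Co, k, k, H, W)
        full_h, full_w = (h - 1) * s + k, (w - 1) * s + k
        yfull = np.zeros((n, self.c_out, full_h, full_w), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                yfull[:, :, i : i + s * h : s, j : j + s * w : s] += t[:, :, i, j]
        y = yfull[:, :, p : p + ho, p : p + wo]
        y = y + self.b.value[None, :, None, None]
        return y, (xf, x.shape)

    def backward(self, dy, cache):
        xf, xshape = cache
        n, c, h, w = xshape
        k, s, p = self.kernel, self.stride, self.pad
        ho, wo = self._out_hw(h, w)
        full_h, full_w = (h - 1) * s + k, (w - 1) * s + k
        dyfull = np.zeros((n, self.c_out, full_h, full_w), dtype=dy.dtype)
        dyfull[:, :, p : p + ho, p : p + wo] = dy
        dt = np.empty((n, self.c_out, k, k, h, w), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dt[:, :, i, j] = dyfull[:, :, i : i + s * h : s, j : j + s * w : s]
        dtf = dt.transpose(0, 4, 5, 1, 2, 3).reshape(n * h * w, self.c_out * k * k)
        self.W.grad += xf.T @ dtf
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dxf = dtf @ self.W.value.T
        return dxf.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class InstanceNorm2d(Module):
    """Per-image, per-channel normalization with learnable scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype), "gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), "beta")

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        return y, (xhat, inv_std)

    def backward(self, dy, cache):
        xhat, inv_std = cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv_std * (dxhat - m1 - xhat * m2)


class ReLU(Module):
    def forward(self, x):
        mask = x >= 0
        return np.where(mask, x, 0), mask

    def backward(self, dy, mask):
        return np.where(mask, dy, 0)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        mask = x >= 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, dy, mask):
        return np.where(mask, dy, self.slope * dy)


class Tanh(Module):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, y):
        return dy * (1.0 - y * y)


class Residual(Module):
    """``y = x + body(x)``; with zero-initialized body convs this is identity."""

    def __init__(self, body: Sequential):
        self.body = body

    def parameters(self):
        return self.body.parameters()

    def forward(self, x):
        h, c = self.body.forward(x)
        return x + h, c

    def backward(self, dy, cache):
        return dy + self.body.backward(dy, cache)


class Adam:
    """Adam over an explicit parameter list (decoupled from modules)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def state_arrays(self) -> list[np.ndarray]:
        return self.m + self.v
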