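"""Minimal CPU neural-network core used by the denoiser and clustering CNN.

Plain-numpy layers with explicit forward/backward passes: im2col-based 2D
convolution, transposed convolution (as the adjoint of convolution), batch
normalization, linear, ReLU/sigmoid/softmax, and an Adam optimizer.  All
randomness is injected through ``numpy.random.Generator`` instances so runs
are bit-reproducible on CPU.

Conventions: activations are float32 arrays shaped ``(N, C, H, W)`` for
spatial layers and ``(N, D)`` for dense layers.  ``forward(x, train=...)``
caches whatever ``backward(grad)`` needs; ``backward`` returns the gradient
w.r.t. the layer input and accumulates parameter gradients in place.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "Sigmoid",
    "Softmax",
    "Flatten",
    "Reshape",
    "GlobalAvgPool2d",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("val", "grad")

    def __init__(self, val: np.ndarray):
        self.val = np.asarray(val, dtype=np.float32)
        self.grad = np.zeros_like(self.val)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Extract k×k patches: (N,C,H,W) -> (N, OH, OW, C, k, k)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,H',W',k,k)
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def _col2im(
    cols: np.ndarray, hw: tuple[int, int], k: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (N,C,H,W)."""
    n, oh, ow, c, _, _ = cols.shape
    h, w = hw
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    colsT = cols.transpose(0, 3, 1, 2, 4, 5)  # (N,C,OH,OW,k,k)
    for kh in range(k):
        for kw in range(k):
            out[:, :, kh : kh + stride * oh : stride,
                kw : kw + stride * ow : stride] += colsT[:, :, :, :, kh, kw]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2D convolution, square kernel, He-initialised."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, scale, (cout, cin * k * k)))
        self.b = Param(np.zeros(cout))
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad

    def params(self):
        return [self.w, self.b]

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[1] != self.cin:
            raise ValueError(f"Conv2d expects (N,{self.cin},H,W), got {x.shape}")
        n = x.shape[0]
        self._hw = x.shape[2:]
        cols = _im2col(x, self.k, self.stride, self.pad)
        self._oh, self._ow = cols.shape[1], cols.shape[2]
        self._cols = cols.reshape(n * self._oh * self._ow, -1)
        out = self._cols @ self.w.val.T + self.b.val
        return out.reshape(n, self._oh, self._ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n = grad.shape[0]
        g2 = grad.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.w.grad += g2.T @ self._cols
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.w.val).reshape(
            n, self._oh, self._ow, self.cin, self.k, self.k
        )
        return _col2im(dcols, self._hw, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Transposed 2D convolution (the adjoint of Conv2d), used for upsampling."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 pad: int = 1, output_pad: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, scale, (cin, cout * k * k)))
        self.b = Param(np.zeros(cout))
        self.cin, self.cout = cin, cout
        self.k, self.stride, self.pad, self.output_pad = k, stride, pad, output_pad

    def params(self):
        return [self.w, self.b]

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p, op = self.k, self.stride, self.pad, self.output_pad
        return (h - 1) * s - 2 * p + k + op, (w - 1) * s - 2 * p + k + op

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[1] != self.cin:
            raise ValueError(f"ConvTranspose2d expects (N,{self.cin},H,W), got {x.shape}")
        n, _, h, w = x.shape
        self._in_hw = (h, w)
        oh, ow = self.out_hw(h, w)
        self._x2 = x.transpose(0, 2, 3, 1).reshape(-1, self.cin)
        cols = (self._x2 @ self.w.val).reshape(n, h, w, self.cout, self.k, self.k)
        # scatter patches onto the upsampled grid; output_pad extends the
        # canvas so stride-2 exactly doubles H and W for k=3, pad=1
        out = _col2im(cols, (oh + self.output_pad, ow + self.output_pad),
                      self.k, self.stride, self.pad)
        out = out[:, :, :oh, :ow]
        return out + self.b.val[None, :, None, None]

    def backward(self, grad):
        n = grad.shape[0]
        h, w = self._in_hw
        self.b.grad += grad.sum(axis=(0, 2, 3))
        if self.output_pad:
            grad = np.pad(grad, ((0, 0), (0, 0),
                                 (0, self.output_pad), (0, self.output_pad)))
        gcols = _im2col(grad, self.k, self.stride, self.pad)  # (N,≥h,≥w,cout,k,k)
        gcols = np.ascontiguousarray(gcols[:, :h, :w]).reshape(n * h * w, -1)
        self.w.grad += self._x2.T @ gcols
        dx2 = gcols @ self.w.val.T
        return dx2.reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        self._train = train
        return self.gamma.val[None, :, None, None] * self._xhat \
            + self.beta.val[None, :, None, None]

    def backward(self, grad):
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.val[None, :, None, None]
        if not self._train:
            return g * self._istd[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (self._istd[None, :, None, None] / m) * (
            m * g - sum_g - self._xhat * sum_gx
        )


class Linear(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / din)
        self.w = Param(rng.normal(0.0, scale, (din, dout)))
        self.b = Param(np.zeros(dout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.val + self.b.val

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.val.T


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Softmax(Layer):
    """Row-wise softmax over (N, D)."""

    def forward(self, x, train=True):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=1, keepdims=True)
        return self._y

    def backward(self, grad):
        y = self._y
        return y * (grad - (grad * y).sum(axis=1, keepdims=True))


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape  # per-sample shape

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._shape)


class GlobalAvgPool2d(Layer):
    def forward(self, x, train=True):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        h, w = self._hw
        return np.broadcast_to(
            grad[:, :, None, None] / (h * w),
            grad.shape + (h, w),
        ).copy()


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.val) for p in params]
        self.v = [np.zeros_like(p.val) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.val -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
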