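"""Minimal CPU layer library with explicit backward passes.

All tensors are ``float64`` numpy arrays in NCHW layout.  Every layer caches
what its backward pass needs during ``forward`` and releases it on
``backward``; layers are therefore stateful and not reentrant, which is fine
for the simple alternating optimization used here.

The library is deliberately small: convolution, fractionally strided
(transposed) convolution, dense, instance normalization, LeakyReLU, tanh,
channel softmax, and Adam.  Gradients are exact adjoints of the forward
linear maps and are verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "Dense",
    "InstanceNorm2d",
    "LeakyReLU",
    "MaxPool2d",
    "Tanh",
    "Sigmoid",
    "AffineScale",
    "ChannelSoftmax",
    "Reshape",
    "Sequential",
    "Adam",
    "init_weight",
]


def init_weight(rng: np.random.Generator, shape, scale: float = 0.02) -> np.ndarray:
    """Normal(0, scale) initialization (DCGAN convention)."""
    return rng.normal(0.0, scale, size=shape)


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def flops(self, in_shape: tuple) -> tuple[int, tuple]:
        """(operation count, output shape) under the documented convention:
        only multiply–accumulate layers are counted, a MAC as 2 operations
        and a bias add as 1 per output element."""
        return 0, in_shape


class Conv2d(Layer):
    """2-D convolution (cross-correlation), NCHW, zero padding."""

    def __init__(self, c_in, c_out, kernel, stride=1, pad=0, bias=True, rng=None):
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, pad
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = Param(init_weight(rng, (c_out, c_in, kernel, kernel)))
        self.b = Param(np.zeros(c_out)) if bias else None
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_size(self, h: int) -> int:
        return (h + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        s, k, p = self.stride, self.k, self.pad
        ho, wo = self.out_size(h), self.out_size(w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out = np.zeros((n, self.c_out, ho, wo))
        Wm = self.W.value
        for pp in range(k):
            for qq in range(k):
                xs = xp[:, :, pp : pp + s * ho : s, qq : qq + s * wo : s]
                out += np.einsum("ncij,oc->noij", xs, Wm[:, :, pp, qq], optimize=True)
        if self.b is not None:
            out += self.b.value[None, :, None, None]
        if train:
            self._cache = (xp, x.shape, (ho, wo))
        return out

    def backward(self, dout):
        xp, x_shape, (ho, wo) = self._cache
        self._cache = None
        s, k, p = self.stride, self.k, self.pad
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        Wm = self.W.value
        for pp in range(k):
            for qq in range(k):
                xs = xp[:, :, pp : pp + s * ho : s, qq : qq + s * wo : s]
                self.W.grad[:, :, pp, qq] += np.einsum(
                    "noij,ncij->oc", dout, xs, optimize=True
                )
                dxp[:, :, pp : pp + s * ho : s, qq : qq + s * wo : s] += np.einsum(
                    "noij,oc->ncij", dout, Wm[:, :, pp, qq], optimize=True
                )
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp

    def flops(self, in_shape):
        n, c, h, w = in_shape
        ho, wo = self.out_size(h), self.out_size(w)
        macs = n * self.c_out * ho * wo * self.c_in * self.k * self.k
        ops = 2 * macs + (n * self.c_out * ho * wo if self.b is not None else 0)
        return ops, (n, self.c_out, ho, wo)


class ConvTranspose2d(Layer):
    """Fractionally strided convolution: out = (in-1)*stride - 2*pad + kernel.

    The forward map is the exact adjoint of the matching :class:`Conv2d`,
    which is what "stride 1/2" upsampling means.
    """

    def __init__(self, c_in, c_out, kernel, stride=2, pad=1, bias=True, rng=None):
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, pad
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = Param(init_weight(rng, (c_in, c_out, kernel, kernel)))
        self.b = Param(np.zeros(c_out)) if bias else None
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_size(self, h: int) -> int:
        return (h - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        s, k, p = self.stride, self.k, self.pad
        ho, wo = self.out_size(h), self.out_size(w)
        # accumulate into a padded buffer, then crop the virtual padding
        yp = np.zeros((n, self.c_out, (h - 1) * s + k, (w - 1) * s + k))
        Wm = self.W.value
        for pp in range(k):
            for qq in range(k):
                yp[:, :, pp : pp + s * h : s, qq : qq + s * w : s] += np.einsum(
                    "ncij,co->noij", x, Wm[:, :, pp, qq], optimize=True
                )
        out = yp[:, :, p : p + ho, p : p + wo]
        if self.b is not None:
            out = out + self.b.value[None, :, None, None]
        if train:
            self._cache = (x, (ho, wo))
        return out

    def backward(self, dout):
        x, (ho, wo) = self._cache
        self._cache = None
        n, c, h, w = x.shape
        s, k, p = self.stride, self.k, self.pad
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        dyp = np.zeros((n, self.c_out, (h - 1) * s + k, (w - 1) * s + k))
        dyp[:, :, p : p + ho, p : p + wo] = dout
        dx = np.zeros_like(x)
        Wm = self.W.value
        for pp in range(k):
            for qq in range(k):
                dys = dyp[:, :, pp : pp + s * h : s, qq : qq + s * w : s]
                self.W.grad[:, :, pp, qq] += np.einsum(
                    "ncij,noij->co", x, dys, optimize=True
                )
                dx += np.einsum("noij,co->ncij", dys, Wm[:, :, pp, qq], optimize=True)
        return dx

    def flops(self, in_shape):
        n, c, h, w = in_shape
        ho, wo = self.out_size(h), self.out_size(w)
        # every input element multiplies the full kernel support
        macs = n * self.c_in * h * w * self.c_out * self.k * self.k
        ops = 2 * macs + (n * self.c_out * ho * wo if self.b is not None else 0)
        return ops, (n, self.c_out, ho, wo)


class Dense(Layer):
    def __init__(self, n_in, n_out, bias=True, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_in, self.n_out = n_in, n_out
        self.W = Param(init_weight(rng, (n_in, n_out)))
        self.b = Param(np.zeros(n_out)) if bias else None
        self._x = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        out = x @ self.W.value
        if self.b is not None:
            out += self.b.value
        if train:
            self._x = x
        return out

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        if self.b is not None:
            self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.value.T
        self._x = None
        return dx

    def flops(self, in_shape):
        n = in_shape[0]
        macs = n * self.n_in * self.n_out
        return 2 * macs + (n * self.n_out if self.b is not None else 0), (n, self.n_out)


class InstanceNorm2d(Layer):
    """Per-sample per-channel normalization over the spatial axes."""

    def __init__(self, c, eps=1e-5, affine=False):
        self.c, self.eps, self.affine = c, eps, affine
        self.gamma = Param(np.ones(c)) if affine else None
        self.beta = Param(np.zeros(c)) if affine else None
        self._cache = None

    def params(self):
        return [self.gamma, self.beta] if self.affine else []

    def forward(self, x, train=True):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        out = xhat
        if self.affine:
            out = xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return out

    def backward(self, dout):
        xhat, inv = self._cache
        self._cache = None
        if self.affine:
            self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
            self.beta.grad += dout.sum(axis=(0, 2, 3))
            dxhat = dout * self.gamma.value[None, :, None, None]
        else:
            dxhat = dout
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=True):
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dout):
        dx = np.where(self._mask, dout, self.slope * dout)
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """Max pooling with overlapping windows (kernel 3, stride 2, pad 1 in the
    ResNet-style encoder)."""

    def __init__(self, kernel=3, stride=2, pad=1):
        self.k, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def out_size(self, h):
        return (h + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        s, k, p = self.stride, self.k, self.pad
        ho, wo = self.out_size(h), self.out_size(w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        stack = np.empty((k * k, n, c, ho, wo))
        for pp in range(k):
            for qq in range(k):
                stack[pp * k + qq] = xp[:, :, pp : pp + s * ho : s, qq : qq + s * wo : s]
        arg = stack.argmax(axis=0)
        out = np.take_along_axis(stack, arg[None], axis=0)[0]
        if train:
            self._cache = (arg, x.shape, (ho, wo))
        return out

    def backward(self, dout):
        arg, x_shape, (ho, wo) = self._cache
        self._cache = None
        n, c, h, w = x_shape
        s, k, p = self.stride, self.k, self.pad
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for pp in range(k):
            for qq in range(k):
                sel = arg == pp * k + qq
                view = dxp[:, :, pp : pp + s * ho : s, qq : qq + s * wo : s]
                view += np.where(sel, dout, 0.0)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp

    def flops(self, in_shape):
        n, c, h, w = in_shape
        return 0, (n, c, self.out_size(h), self.out_size(w))


class Tanh(Layer):
    def forward(self, x, train=True):
        out = np.tanh(x)
        if train:
            self._out = out
        return out

    def backward(self, dout):
        dx = dout * (1.0 - self._out**2)
        self._out = None
        return dx


class AffineScale(Layer):
    """Fixed (non-trainable) elementwise y = a*x + b; e.g. tanh → [0, 1]."""

    def __init__(self, a: float, b: float):
        self.a, self.b = a, b

    def forward(self, x, train=True):
        return self.a * x + self.b

    def backward(self, dout):
        return self.a * dout


class Sigmoid(Layer):
    def forward(self, x, train=True):
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, dout):
        dx = dout * self._out * (1.0 - self._out)
        self._out = None
        return dx


class ChannelSoftmax(Layer):
    """Softmax over the channel axis — the per-pixel "soft maximum" that turns
    the three discriminator output maps into a probability distribution."""

    def forward(self, x, train=True):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=1, keepdims=True)
        if train:
            self._out = out
        return out

    def backward(self, dout):
        p = self._out
        self._out = None
        return p * (dout - (dout * p).sum(axis=1, keepdims=True))


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = shape  # without the batch axis

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, dout):
        return dout.reshape(self._in_shape)

    def flops(self, in_shape):
        return 0, (in_shape[0],) + tuple(self.shape)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout

    def flops(self, in_shape):
        total = 0
        for lay in self.layers:
            ops, in_shape = lay.flops(in_shape)
            total += ops
        return total, in_shape


class Adam:
    """Adam with a mutable learning rate (for the step decay schedule)."""

    def __init__(self, params: list[Param], lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "lr": self.lr,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]


def count_parameters(model: Layer) -> int:
    """Exact number of trainable scalars in a layer or layer stack."""
    return int(sum(p.size for p in model.params()))


def count_flops(model: Layer, in_shape: tuple) -> int:
    """Analytic operation count for one forward pass on ``in_shape`` input.

    Convention: only multiply–accumulate layers (convolutions, dense) are
    counted; a multiply–accumulate is 2 operations and a bias add is 1 per
    output element.  Normalization and activation layers are free.
    """
    ops, _ = model.flops(in_shape)
    return int(ops)
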