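"""Minimal NumPy neural-network kernels with hand-written backprop.

Only what the encoder needs: strided and padded 2-D convolution (im2col +
BLAS matmul), depthwise convolution, batch normalization with running
statistics, ELU, fully connected layers, and Adam. Conventions (ELU alpha=1,
BN epsilon/momentum, Xavier-normal fan-in+fan-out initialization) follow the
ones mainstream deep-learning frameworks use so that the architecture's
published hyperparameters transfer unchanged.

All parameters and activations are float32. Layers cache what their backward
pass needs during ``forward(..., training=True)``; ``backward`` accumulates
parameter gradients in ``Param.grad`` and returns the input gradient.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def xavier_normal(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)


def elu(x: np.ndarray) -> np.ndarray:
    # expm1(min(x,0)) + max(x,0), branch-free and allocation-light
    y = np.minimum(x, 0)
    np.expm1(y, out=y)
    y += np.maximum(x, 0)
    return y


def elu_grad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # d/dx ELU = 1 for x>0, exp(x) = y+1 otherwise
    return np.where(x > 0, 1.0, y + 1.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def sdict(self) -> dict[str, np.ndarray]:
        return {}

    def load(self, state: dict[str, np.ndarray]) -> None:
        pass


class Conv2d(Layer):
    """Standard 2-D convolution (cross-correlation) with square kernel."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1, pad: int = 0, rng=None):
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in, fan_out = c_in * k * k, c_out * k * k
        self.W = Param(xavier_normal(rng, (c_out, c_in, k, k), fan_in, fan_out))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def _cols(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            xp.shape[0] * ho * wo, self.c_in * self.k * self.k
        )

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        if self.k == 1 and self.stride == 1 and self.pad == 0:
            # pointwise convolution: plain channel matmul, no im2col
            x3 = x.reshape(b, c, h * w)
            out = np.matmul(self.W.value.reshape(self.c_out, c), x3)
            out += self.b.value[None, :, None]
            if training:
                self._cache = ("pw", x3, (b, c, h, w))
            return out.reshape(b, self.c_out, h, w)
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (xp.shape[2] - self.k) // self.stride + 1
        wo = (xp.shape[3] - self.k) // self.stride + 1
        cols = self._cols(xp, ho, wo)
        wmat = self.W.value.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.b.value
        if training:
            self._cache = ("gen", cols, x.shape, xp.shape, ho, wo)
        return out.reshape(b, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache[0] == "pw":
            _, x3, (b, c, h, w) = self._cache
            dy3 = dy.reshape(b, self.c_out, h * w)
            # sum over batch of dy3[b] @ x3[b].T
            self.W.grad += np.einsum("bos,bcs->oc", dy3, x3, optimize=True).reshape(self.W.value.shape)
            self.b.grad += dy3.sum(axis=(0, 2))
            return np.matmul(self.W.value.reshape(self.c_out, c).T, dy3).reshape(b, c, h, w)
        _, cols, xshape, xpshape, ho, wo = self._cache
        bsz = xshape[0]
        dym = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.W.grad += (dym.T @ cols).reshape(self.W.value.shape)
        self.b.grad += dym.sum(axis=0)
        dcols = (dym @ self.W.value.reshape(self.c_out, -1)).reshape(
            bsz, ho, wo, self.c_in, self.k, self.k
        )
        dxp = np.zeros(xpshape, dtype=np.float32)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        p = self.pad
        return dxp[:, :, p : p + xshape[2], p : p + xshape[3]] if p else dxp

    def sdict(self):
        return {"W": self.W.value, "b": self.b.value}

    def load(self, state):
        self.W.value[...] = state["W"]
        self.b.value[...] = state["b"]


class DepthwiseConv2d(Layer):
    """Per-channel k x k convolution (the spatial half of a depth-separable
    layer)."""

    def __init__(self, c: int, k: int, pad: int, rng=None):
        self.c, self.k, self.pad = c, k, pad
        rng = rng or np.random.default_rng(0)
        self.W = Param(xavier_normal(rng, (c, k, k), k * k, k * k))
        self.b = Param(np.zeros(c))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # shift-and-add: k*k fused multiply-accumulates over contiguous slices
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = xp.shape[2] - self.k + 1
        wo = xp.shape[3] - self.k + 1
        out = np.empty((x.shape[0], self.c, ho, wo), dtype=np.float32)
        out[:] = self.b.value[None, :, None, None]
        buf = np.empty_like(out)
        for i in range(self.k):
            for j in range(self.k):
                np.multiply(xp[:, :, i : i + ho, j : j + wo], self.W.value[None, :, i, j, None, None], out=buf)
                out += buf
        if training:
            self._cache = (xp, x.shape)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, xshape = self._cache
        ho, wo = dy.shape[2], dy.shape[3]
        self.b.grad += np.einsum("bchw->c", dy)
        dxp = np.zeros(xp.shape, dtype=np.float32)
        buf = np.empty_like(dy)
        for i in range(self.k):
            for j in range(self.k):
                np.multiply(dy, xp[:, :, i : i + ho, j : j + wo], out=buf)
                self.W.grad[:, i, j] += np.einsum("bchw->c", buf)
                np.multiply(dy, self.W.value[None, :, i, j, None, None], out=buf)
                dxp[:, :, i : i + ho, j : j + wo] += buf
        p = self.pad
        return dxp[:, :, p : p + xshape[2], p : p + xshape[3]] if p else dxp

    def sdict(self):
        return {"W": self.W.value, "b": self.b.value}

    def load(self, state):
        self.W.value[...] = state["W"]
        self.b.value[...] = state["b"]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            # eval path: single fused affine map with frozen statistics
            a = (self.gamma.value / np.sqrt(self.running_var + self.eps)).astype(np.float32)
            c = (self.beta.value - self.running_mean * a).astype(np.float32)
            return x * a[None, :, None, None] + c[None, :, None, None]
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean.astype(np.float32)[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None] * invstd[None, :, None, None]
        return g * (dy - (dbeta / n)[None, :, None, None] - xhat * (dgamma / n)[None, :, None, None])

    def sdict(self):
        return {
            "gamma": self.gamma.value,
            "beta": self.beta.value,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }

    def load(self, state):
        self.gamma.value[...] = state["gamma"]
        self.beta.value[...] = state["beta"]
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class ELU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = elu(x).astype(np.float32, copy=False)
        if training:
            self._cache = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # ELU' = 1 for x>0 and y+1 for x<0, i.e. min(y,0)+1 everywhere
        y = self._cache
        g = np.minimum(y, 0)
        g += 1.0
        g *= dy
        return g


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def sdict(self):
        out = {}
        for i, l in enumerate(self.layers):
            for k, v in l.sdict().items():
                out[f"{i}.{k}"] = v
        return out

    def load(self, state):
        for i, l in enumerate(self.layers):
            sub = {k.split(".", 1)[1]: v for k, v in state.items() if k.startswith(f"{i}.")}
            if sub:
                l.load(sub)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(xavier_normal(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def sdict(self):
        return {"W": self.W.value, "b": self.b.value}

    def load(self, state):
        self.W.value[...] = state["W"]
        self.b.value[...] = state["b"]


class Adam:
    """Adam with bias correction; ``lr`` is mutable so a scheduler can anneal
    it between epochs."""

    def __init__(self, params: list[Param], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
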