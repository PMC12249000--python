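"""Minimal NumPy neural-network layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``.grads`` during ``backward``.
Arrays follow the ``N x C x H x W`` convention throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Dropout",
    "Linear",
    "GlobalAvgPool",
    "Sequential",
    "sigmoid",
    "he_normal",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out.astype(x.dtype, copy=False)


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He (Kaiming) normal initialization: N(0, sqrt(2 / fan_in))."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Module:
    """Base class: named parameters, gradients, and train/eval mode."""

    def __init__(self, name: str = ""):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def named_parameters(self):
        for k, v in self.params.items():
            yield f"{self.name}.{k}" if self.name else k, v

    def children(self):
        return iter(())

    def modules(self):
        yield self
        for c in self.children():
            yield from c.modules()

    def all_parameters(self):
        """(qualified name, value array, owning module, key) for every weight."""
        for m in self.modules():
            for k, v in m.params.items():
                yield (f"{m.name}.{k}" if m.name else k), v, m, k

    def num_parameters(self) -> int:
        return sum(int(v.size) for _, v, _, _ in self.all_parameters())

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)


def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _im2col(xp: np.ndarray, k: int, stride: int):
    """(N, C, Hp, Wp) padded input -> (N, C, k*k, Ho, Wo) patch view."""
    n, c, hp, wp = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]  # (N, C, Ho, Wo, k, k)
    cols = windows.reshape(n, c, ho, wo, k * k).transpose(0, 1, 4, 2, 3)
    return np.ascontiguousarray(cols), ho, wo


class Conv2d(Module):
    """2-D convolution with 'same' zero padding and optional channel groups.

    Weight layout: (C_out, C_in/groups, k, k). Depthwise convolution is
    ``groups == in_channels``.
    """

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 groups=1, bias=True, name=""):
        super().__init__(name)
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.stride, self.groups, self.has_bias = stride, groups, bias
        cpg = in_channels // groups
        self.params["weight"] = np.zeros((out_channels, cpg, kernel_size, kernel_size),
                                         dtype=np.float32)
        if bias:
            self.params["bias"] = np.zeros(out_channels, dtype=np.float32)
        self.zero_grad()

    def init_weights(self, rng: np.random.Generator) -> None:
        fan_in = (self.cin // self.groups) * self.k * self.k
        self.params["weight"] = he_normal(rng, self.params["weight"].shape, fan_in)

    def forward(self, x, train=False):
        if x.shape[1] != self.cin:
            raise ValueError(
                f"{self.name or 'conv'}: expected {self.cin} input channels, got {x.shape[1]}")
        n = x.shape[0]
        g, cpg, copg = self.groups, self.cin // self.groups, self.cout // self.groups
        xp = _pad_same(x, self.k)
        cols, ho, wo = _im2col(xp, self.k, self.stride)  # (N, C, k2, Ho, Wo)
        cols = cols.reshape(n, g, cpg * self.k * self.k, ho, wo)
        w = self.params["weight"].reshape(g, copg, cpg * self.k * self.k)
        out = np.einsum("ngqhw,goq->nohw" if g == 1 else "ngqhw,goq->ngohw",
                        cols, w, optimize=True)
        if g > 1:
            out = out.reshape(n, self.cout, ho, wo)
        if self.has_bias:
            out = out + self.params["bias"][None, :, None, None]
        self._cache = (x.shape, cols, ho, wo)
        return out.astype(np.float32, copy=False)

    def backward(self, dout):
        (xshape, cols, ho, wo) = self._cache
        n = xshape[0]
        g, cpg, copg = self.groups, self.cin // self.groups, self.cout // self.groups
        k2 = self.k * self.k
        if self.has_bias:
            self.grads["bias"] += dout.sum(axis=(0, 2, 3))
        dg = dout.reshape(n, g, copg, ho, wo)
        dw = np.einsum("ngohw,ngqhw->goq", dg, cols, optimize=True)
        self.grads["weight"] += dw.reshape(self.params["weight"].shape)
        w = self.params["weight"].reshape(g, copg, cpg * k2)
        dcols = np.einsum("ngohw,goq->ngqhw", dg, w, optimize=True)
        dcols = dcols.reshape(n, self.cin, k2, ho, wo)
        # col2im: scatter-add each kernel offset back onto the padded grid
        p = self.k // 2
        hp, wp = xshape[2] + 2 * p, xshape[3] + 2 * p
        dxp = np.zeros((n, self.cin, hp, wp), dtype=np.float64)
        s = self.stride
        for idx in range(k2):
            di, dj = divmod(idx, self.k)
            dxp[:, :, di:di + s * ho:s, dj:dj + s * wo:s] += dcols[:, :, idx]
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp.astype(np.float32, copy=False)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5, name=""):
        super().__init__(name)
        self.c, self.momentum, self.eps = channels, momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.zero_grad()

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.params["gamma"][None, :, None, None] * xhat \
            + self.params["beta"][None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return out.astype(np.float32, copy=False)

    def backward(self, dout):
        xhat, inv, train, xshape = self._cache
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        if not train:
            return (dout * g * inv[None, :, None, None]).astype(np.float32, copy=False)
        m = xshape[0] * xshape[2] * xshape[3]
        dxhat = dout * g
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True))
        return dx.astype(np.float32, copy=False)


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(np.float32, copy=False)

    def backward(self, dout):
        return np.where(self._mask, dout, 0).astype(np.float32, copy=False)


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode. RNG is injected per run."""

    def __init__(self, rate, name=""):
        super().__init__(name)
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        rng = self.rng if self.rng is not None else np.random.default_rng(0)
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return (x * self._mask).astype(np.float32, copy=False)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(np.float32, copy=False)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, name=""):
        super().__init__(name)
        self.fin, self.fout, self.has_bias = in_features, out_features, bias
        self.params["weight"] = np.zeros((out_features, in_features), dtype=np.float32)
        if bias:
            self.params["bias"] = np.zeros(out_features, dtype=np.float32)
        self.zero_grad()

    def init_weights(self, rng):
        self.params["weight"] = he_normal(rng, (self.fout, self.fin), self.fin)

    def forward(self, x, train=False):
        self._x = x
        out = x @ self.params["weight"].T
        if self.has_bias:
            out = out + self.params["bias"]
        return out.astype(np.float32, copy=False)

    def backward(self, dout):
        self.grads["weight"] += dout.T @ self._x
        if self.has_bias:
            self.grads["bias"] += dout.sum(axis=0)
        return (dout @ self.params["weight"]).astype(np.float32, copy=False)


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return (np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)
                ).astype(np.float32, copy=False)


class Sequential(Module):
    def __init__(self, layers, name=""):
        super().__init__(name)
        self.layers = list(layers)

    def children(self):
        return iter(self.layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
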