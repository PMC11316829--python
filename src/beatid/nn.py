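"""Minimal NumPy neural-network framework: layers, backprop, Adam.

Layers operate on NHWC float32 tensors.  Convolutions follow
cross-correlation semantics with zero "same" padding (output spatial size
ceil(in/stride), padding split with the extra sample on the bottom/right)
and carry no bias — batch normalization follows every convolution.  The
framework implements exactly what the identification model needs: standard,
depthwise and pointwise convolutions, batch norm, elementwise activations,
global average pooling, dense layers, a softmax cross-entropy loss and an
Adam optimizer.  All randomness flows through an explicit Generator, so a
fixed seed reproduces training bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "selu",
    "gelu",
    "elu",
    "softmax",
    "Layer",
    "Conv2D",
    "DepthwiseConv2D",
    "PointwiseConv2D",
    "BatchNorm",
    "Activation",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax_cross_entropy",
]

SELU_LAMBDA = 1.0507
SELU_ALPHA = 1.6733
GELU_C = 0.044715
ELU_ALPHA = 1.0


def selu(x: np.ndarray | float) -> np.ndarray | float:
    """Scaled exponential linear unit: lambda*x for x>0, lambda*alpha*(e^x - 1) else."""
    x = np.asarray(x)
    return np.where(
        x > 0, SELU_LAMBDA * x, SELU_LAMBDA * SELU_ALPHA * np.expm1(np.minimum(x, 0.0))
    )[()]


def _selu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(
        x > 0, SELU_LAMBDA, SELU_LAMBDA * SELU_ALPHA * np.exp(np.minimum(x, 0.0))
    )


_SQRT_2_PI = np.sqrt(2.0 / np.pi)


def gelu(x: np.ndarray | float, strict_cdf: bool = False) -> np.ndarray | float:
    """Gaussian error linear unit, tanh approximation.

    ``strict_cdf=True`` drops the leading multiplicative x and returns only
    the approximate Gaussian CDF term 0.5*(1 + tanh(...)).
    """
    x = np.asarray(x, dtype=np.float64)
    cdf = 0.5 * (1.0 + np.tanh(_SQRT_2_PI * (x + GELU_C * x**3)))
    return (cdf if strict_cdf else x * cdf)[()]


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    u = _SQRT_2_PI * (x + GELU_C * x**3)
    t = np.tanh(u)
    du = _SQRT_2_PI * (1.0 + 3.0 * GELU_C * x**2)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * du


def elu(x: np.ndarray | float, alpha: float = ELU_ALPHA) -> np.ndarray | float:
    x = np.asarray(x)
    return np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))[()]


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, ELU_ALPHA * np.exp(np.minimum(x, 0.0)))


_ACTIVATIONS = {
    "selu": (selu, _selu_grad),
    "gelu": (gelu, _gelu_grad),
    "elu": (elu, _elu_grad),
}


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base layer; params/grads are dicts of same-shaped float32 arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _same_pad(n: int, k: int, stride: int) -> tuple[int, int, int]:
    """(out, pad_before, pad_after) for SAME padding at the given stride."""
    out = -(-n // stride)
    total = max((out - 1) * stride + k - n, 0)
    return out, total // 2, total - total // 2


def _window(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Extract strided (N, OH, OW, k, k, C) patches with SAME padding."""
    n, h, w, c = x.shape
    oh, pt, pb = _same_pad(h, k, stride)
    ow, pl, pr = _same_pad(w, k, stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N, H', W', C, k, k)
    win = win[:, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)), (pt, pl)


def _scatter_patches(
    dpatch: np.ndarray,
    in_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pads: tuple[int, int],
) -> np.ndarray:
    """Adjoint of _window: accumulate (N, OH, OW, k, k, C) grads into input."""
    n, h, w, c = in_shape
    oh, ow = dpatch.shape[1], dpatch.shape[2]
    pt, pl = pads
    hp = pt + h + max((oh - 1) * stride + k - (pt + h), 0)
    wp = pl + w + max((ow - 1) * stride + k - (pl + w), 0)
    dxp = np.zeros((n, hp, wp, c), dtype=dpatch.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + stride * oh : stride, j : j + stride * ow : stride] += dpatch[
                :, :, :, i, j
            ]
    return dxp[:, pt : pt + h, pl : pl + w]


class Conv2D(Layer):
    """Standard 2-D convolution (cross-correlation), SAME padding, no bias."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (k * k * in_ch))
        self.params["W"] = (
            rng.normal(0.0, scale, size=(k, k, in_ch, out_ch)).astype(np.float32)
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[-1]}")
        patches, self._pads = _window(x, self.k, self.stride)
        self._x_shape = x.shape
        n, oh, ow = patches.shape[:3]
        cols = patches.reshape(n * oh * ow, -1)
        if train:
            self._cols, self._oshape = cols, (n, oh, ow)
        wmat = self.params["W"].reshape(-1, self.out_ch)
        return (cols @ wmat).reshape(n, oh, ow, self.out_ch)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, oh, ow = self._oshape
        dflat = dout.reshape(n * oh * ow, self.out_ch)
        self.grads["W"] = (self._cols.T @ dflat).reshape(self.params["W"].shape)
        dcols = dflat @ self.params["W"].reshape(-1, self.out_ch).T
        dpatch = dcols.reshape(n, oh, ow, self.k, self.k, self.in_ch)
        return _scatter_patches(dpatch, self._x_shape, self.k, self.stride, self._pads)


class DepthwiseConv2D(Layer):
    """Per-channel 3x3 spatial filtering; channel count preserved."""

    def __init__(
        self,
        ch: int,
        k: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.ch, self.k, self.stride = ch, k, stride
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (k * k))
        self.params["W"] = rng.normal(0.0, scale, size=(k, k, ch)).astype(np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.ch:
            raise ValueError(f"expected {self.ch} channels, got {x.shape[-1]}")
        n, h, w, c = x.shape
        k, s = self.k, self.stride
        oh, pt, pb = _same_pad(h, k, s)
        ow, pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        out = np.zeros((n, oh, ow, c), dtype=x.dtype)
        wgt = self.params["W"]
        for i in range(k):
            for j in range(k):
                out += xp[:, i : i + s * oh : s, j : j + s * ow : s] * wgt[i, j]
        if train:
            self._xp, self._x_shape, self._pads, self._oshape = xp, x.shape, (pt, pl), (oh, ow)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        oh, ow = self._oshape
        pt, pl = self._pads
        n, h, w, c = self._x_shape
        wgt = self.params["W"]
        dW = np.empty_like(wgt)
        dxp = np.zeros_like(self._xp)
        for i in range(k):
            for j in range(k):
                sl = np.s_[:, i : i + s * oh : s, j : j + s * ow : s]
                dW[i, j] = (self._xp[sl] * dout).sum(axis=(0, 1, 2))
                dxp[sl] += dout * wgt[i, j]
        self.grads["W"] = dW
        return dxp[:, pt : pt + h, pl : pl + w]


class PointwiseConv2D(Layer):
    """1x1 convolution: per-pixel linear mixing of channels."""

    def __init__(
        self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None
    ) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_ch)
        self.params["W"] = rng.normal(0.0, scale, size=(in_ch, out_ch)).astype(
            np.float32
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[-1]}")
        if train:
            self._x = x
        return x @ self.params["W"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = np.tensordot(self._x, dout, axes=([0, 1, 2], [0, 1, 2]))
        return dout @ self.params["W"].T


class BatchNorm(Layer):
    """Batch normalization over N,H,W per channel (or N for 2-D input)."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.params["gamma"] = np.ones(ch, dtype=np.float32)
        self.params["beta"] = np.zeros(ch, dtype=np.float32)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
            self._xhat = (x - mean) / np.sqrt(var + self.eps)
            self._istd = 1.0 / np.sqrt(var + self.eps)
            self._m = int(np.prod([x.shape[a] for a in axes]))
            return self.params["gamma"] * self._xhat + self.params["beta"]
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = tuple(range(dout.ndim - 1))
        xhat, istd, m = self._xhat, self._istd, self._m
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        return (
            istd
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        ).astype(dout.dtype)


class Activation(Layer):
    """Elementwise activation; works in the input dtype and caches the
    intermediates its backward pass needs (the tanh term for GeLU, the
    exponential branch for SeLU/ELU)."""

    def __init__(self, name: str) -> None:
        super().__init__()
        if name not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {name!r}")
        self.name = name
        self.fn, self.grad_fn = _ACTIVATIONS[name]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.name == "gelu":
            u = x + GELU_C * x * x * x
            u *= np.float32(_SQRT_2_PI)
            t = np.tanh(u)
            out = 0.5 * x * (1.0 + t)
            if train:
                self._x, self._t = x, t
            return out.astype(x.dtype)
        pos = x > 0
        e = np.exp(np.minimum(x, 0.0))
        if self.name == "selu":
            out = np.where(pos, SELU_LAMBDA * x, SELU_LAMBDA * SELU_ALPHA * (e - 1.0))
        else:  # elu
            out = np.where(pos, x, ELU_ALPHA * (e - 1.0))
        if train:
            self._pos, self._e = pos, e
        return out.astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.name == "gelu":
            x, t = self._x, self._t
            du = np.float32(_SQRT_2_PI) * (1.0 + 3.0 * GELU_C * x * x)
            g = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du
        elif self.name == "selu":
            g = np.where(self._pos, SELU_LAMBDA, SELU_LAMBDA * SELU_ALPHA * self._e)
        else:
            g = np.where(self._pos, 1.0, ELU_ALPHA * self._e)
        return (dout * g).astype(dout.dtype)


class GlobalAvgPool(Layer):
    """(N, H, W, C) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).astype(
            dout.dtype
        )


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with bias."""

    def __init__(
        self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_dim)
        self.params["W"] = rng.normal(0.0, scale, size=(in_dim, out_dim)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(out_dim, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    """Ordered layer stack with forward/backward and parameter accounting."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield (li, name), layer

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class Adam:
    """Adam optimizer over a Sequential's parameters."""

    def __init__(
        self,
        model: Sequential,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}
        for key, layer in model.parameters():
            shape = layer.params[key[1]].shape
            self.m[key] = np.zeros(shape, dtype=np.float32)
            self.v[key] = np.zeros(shape, dtype=np.float32)

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for key, layer in self.model.parameters():
            g = layer.grads[key[1]].astype(np.float32)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / b1t
            vhat = self.v[key] / b2t
            layer.params[key[1]] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
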