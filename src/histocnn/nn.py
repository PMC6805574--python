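"""Minimal numpy neural-network layers with manual backpropagation.

Layers operate on NCHW float64 arrays and implement ``forward``/``backward``
pairs plus structural surgery hooks (channel slicing) used by the channel
pruning stage.  The scope is deliberately small: exactly the layer types the
two-branch architecture needs, with deterministic seeded initialization.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "SEBlock",
    "softmax",
    "se_bottleneck_width",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a (N, K) logit array."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def se_bottleneck_width(channels: int, reduction: int) -> int:
    """Bottleneck width of the squeeze/excite FC pair: max(1, round(C/r))."""
    return max(1, int(np.floor(channels / reduction + 0.5)))


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "weight_decay")

    def __init__(self, value: np.ndarray, weight_decay: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.weight_decay = weight_decay

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base layer: forward/backward plus parameter traversal."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> Iterator[Parameter]:
        return iter(())

    def children(self) -> Iterator["Module"]:
        return iter(())

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self.children():
            yield from child.modules()

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


class Sequential(Module):
    def __init__(self, layers: Sequence[Module] = ()):
        self.layers: list[Module] = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()

    def children(self):
        return iter(self.layers)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int, pad_value: float = 0.0):
    """Return (cols, out_h, out_w); cols has shape (N, out_h*out_w, C*k*k)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(
            x,
            ((0, 0), (0, 0), (pad, pad), (pad, pad)),
            mode="constant",
            constant_values=pad_value,
        )
    out_h = (h + 2 * pad - k) // stride + 1
    out_w = (w + 2 * pad - k) // stride + 1
    view = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,Hf,Wf,k,k)
    view = view[:, :, ::stride, ::stride]               # (N,C,out_h,out_w,k,k)
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h * out_w, c * k * k)
    return np.ascontiguousarray(cols), out_h, out_w


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add column gradients back onto the (padded) input grid."""
    n, c, h, w = x_shape
    out_h = (h + 2 * pad - k) // stride + 1
    out_w = (w + 2 * pad - k) // stride + 1
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(n, out_h, out_w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * out_h : stride, j : j + stride * out_w : stride] += d[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Module):
    """2-D convolution (cross-correlation) with optional bias."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, scale, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels), weight_decay=False) if bias else None
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None
        self.last_macs = 0

    @property
    def in_channels(self) -> int:
        return self.weight.value.shape[1]

    @property
    def out_channels(self) -> int:
        return self.weight.value.shape[0]

    def forward(self, x, train=True):
        cols, out_h, out_w = _im2col(x, self.kernel_size, self.stride, self.padding)
        w2 = self.weight.value.reshape(self.out_channels, -1)
        out = cols @ w2.T
        if self.bias is not None:
            out += self.bias.value
        out = out.transpose(0, 2, 1).reshape(x.shape[0], self.out_channels, out_h, out_w)
        self._cache = (cols, x.shape)
        self.last_macs = out_h * out_w * self.out_channels * self.in_channels * self.kernel_size**2
        return out

    def backward(self, grad):
        cols, x_shape = self._cache
        n = grad.shape[0]
        g2 = grad.reshape(n, self.out_channels, -1).transpose(0, 2, 1)  # (N, P, Cout)
        dw = np.einsum("npo,npk->ok", g2, cols)
        self.weight.grad += dw.reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=(0, 1))
        dcols = g2 @ self.weight.value.reshape(self.out_channels, -1)
        return _col2im(dcols, x_shape, self.kernel_size, self.stride, self.padding)

    def parameters(self):
        yield self.weight
        if self.bias is not None:
            yield self.bias

    # -- surgery -----------------------------------------------------------
    def slice_out(self, idx: np.ndarray) -> None:
        self.weight = Parameter(self.weight.value[idx])
        if self.bias is not None:
            self.bias = Parameter(self.bias.value[idx], weight_decay=False)

    def slice_in(self, idx: np.ndarray) -> None:
        self.weight = Parameter(self.weight.value[:, idx])


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(channels), weight_decay=False)
        self.beta = Parameter(np.zeros(channels), weight_decay=False)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    @property
    def channels(self) -> int:
        return self.gamma.value.shape[0]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return out

    def backward(self, grad):
        xhat, inv, train, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not train:
            return g * inv[None, :, None, None]
        gs = g.sum(axis=(0, 2, 3))[None, :, None, None]
        gxs = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (g - gs / n_eff - xhat * gxs / n_eff) * inv[None, :, None, None]

    def parameters(self):
        yield self.gamma
        yield self.beta

    def slice(self, idx: np.ndarray) -> None:
        self.gamma = Parameter(self.gamma.value[idx], weight_decay=False)
        self.beta = Parameter(self.beta.value[idx], weight_decay=False)
        self.running_mean = self.running_mean[idx]
        self.running_var = self.running_var[idx]


class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x, train=True):
        k, s, p = self.kernel_size, self.stride, self.padding
        cols, out_h, out_w = _im2col(x, k, s, p, pad_value=-np.inf)
        n, c = x.shape[0], x.shape[1]
        # cols: (N, P, C*k*k) -> (N, P, C, k*k)
        win = cols.reshape(n, out_h * out_w, c, k * k)
        arg = win.argmax(axis=3)
        out = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]
        out = out.transpose(0, 2, 1).reshape(n, c, out_h, out_w)
        self._cache = (arg, x.shape, out_h, out_w)
        return out

    def backward(self, grad):
        k, s, p = self.kernel_size, self.stride, self.padding
        arg, x_shape, out_h, out_w = self._cache
        n, c = x_shape[0], x_shape[1]
        g = grad.reshape(n, c, out_h * out_w).transpose(0, 2, 1)  # (N,P,C)
        dwin = np.zeros((n, out_h * out_w, c, k * k))
        np.put_along_axis(dwin, arg[..., None], g[..., None], axis=3)
        dcols = dwin.reshape(n, out_h * out_w, c * k * k)
        return _col2im(dcols, x_shape, k, s, p)


class GlobalAvgPool(Module):
    """Average over the full spatial grid, returning (N, C)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Flatten(Module):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features), weight_decay=False) if bias else None
        self._cache = None
        self.last_macs = 0

    @property
    def in_features(self) -> int:
        return self.weight.value.shape[1]

    @property
    def out_features(self) -> int:
        return self.weight.value.shape[0]

    def forward(self, x, train=True):
        self._cache = x
        self.last_macs = self.in_features * self.out_features
        out = x @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        return out

    def backward(self, grad):
        x = self._cache
        self.weight.grad += grad.T @ x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value

    def parameters(self):
        yield self.weight
        if self.bias is not None:
            yield self.bias

    def slice_in(self, idx: np.ndarray) -> None:
        self.weight = Parameter(self.weight.value[:, idx])


class SEBlock(Module):
    """Squeeze/excite channel gate with a pruning statistics hook.

    Squeeze = global average over the spatial grid; excite = two bias-free FC
    layers (ReLU then sigmoid); scale = per-channel multiplication.  When
    ``record`` is enabled the per-sample activation factors ``s`` of the last
    forward pass are kept for channel-importance accumulation.
    """

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        b = se_bottleneck_width(channels, reduction)
        self.w1 = Parameter(rng.normal(0.0, np.sqrt(2.0 / channels), (b, channels)))
        self.w2 = Parameter(rng.normal(0.0, np.sqrt(1.0 / b), (channels, b)))
        self.reduction = reduction
        self.record = False
        self.last_s: np.ndarray | None = None
        self._cache = None
        self.last_macs = 0

    @property
    def channels(self) -> int:
        return self.w1.value.shape[1]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        z = x.mean(axis=(2, 3))                       # (N, C)
        h1 = z @ self.w1.value.T
        h1r = np.maximum(h1, 0.0)
        s = 1.0 / (1.0 + np.exp(-(h1r @ self.w2.value.T)))  # (N, C)
        if self.record:
            self.last_s = s.copy()
        out = x * s[:, :, None, None]
        self._cache = (x, z, h1, h1r, s)
        self.last_macs = self.w1.value.size + self.w2.value.size
        return out

    def backward(self, grad):
        x, z, h1, h1r, s = self._cache
        h, w = x.shape[2], x.shape[3]
        ds = (grad * x).sum(axis=(2, 3))              # (N, C)
        dpre2 = ds * s * (1.0 - s)
        self.w2.grad += dpre2.T @ h1r
        dh1r = dpre2 @ self.w2.value
        dpre1 = dh1r * (h1 > 0)
        self.w1.grad += dpre1.T @ z
        dz = dpre1 @ self.w1.value
        dx = grad * s[:, :, None, None]
        dx += dz[:, :, None, None] / (h * w)
        return dx

    def parameters(self):
        yield self.w1
        yield self.w2

    def slice(self, idx: np.ndarray) -> None:
        """Restrict the gate to the kept channel set.

        The bottleneck shrinks to max(1, round(C_p / r)); the leading
        bottleneck units are retained (deterministic convention).
        """
        w1 = self.w1.value[:, idx]
        w2 = self.w2.value[idx, :]
        b_new = se_bottleneck_width(len(idx), self.reduction)
        self.w1 = Parameter(w1[:b_new, :])
        self.w2 = Parameter(w2[:, :b_new])
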