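"""Neural-network building blocks (modules) on top of the autograd core.

Layout convention for image data is NCHW.  Initialisation is He-uniform for
rectifier layers; every module takes a ``numpy.random.Generator`` so that
model construction is fully seeded.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "ReLU",
    "Tanh",
    "Sequential",
    "ResidualBlock",
    "AvgPool2d",
    "GlobalAvgPool",
    "Flatten",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, grad reset and (de)serialisation."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        yield f"{full}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
            elif isinstance(value, dict):
                for k, item in value.items():
                    if isinstance(item, Parameter):
                        yield f"{full}.{k}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{k}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N,C,OH',OW',kh,kw)
    windows = windows[:, :, ::stride, ::stride]
    oh, ow = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(gcols: np.ndarray, x_shape, kh, kw, stride, pad, oh, ow):
    n, c, h, w = x_shape
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    g = gcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += g[
                :, :, :, :, i, j
            ]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


class Conv2d(Module):
    """2D convolution via im2col with a hand-written backward."""

    def __init__(self, in_channels, out_channels, kernel_size, rng, stride=1, padding=0):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        bound = np.sqrt(6.0 / fan_in)
        self.weight = Parameter(
            rng.uniform(-bound, bound, (fan_in, out_channels))
        )
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, h, w = x.data.shape
        cols, oh, ow = _im2col(x.data, k, k, s, p)
        out_mat = cols @ self.weight.data + self.bias.data
        out_data = out_mat.reshape(n, oh, ow, self.out_channels).transpose(0, 3, 1, 2)

        weight, bias = self.weight, self.bias

        def backward(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(-1, self.out_channels)
            gw = cols.T @ gmat
            gb = gmat.sum(axis=0)
            gcols = gmat @ weight.data.T
            gx = _col2im(gcols, (n, c, h, w), k, k, s, p, oh, ow)
            return gx, gw, gb

        out = Tensor(out_data)
        if x.requires_grad or weight.requires_grad or bias.requires_grad:
            out.requires_grad = True
            out._parents = (x, weight, bias)
            out._backward = backward
        return out


class AvgPool2d(Module):
    """Average pooling by an integer factor (spatial dims must divide)."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        f = self.factor
        n, c, h, w = x.shape
        if h % f or w % f:
            raise ValueError(f"spatial dims {(h, w)} not divisible by {f}")
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))


class GlobalAvgPool(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        return x.reshape(n, -1)


class ResidualBlock(Module):
    """Two 3x3 convolutions with a skip connection.

    When the channel count or stride changes, the skip path uses a 1x1
    projection convolution, as in standard residual networks.
    """

    def __init__(self, in_channels: int, rng: np.random.Generator,
                 out_channels: int | None = None, stride: int = 1):
        out_channels = out_channels or in_channels
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng, stride=stride, padding=1)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng, padding=1)
        self.proj = (
            Conv2d(in_channels, out_channels, 1, rng, stride=stride)
            if (out_channels != in_channels or stride != 1)
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        out = self.conv2(self.conv1(x).relu())
        skip = self.proj(x) if self.proj is not None else x
        return (out + skip).relu()
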