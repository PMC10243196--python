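"""Layer/module abstractions over the autodiff core.

Mirrors the familiar Module/Parameter idiom: modules own named parameters
and buffers, compose hierarchically, and serialize to flat name->array
state dicts.  Initialization is He-normal for conv weights and is driven
by an explicit ``numpy.random.Generator`` so model construction is fully
deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Parameter", "Module", "Identity", "ReLU", "Sigmoid", "Tanh",
    "Conv2d", "DeformConv2d", "InstanceNorm2d", "BatchNorm2d",
    "MaxPool2d", "BilinearUpsample2x", "PixelShuffle", "Sequential",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter/buffer registration, state dicts, train/eval."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ------------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- mode -----------------------------------------------------------------
    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- serialization --------------------------------------------------------
    def state_dict(self) -> dict:
        out = {}
        for n, p in self.named_parameters():
            out[n] = p.data.copy()
        for n, b in self.named_buffers():
            out[n] = b.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        mine = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(mine) | set(bufs)) - set(state)
        extra = set(state) - (set(mine) | set(bufs))
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for n, p in mine.items():
            if p.data.shape != state[n].shape:
                raise ValueError(f"shape mismatch for {n}")
            p.data = np.asarray(state[n], dtype=np.float64).copy()
        for n in bufs:
            bufs[n][...] = state[n]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class Conv2d(Module):
    """2-D convolution; He-normal init, optional groups/stride/bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        if zero_init:
            w = np.zeros((out_channels, in_channels // groups, k, k))
        else:
            rng = rng or np.random.default_rng()
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(out_channels, in_channels // groups, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        if x.data.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, "
                             f"got {x.data.shape[1]}")
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class DeformConv2d(Module):
    """Modulated deformable 3x3 conv whose offsets/modulation are predicted
    from the input by an internal 3x3 conv.

    The predictor is zero-initialized and the modulation is
    ``2 * sigmoid(raw)``, so at initialization the offsets are zero and the
    modulation is exactly 1: the layer then coincides with a plain 3x3
    convolution, which both stabilizes training and admits a standard-conv
    oracle test.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.offset_conv = Conv2d(in_channels, 27, 3, padding=1, zero_init=True)
        rng = rng or np.random.default_rng()
        fan_in = in_channels * 9
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                           size=(out_channels, in_channels, 3, 3)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        pred = self.offset_conv(x)
        offset = pred[:, :18]
        mask = pred[:, 18:].sigmoid() * 2.0
        return F.deform_conv2d(x, offset, mask, self.weight, self.bias)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over H,W with affine params.

    No running statistics are tracked: the statistics of the current
    instance are used at train and test time alike, which is the usual
    choice for restoration networks trained on small patches.
    """

    def __init__(self, num_features: int, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        C = self.num_features
        return xn * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


class BatchNorm2d(Module):
    """Batch normalization over (N,H,W) with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self._buffers["running_mean"] = np.zeros(num_features)
        self._buffers["running_var"] = np.ones(num_features)

    def forward(self, x):
        C = self.num_features
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(C)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(C)
            xn = xc / (var + self.eps).sqrt()
        else:
            mu = self._buffers["running_mean"].reshape(1, C, 1, 1)
            sd = np.sqrt(self._buffers["running_var"].reshape(1, C, 1, 1) + self.eps)
            xn = (x - Tensor(mu)) / Tensor(sd)
        return xn * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


class MaxPool2d(Module):
    def forward(self, x):
        return F.max_pool2d(x)


class BilinearUpsample2x(Module):
    def forward(self, x):
        return F.bilinear_upsample2x(x)


class PixelShuffle(Module):
    def __init__(self, upscale_factor: int = 2):
        super().__init__()
        self.upscale_factor = upscale_factor

    def forward(self, x):
        return F.pixel_shuffle(x, self.upscale_factor)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]
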