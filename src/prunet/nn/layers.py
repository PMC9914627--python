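"""Layer/module abstractions over the autograd ops.

Modules register parameters and sub-modules through attribute assignment
(the familiar container pattern). Weights are He-initialised from an
explicit ``numpy.random.Generator`` so every model build is reproducible;
passing ``rng=None`` zero-initialises, which is the cheap path used when a
model is built only to be counted.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield (f"{prefix}.{name}" if prefix else name), b
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_buffers(sub)

    # -- modes -------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state -------------------------------------------------------------
    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data[...] = value
            elif kind == "buffer":
                buffers[name][...] = value
            else:
                raise KeyError(f"unrecognised state entry {key!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items = []
        for mod in modules:
            self.append(mod)

    def append(self, mod: Module) -> None:
        self._modules[str(len(self._items))] = mod
        self._items.append(mod)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


def _he(rng, shape, fan_in):
    dtype = ag.default_dtype()
    if rng is None:
        return np.zeros(shape, dtype=dtype)
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d(Module):
    """Same-padded stride-1 convolution with odd kernel size."""

    def __init__(self, in_channels, out_channels, kernel_size=3, bias=True, rng=None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_he(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=ag.default_dtype())) if bias else None
        self._out_shape = None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.conv2d(x, self.weight, self.bias)
        self._out_shape = out.shape
        return out


class ConvTranspose2x2(Module):
    """Stride-2 transposed convolution (2x2 kernel), doubling H and W."""

    def __init__(self, in_channels, out_channels, bias=True, rng=None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(_he(rng, (in_channels, out_channels, 2, 2), in_channels * 4))
        self.bias = Parameter(np.zeros(out_channels, dtype=ag.default_dtype())) if bias else None
        self._out_shape = None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.conv_transpose2x2(x, self.weight, self.bias)
        self._out_shape = out.shape
        return out


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        dtype = ag.default_dtype()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self._buffers["running_mean"] = np.zeros(channels, dtype=dtype)
        self._buffers["running_var"] = np.ones(channels, dtype=dtype)
        self._out_shape = None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.batch_norm(
            x, self.gamma, self.beta,
            self._buffers["running_mean"], self._buffers["running_var"],
            training=self.training, momentum=self.momentum, eps=self.eps,
        )
        self._out_shape = out.shape
        return out


class MaxPool2d(Module):
    def __init__(self, factor=2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return ag.max_pool(x, self.factor)


class Upsample(Module):
    """Bilinear upsampling by an integer factor."""

    def __init__(self, factor=2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return ag.upsample_bilinear(x, self.factor)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
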