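"""Neural-network building blocks on top of :mod:`mtsurv.autodiff`.

Modules hold :class:`Parameter` leaves, support recursive parameter
traversal, train/eval switching, and flat ``state_dict`` round-trips (saved
as ``.npz`` checkpoints).  Initialization follows He/Kaiming fan-in scaling
and is fully determined by the :class:`numpy.random.Generator` passed to
each layer, so model construction is reproducible from a single seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import (
    Tensor,
    avg_pool3d,
    concat,
    conv3d,
    conv_transpose3d,
    max_pool3d,
)

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv3d",
    "ConvTranspose3d",
    "Linear",
    "InstanceNorm3d",
    "BatchNorm3d",
    "LayerNorm",
    "MaxPool3d",
    "AvgPool3d",
    "LeakyReLU",
    "ReLU",
    "Sigmoid",
    "Tanh",
]


class Parameter(Tensor):
    def __init__(self, value):
        super().__init__(np.asarray(value, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, attr in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(f"{full}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield from attr.modules()

    def num_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    # -- mode -----------------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.value.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, attr in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(attr, Module):
                yield from attr.named_buffers(f"{full}.")
            elif isinstance(attr, np.ndarray) and name.startswith("running_"):
                yield full, attr

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key in params:
                params[key].value = np.asarray(value, dtype=np.float32).reshape(params[key].shape)
            elif key in buffers:
                buffers[key][...] = value
            else:
                raise KeyError(f"unexpected key in state dict: {key}")
        return self

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._mods: list[Module] = list(mods)
        for i, m in enumerate(self._mods):
            setattr(self, f"m{i}", m)

    def append(self, mod: Module):
        setattr(self, f"m{len(self._mods)}", mod)
        self._mods.append(mod)

    def __iter__(self):
        return iter(self._mods)

    def __len__(self):
        return len(self._mods)

    def __getitem__(self, i):
        return self._mods[i]


class Sequential(ModuleList):
    def forward(self, x: Tensor) -> Tensor:
        for mod in self._mods:
            x = mod(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(1.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        fan_in = cin * kernel**3
        self.weight = Parameter(_kaiming(rng, (cout, cin, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(_kaiming(rng, (cout,), fan_in)) if bias else None

    def forward(self, x):
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    def __init__(self, cin, cout, kernel, stride=2, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        fan_in = cin * kernel**3
        self.weight = Parameter(_kaiming(rng, (cin, cout, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(_kaiming(rng, (cout,), fan_in)) if bias else None

    def forward(self, x):
        return conv_transpose3d(x, self.weight, self.bias, self.stride)


class Linear(Module):
    def __init__(self, cin, cout, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (cin, cout), cin))
        self.bias = Parameter(_kaiming(rng, (cout,), cin)) if bias else None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels, eps=1e-5, affine=False):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels)) if affine else None
        self.beta = Parameter(np.zeros(channels)) if affine else None

    def forward(self, x):
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        y = xc / (var + self.eps).sqrt()
        if self.gamma is not None:
            y = y * self.gamma.reshape(1, -1, 1, 1, 1) + self.beta.reshape(1, -1, 1, 1, 1)
        return y


class BatchNorm3d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3, 4), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.value.ravel().astype(np.float32)
            self.running_var = (1 - m) * self.running_var + m * var.value.ravel().astype(np.float32)
            y = xc / (var + self.eps).sqrt()
        else:
            shape = (1, -1, 1, 1, 1)
            y = (x - self.running_mean.reshape(shape)) / np.sqrt(
                self.running_var.reshape(shape) + self.eps
            )
        return y * self.gamma.reshape(1, -1, 1, 1, 1) + self.beta.reshape(1, -1, 1, 1, 1)


class LayerNorm(Module):
    """Normalization over the last axis (feature vectors, token embeddings)."""

    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class MaxPool3d(Module):
    def __init__(self, kernel=2, stride=None, padding=0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride or kernel, padding

    def forward(self, x):
        return max_pool3d(x, self.kernel, self.stride, self.padding)


class AvgPool3d(Module):
    def __init__(self, kernel=2, stride=None):
        super().__init__()
        self.kernel, self.stride = kernel, stride or kernel

    def forward(self, x):
        return avg_pool3d(x, self.kernel, self.stride)


class LeakyReLU(Module):
    def __init__(self, slope=0.1):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, D, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3, 4))


def softmax_last(x: Tensor) -> Tensor:
    shifted = x - x.value.max(axis=-1, keepdims=True)  # constant shift, grad-safe
    e = shifted.exp()
    return e / e.sum(axis=-1, keepdims=True)
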