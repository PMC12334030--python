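"""Layer/module abstractions over the autodiff core.

Mirrors the familiar container pattern: a :class:`Module` discovers its
parameters and submodules through attribute assignment, supports
train/eval switching, and exposes a flat ``state_dict`` for
checkpointing.  Weight initialisation is explicit — every module takes a
``numpy.random.Generator`` so that a model built twice from the same seed
is bit-identical.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import core
from .core import Tensor


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02,
                 bound: float = 2.0) -> np.ndarray:
    """Truncated-normal draw: N(0, std²) resampled until |x| ≤ bound·std."""
    out = rng.normal(0.0, std, size=shape)
    mask = np.abs(out) > bound * std
    while mask.any():
        out[mask] = rng.normal(0.0, std, size=int(mask.sum()))
        mask = np.abs(out) > bound * std
    return out


class Parameter(Tensor):
    """A learnable tensor (``requires_grad`` always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- checkpointing -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{p.data.shape} vs {state[name].shape}")
            p.data[...] = state[name]
        for name, buf in buffers.items():
            buf[...] = state[name]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._items: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._items))] = m
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Conv3d(Module):
    """3-D convolution layer; weights are truncated-normal, biases zero."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size, *,
                 stride=1, padding=0, dilation=1, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator,
                 init_std: float = 0.02):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        k = core._triple(kernel_size)
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        self.weight = Parameter(
            trunc_normal(rng, (out_channels, in_channels // groups, *k),
                         std=init_std))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return core.conv3d(x, self.weight, self.bias, stride=self.stride,
                           padding=self.padding, dilation=self.dilation,
                           groups=self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, init_std: float = 0.02):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (out_features, in_features),
                                             std=init_std))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return core.linear(x, self.weight, self.bias)


class LayerNorm3d(Module):
    """Channel-wise layer normalisation at each voxel of (N, C, D, H, W)."""

    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return core.layer_norm_channels(x, self.weight, self.bias, self.eps)


class BatchNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        object.__setattr__(self, "_buffer_names", ("running_mean", "running_var"))

    def forward(self, x: Tensor) -> Tensor:
        return core.batch_norm(x, self.weight, self.bias,
                               self.running_mean, self.running_var,
                               training=self.training,
                               momentum=self.momentum, eps=self.eps)


class AdamW:
    """Adam with decoupled weight decay.

    State (first/second moments, step counter) is exposed through
    ``state_dict`` so training can resume bit-identically.
    """

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [a.copy() for a in self.m],
                "v": [a.copy() for a in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src
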