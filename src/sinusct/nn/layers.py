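"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    conv3d,
    conv_transpose3d,
    dropout,
    group_norm,
    layer_norm,
)

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv3d",
    "ConvTranspose3d",
    "GroupNorm",
    "LayerNorm",
    "Dropout",
]


class Parameter(Tensor):
    """A tensor registered as a trainable model weight."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        for _, m in self._named_modules():
            yield m

    def named_parameters(self):
        for prefix, mod in self._named_modules():
            for k, v in vars(mod).items():
                if isinstance(v, Parameter):
                    yield (f"{prefix}{k}", v)

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for k, v in vars(self).items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                yield from Module._named_in_seq(v, f"{prefix}{k}")

    @staticmethod
    def _named_in_seq(seq, prefix: str):
        for i, item in enumerate(seq):
            if isinstance(item, Module):
                yield from item._named_modules(f"{prefix}.{i}.")
            elif isinstance(item, (list, tuple)):
                yield from Module._named_in_seq(item, f"{prefix}.{i}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            self.weight = Parameter(np.zeros((in_features, out_features), np.float32))
        else:
            self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = in_ch * kernel ** 3
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, np.float32))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int):
        super().__init__()
        fan_in = in_ch * kernel ** 3
        self.weight = Parameter(_kaiming(rng, (in_ch, out_ch, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, np.float32))
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias, self.stride)


class GroupNorm(Module):
    def __init__(self, num_groups: int, num_channels: int):
        super().__init__()
        self.num_groups = num_groups
        self.weight = Parameter(np.ones(num_channels, np.float32))
        self.bias = Parameter(np.zeros(num_channels, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return group_norm(x, self.num_groups, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int):
        super().__init__()
        self.weight = Parameter(np.ones(dim, np.float32))
        self.bias = Parameter(np.zeros(dim, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias)


class Dropout(Module):
    """Inverted dropout; draws from its own stream so eval mode is free."""

    def __init__(self, p: float, seed: int):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.rng, self.training)
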