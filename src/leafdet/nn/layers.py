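"""Module/parameter abstractions and basic layers over the autograd engine."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, batch_norm2d, conv2d, max_pool2d, upsample_nearest2x

__all__ = [
    "manual_seed",
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "SiLU",
    "Sigmoid",
    "Identity",
    "MaxPool2d",
    "Upsample2x",
    "ConvBNAct",
]

_init_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the global parameter-initialization RNG."""
    global _init_rng
    _init_rng = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter traversal and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def forward(self, *args):
        raise NotImplementedError

    def __call__(self, *args):
        return self.forward(*args)

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        out = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    out.append(v)
        return out

    def named_state(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (for checkpoints)."""
        state: dict[str, np.ndarray] = {}

        def walk(obj: "Module", prefix: str) -> None:
            for k, v in obj.__dict__.items():
                if isinstance(v, Parameter):
                    state[f"{prefix}{k}"] = v.data
                elif isinstance(v, np.ndarray):
                    state[f"{prefix}{k}"] = v
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state mismatch on keys: {sorted(missing)[:5]} ...")
        for k, arr in state.items():
            own[k][...] = arr

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """2-d convolution; padding defaults to k//2 ('same' for stride 1)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 1,
        stride: int = 1,
        padding: int | None = None,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError(f"channels ({cin}->{cout}) not divisible by groups={groups}")
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (cin // groups) * k * k
        bound = math.sqrt(6.0 / fan_in)  # Kaiming-uniform
        self.weight = Parameter(
            _init_rng.uniform(-bound, bound, size=(cout, cin // groups, k, k))
        )
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.03, eps: float = 1e-4):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return batch_norm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, k: int, stride: int = 1):
        super().__init__()
        self.k, self.stride = k, stride

    def forward(self, x):
        return max_pool2d(x, self.k, self.stride)


class Upsample2x(Module):
    def forward(self, x):
        return upsample_nearest2x(x)


class ConvBNAct(Module):
    """Conv -> BatchNorm -> SiLU, the detector's standard convolution unit."""

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 groups: int = 1, act: bool = True):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, groups=groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = SiLU() if act else Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))
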