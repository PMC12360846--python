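"""Parameterized layers built on the autograd primitives."""

from __future__ import annotations

import numpy as np

from mapgan.nn import autograd as ag
from mapgan.nn.autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery through attributes."""

    def named_parameters(self, prefix: str = ""):
        def walk(name: str, value):
            if isinstance(value, Parameter):
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(f"{name}.{i}", item)

        for name, value in vars(self).items():
            yield from walk(f"{prefix}{name}", value)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise ValueError(
                f"state dict mismatch; missing={sorted(missing)}, "
                f"unexpected={sorted(unexpected)}"
            )
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for '{name}': {p.data.shape} vs "
                    f"{state[name].shape}"
                )
            p.data = state[name].astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """3D convolution with 'same' padding by default; Kaiming-normal init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k**3
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(
            rng.standard_normal((out_channels, in_channels, k, k, k)) * std
        )
        self.bias = Parameter(np.zeros(out_channels))
        self.stride = stride
        self.padding = (k - 1) // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias, self.stride, self.padding)


class InstanceNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.instance_norm(x, self.gamma, self.beta, self.eps)


class PReLU(Module):
    def __init__(self, channels: int, init: float = 0.25):
        self.alpha = Parameter(np.full(channels, init))

    def forward(self, x: Tensor) -> Tensor:
        return ag.prelu(x, self.alpha)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        std = float(np.sqrt(2.0 / in_features))
        self.weight = Parameter(rng.standard_normal((in_features, out_features)) * std)
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)
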