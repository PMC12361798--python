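"""Parameterised layers and the Module container."""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .autodiff import Tensor


class Module:
    """Base class: recursively collects parameters from attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match the model's parameter list")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialisation
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(c_out, c_in, k, k)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32), requires_grad=True
        )
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.matmul(x, self.weight) + self.bias


class SpectralGate(Module):
    """Learnable frequency-domain attention for a fixed feature-map shape.

    Initialised at zero spectral weights, so a freshly built gate passes
    features through unchanged (pure residual) and training learns which
    frequency bands to amplify or suppress.
    """

    def __init__(self, channels: int, height: int, width: int):
        self.weight = Tensor(
            np.zeros((channels, height, width), dtype=np.float32), requires_grad=True
        )

    def forward(self, x: Tensor) -> Tensor:
        return F.spectral_gate(x, self.weight)
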