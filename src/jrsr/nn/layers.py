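"""Layer/module abstractions over the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = ["Module", "Conv2d", "LeakyReLU", "Sequential", "Parameter"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: child modules/parameters are discovered via attributes."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """3x3 (default) 'same' convolution with He-style init.

    ``init="zero"`` zeroes the weights (and bias unless ``bias_value`` is
    given), which is how residual branches start as exact identities.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 3,
        rng: np.random.Generator | None = None,
        init: str = "he",
        gain: float = 1.0,
        bias_value: float = 0.0,
    ):
        rng = rng or np.random.default_rng(0)
        if init == "zero":
            w = np.zeros((c_out, c_in, k, k))
        else:
            std = gain * np.sqrt(2.0 / (c_in * k * k))
            w = rng.normal(0.0, std, size=(c_out, c_in, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.full(c_out, float(bias_value)))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
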