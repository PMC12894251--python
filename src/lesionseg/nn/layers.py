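"""Parameterized layers and a tiny module system."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, add, conv2d, matmul

__all__ = ["Module", "Conv2d", "Dense"]


class Module:
    """Container tracking sub-modules and parameters by attribute name."""

    def __setattr__(self, name, value):
        if isinstance(value, (Module, Tensor)):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, (Module, Tensor)) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, child in self.__dict__.get("_children", {}).items():
            path = f"{prefix}{name}"
            if isinstance(child, Tensor):
                yield path, child
            else:
                yield from child.named_parameters(prefix=path + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def set_requires_grad(self, flag: bool):
        for _, p in self.named_parameters():
            p.requires_grad = flag

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"{name}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))


class Conv2d(Module):
    """Stride-1 same-padded (optionally dilated) convolution with He init."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int = 1,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng if rng is not None else np.random.default_rng(0)
        std = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.dilation = dilation
        self.weight = Tensor(rng.normal(0.0, std, (kernel, kernel, c_in, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng if rng is not None else np.random.default_rng(0)
        std = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, std, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        if self.bias is not None:
            y = add(y, self.bias)
        return y
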