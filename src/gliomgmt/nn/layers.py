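"""Trainable layers built on the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, add, conv2d, matmul

__all__ = ["Conv2D", "Dense", "Module"]


class Module:
    """Base class: recursively collects trainable parameters."""

    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(p.data.dtype, copy=True)


class Conv2D(Module):
    """3x3 (or kxk) same-padding convolution with He-normal init."""

    def __init__(self, cin: int, cout: int, k: int = 3, *,
                 rng: np.random.Generator, dtype=np.float32):
        fan_in = k * k * cin
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, (k, k, cin, cout)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, *,
                 rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(0.0, std, (n_in, n_out)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.w), self.b)
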