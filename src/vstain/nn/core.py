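"""Parameter container, module protocol, and sequential composition."""

from __future__ import annotations

import numpy as np


class Parameter:
    """A learnable array with an accumulated gradient of the same shape."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0

    @property
    def size(self) -> int:
        return int(self.data.size)


class Module:
    """Base class.  Subclasses implement ``forward`` and ``backward``.

    ``forward(x) -> (y, cache)``; ``backward(cache, dy) -> dx`` and adds to
    each parameter's ``.grad``.
    """

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, cache, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data[...] = a


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x):
        caches = []
        for m in self.modules:
            x, c = m.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, dy):
        for m, c in zip(reversed(self.modules), reversed(caches)):
            dy = m.backward(c, dy)
        return dy

    def __iter__(self):
        return iter(self.modules)

    def __len__(self):
        return len(self.modules)
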