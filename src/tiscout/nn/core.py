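"""Minimal neural-network primitives on NumPy arrays.

The engine is deliberately small: layers are objects that cache what their
backward pass needs, ``backward`` consumes the upstream gradient and returns
the gradient with respect to the layer input while accumulating parameter
gradients in place.  Everything is deterministic given the RNG used at
construction time, which is what the reproducibility contracts of the
training pipeline rely on.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

DEFAULT_DTYPE = np.float32


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "requires_grad", "name")

    def __init__(self, value: np.ndarray, name: str = "", requires_grad: bool = True):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)
        self.requires_grad = requires_grad
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Module:
    """Base class: tracks parameters and submodules via attribute assignment."""

    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{mname}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def num_parameters(self, trainable_only: bool = True) -> int:
        return sum(
            p.size for p in self.parameters() if p.requires_grad or not trainable_only
        )

    # Subclasses implement forward(x) -> y and backward(dy) -> dx.
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # --- state (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.value for name, p in self.named_parameters()}
        for mname, m in self._named_modules():
            for key, buf in getattr(m, "_buffers", {}).items():
                state[f"{mname}{key}"] = buf
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            arr = np.asarray(state[name], dtype=p.value.dtype)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.value.shape}")
            p.value[...] = arr
        for mname, m in self._named_modules():
            for key in getattr(m, "_buffers", {}):
                full = f"{mname}{key}"
                if full in state:
                    m._buffers[key][...] = np.asarray(state[full])

    def _named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield (prefix, self)
        for mname, m in self._modules.items():
            yield from m._named_modules(prefix=f"{prefix}{mname}.")


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype=DEFAULT_DTYPE) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...], bound: float, dtype=DEFAULT_DTYPE) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape).astype(dtype)
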