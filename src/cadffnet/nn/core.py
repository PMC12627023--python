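"""Minimal NumPy module/parameter framework with explicit backward passes.

Every layer is a :class:`Module` that caches what its backward pass needs
during ``forward`` and releases gradients into ``Parameter.grad`` during
``backward``.  There is no autograd tape: composite modules chain their
children's backward calls by hand, which keeps the dependency footprint at
"numpy only" and makes each gradient auditable against finite differences.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Dict, Iterator, List, Tuple

import numpy as np

#: dtype used for newly created parameters and buffers. float32 for speed;
#: tests that compare against loop oracles at 1e-6 switch to float64.
DEFAULT_DTYPE = np.float32


def current_dtype():
    """The dtype newly constructed parameters and buffers will use."""
    return DEFAULT_DTYPE


@contextmanager
def default_dtype(dtype):
    """Temporarily change the dtype used by newly constructed modules."""
    global DEFAULT_DTYPE
    prev = DEFAULT_DTYPE
    DEFAULT_DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DEFAULT_DTYPE = prev


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=current_dtype())
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter(shape={self.data.shape})"


class Module:
    """Base class: parameter discovery, train/eval mode, state dict."""

    def __init__(self) -> None:
        self.training = True

    # -- parameter / buffer traversal ------------------------------------
    @staticmethod
    def _children(value, prefix: str):
        """Yield (name, Module) pairs, recursing through nested lists."""
        if isinstance(value, Module):
            yield prefix, value
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from Module._children(item, f"{prefix}.{i}")

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            else:
                for child_name, child in self._children(value, full):
                    yield from child.named_parameters(f"{child_name}.")

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if name.startswith("running_") and isinstance(value, np.ndarray):
                yield full, value
            else:
                for child_name, child in self._children(value, full):
                    yield from child.named_buffers(f"{child_name}.")

    # -- bookkeeping ------------------------------------------------------
    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def _set_mode(self, training: bool) -> None:
        self.training = training
        for value in vars(self).values():
            for _, child in self._children(value, ""):
                child._set_mode(training)

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        seen = set()
        for name, p in params.items():
            if name not in state:
                raise KeyError(f"missing parameter in state dict: {name}")
            if state[name].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: "
                    f"{state[name].shape} vs {p.data.shape}"
                )
            p.data[...] = state[name]
            seen.add(name)
        for name, buf in self.named_buffers():
            if name in state:
                buf[...] = state[name]
                seen.add(name)


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Kaiming-normal initialization for ReLU networks."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape)


def uniform_fan_in(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape)
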