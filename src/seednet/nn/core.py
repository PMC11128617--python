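"""Minimal layer/parameter framework with explicit reverse-mode gradients.

Modules cache whatever their backward pass needs during ``forward``; calling
``backward(grad_out)`` immediately after a forward pass accumulates parameter
gradients in place and returns the gradient with respect to the module input.
The framework is deliberately small: a static DAG of layers (sequential chains
plus residual additions and channel gates) is all the network family needs.
"""

from __future__ import annotations

from typing import Iterator, List, Tuple

import numpy as np


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.data.size)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name or 'unnamed'}, shape={self.data.shape})"


class Module:
    """Base class; children are discovered from instance attributes."""

    def __init__(self) -> None:
        self.training = True

    # -- forward/backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- introspection ---------------------------------------------------
    def named_children(self) -> Iterator[Tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def own_parameters(self) -> Iterator[Parameter]:
        for value in vars(self).values():
            if isinstance(value, Parameter):
                yield value

    def named_parameters(self, prefix: str = "",
                         _seen=None) -> Iterator[Tuple[str, Parameter]]:
        # a module (and hence its parameters) may be reachable under more
        # than one attribute; report each parameter exactly once
        seen = _seen if _seen is not None else set()
        for name, value in vars(self).items():
            if isinstance(value, Parameter) and id(value) not in seen:
                seen.add(id(value))
                yield (f"{prefix}{name}", value)
        for name, child in self.named_children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.",
                                              _seen=seen)

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self, _seen=None) -> Iterator["Module"]:
        seen = _seen if _seen is not None else set()
        if id(self) in seen:
            return
        seen.add(id(self))
        yield self
        for _, child in self.named_children():
            yield from child.modules(_seen=seen)

    # -- mode / gradient management -------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- serialization ---------------------------------------------------
    def named_buffers(self, prefix: str = "",
                      _seen=None) -> Iterator[Tuple[str, np.ndarray]]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        seen = _seen if _seen is not None else set()
        for name, value in vars(self).items():
            if (isinstance(value, np.ndarray) and not name.startswith("_")
                    and id(value) not in seen):
                seen.add(id(value))
                yield (f"{prefix}{name}", value)
        for name, child in self.named_children():
            yield from child.named_buffers(prefix=f"{prefix}{name}.",
                                           _seen=seen)

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(own) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"missing entries in state dict: {sorted(missing)}")
        for name, p in own.items():
            value = np.asarray(state[name], dtype=np.float32)
            if value.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {value.shape} vs {p.data.shape}"
                )
            p.data[...] = value
        for name, b in buffers.items():
            value = np.asarray(state[name], dtype=b.dtype)
            if value.shape != b.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {value.shape} vs {b.shape}")
            b[...] = value


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)
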