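"""Parameter containers, initialisation and optimisation.

Thin layer over :mod:`dtifuse.autodiff`: named parameter registry,
He/Glorot initialisers driven by a single seeded generator, and an Adam
optimiser.  Checkpoints are ``.npz`` archives of the named parameter
arrays plus a JSON config sidecar written by the caller.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor


class ParamStore:
    """Ordered registry of named trainable tensors."""

    def __init__(self, rng: np.random.Generator, dtype=np.float64):
        self.rng = rng
        self.dtype = np.dtype(dtype)
        self._params: dict[str, Tensor] = {}

    def add(self, name: str, array: np.ndarray) -> Tensor:
        if name in self._params:
            raise ValueError(f"duplicate parameter name {name!r}")
        t = Tensor(np.asarray(array, dtype=self.dtype), requires_grad=True)
        self._params[name] = t
        return t

    def dense(self, name: str, fan_in: int, fan_out: int) -> Tensor:
        """He-uniform weight matrix (fan_in, fan_out) for rectifier nets."""
        bound = np.sqrt(6.0 / fan_in)
        return self.add(name, self.rng.uniform(-bound, bound, (fan_in, fan_out)))

    def bias(self, name: str, size: int) -> Tensor:
        return self.add(name, np.zeros(size))

    def embedding(self, name: str, vocab_size: int, dim: int) -> Tensor:
        """Embedding table with the padding row (id 0) pinned to zero."""
        w = self.rng.normal(0.0, 0.1, (vocab_size, dim))
        w[0] = 0.0
        return self.add(name, w)

    def conv_kernel(self, name: str, k: int, c_in: int, c_out: int) -> Tensor:
        bound = np.sqrt(6.0 / (k * c_in))
        return self.add(name, self.rng.uniform(-bound, bound, (k, c_in, c_out)))

    def __getitem__(self, name: str) -> Tensor:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def items(self) -> Iterator[tuple[str, Tensor]]:
        return iter(self._params.items())

    def tensors(self) -> list[Tensor]:
        return list(self._params.values())

    def zero_grad(self) -> None:
        for t in self._params.values():
            t.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self._params.items():
            if k not in state:
                raise KeyError(f"checkpoint missing parameter {k!r}")
            if state[k].shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            t.data = np.asarray(state[k], dtype=self.dtype).copy()


class Adam:
    """Adam optimiser over a :class:`ParamStore`.

    Embedding padding rows (parameters registered via
    :meth:`ParamStore.embedding`) are kept at zero by the store's
    convention that their gradient row is zeroed before stepping.
    """

    def __init__(self, store: ParamStore, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 frozen_rows: dict[str, int] | None = None):
        self.store = store
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.frozen_rows = frozen_rows or {}
        self._m = {k: np.zeros_like(v.data) for k, v in store.items()}
        self._v = {k: np.zeros_like(v.data) for k, v in store.items()}

    def step(self) -> None:
        self.t += 1
        for name, p in self.store.items():
            if p.grad is None:
                continue
            g = p.grad
            if name in self.frozen_rows:
                g = g.copy()
                g[self.frozen_rows[name]] = 0.0
            m = self._m[name] = self.b1 * self._m[name] + (1 - self.b1) * g
            v = self._v[name] = self.b2 * self._v[name] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        self.store.zero_grad()
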