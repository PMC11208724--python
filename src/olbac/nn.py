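"""Layers, parameter containers and the Adam optimizer used by the models.

Parameters are plain :class:`~olbac.autodiff.Tensor` leaves with
``requires_grad=True``. A :class:`Module` tree exposes ``parameters()`` /
``state_dict()`` for optimization and flat ``.npz`` checkpointing, and a
``train``/``eval`` mode flag that gates dropout.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "GRUCell", "Dropout", "Adam"]


class Module:
    """Container of named parameters and sub-modules."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-s, s, size=(n_in, n_out))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class GRUCell(Module):
    """Gated recurrent unit: one update of hidden state h given input x."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.lin_x = Linear(n_in, 3 * n_hidden, rng)
        self.lin_h = Linear(n_hidden, 3 * n_hidden, rng)
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        d = self.n_hidden
        gx, gh = self.lin_x(x), self.lin_h(h)
        # column blocks: [update z | reset r | candidate n]
        z = (gx.cols(0, d) + gh.cols(0, d)).sigmoid()
        r = (gx.cols(d, 2 * d) + gh.cols(d, 2 * d)).sigmoid()
        n = (gx.cols(2 * d, 3 * d) + r * gh.cols(2 * d, 3 * d)).tanh()
        return (1.0 - z) * n + z * h


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Draws from the rng it holds."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class Adam:
    """Adam with optional external learning-rate control (set ``.lr``)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)
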