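"""First-order optimizers (Adam, SGD, RMSprop) over layer parameter dicts."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, learning_rate: float):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.lr = learning_rate
        self.state: dict[tuple, dict] = {}

    def step(self, params_and_grads):
        """``params_and_grads``: iterable of (key, param array, grad array)."""
        for key, p, g in params_and_grads:
            self._update(key, p, g)

    def _update(self, key, p, g):
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, learning_rate: float, momentum: float = 0.0):
        super().__init__(learning_rate)
        self.momentum = momentum

    def _update(self, key, p, g):
        if self.momentum:
            st = self.state.setdefault(key, {"v": np.zeros_like(p)})
            st["v"] = self.momentum * st["v"] - self.lr * g
            p += st["v"]
        else:
            p -= self.lr * g


class RMSprop(Optimizer):
    def __init__(self, learning_rate: float, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(learning_rate)
        self.rho, self.eps = rho, eps

    def _update(self, key, p, g):
        st = self.state.setdefault(key, {"s": np.zeros_like(p)})
        st["s"] = self.rho * st["s"] + (1 - self.rho) * g * g
        p -= self.lr * g / (np.sqrt(st["s"]) + self.eps)


class Adam(Optimizer):
    def __init__(
        self,
        learning_rate: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        super().__init__(learning_rate)
        self.b1, self.b2, self.eps = beta1, beta2, eps

    def _update(self, key, p, g):
        st = self.state.setdefault(key, {"m": np.zeros_like(p), "v": np.zeros_like(p), "t": 0})
        st["t"] += 1
        st["m"] = self.b1 * st["m"] + (1 - self.b1) * g
        st["v"] = self.b2 * st["v"] + (1 - self.b2) * g * g
        mhat = st["m"] / (1 - self.b1 ** st["t"])
        vhat = st["v"] / (1 - self.b2 ** st["t"])
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


OPTIMIZERS = {"Adam": Adam, "SGD": SGD, "RMSprop": RMSprop}


def make_optimizer(name: str, learning_rate: float) -> Optimizer:
    try:
        return OPTIMIZERS[name](learning_rate)
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; expected one of {sorted(OPTIMIZERS)}")
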