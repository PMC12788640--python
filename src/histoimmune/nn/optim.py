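"""AdamW with parameter groups and a cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW", "CosineAnnealing"]


class AdamW:
    """Decoupled weight-decay Adam.

    ``groups`` is a list of dicts with keys ``params`` (list of Tensors),
    ``lr`` and optionally ``weight_decay``; each group keeps its own base
    learning rate so a schedule can scale them jointly.
    """

    def __init__(self, groups, betas=(0.9, 0.999), eps: float = 1e-8):
        self.groups = []
        for g in groups:
            self.groups.append(
                {
                    "params": list(g["params"]),
                    "lr": float(g["lr"]),
                    "base_lr": float(g["lr"]),
                    "weight_decay": float(g.get("weight_decay", 0.0)),
                }
            )
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for group in self.groups:
            lr, wd = group["lr"], group["weight_decay"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                key = id(p)
                if key not in self._m:
                    self._m[key] = np.zeros_like(p.data)
                    self._v[key] = np.zeros_like(p.data)
                m, v = self._m[key], self._v[key]
                g = p.grad
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                if wd:
                    p.data *= 1.0 - lr * wd
                p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for group in self.groups:
            for p in group["params"]:
                p.grad = None


class CosineAnnealing:
    """Scales every group's lr along a half cosine from base_lr to eta_min."""

    def __init__(self, optimizer: AdamW, t_max: int, eta_min: float = 0.0):
        self.opt = optimizer
        self.t_max = max(int(t_max), 1)
        self.eta_min = eta_min
        self.t = 0

    def step(self) -> None:
        self.t = min(self.t + 1, self.t_max)
        frac = 0.5 * (1.0 + np.cos(np.pi * self.t / self.t_max))
        for group in self.opt.groups:
            group["lr"] = self.eta_min + (group["base_lr"] - self.eta_min) * frac
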