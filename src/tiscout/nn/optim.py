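"""Adam optimiser with parameter groups (per-group learning rates)."""

from __future__ import annotations

import numpy as np

from .core import Parameter


class Adam:
    """Adam with classic L2 weight decay (decay folded into the gradient),
    matching the common framework default rather than decoupled AdamW.

    ``groups`` is a list of dicts: {"params": [Parameter, ...], "lr": float}.
    """

    def __init__(self, groups: list[dict], betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.groups = []
        for g in groups:
            params = [p for p in g["params"] if p.requires_grad]
            self.groups.append({
                "params": params,
                "lr": float(g["lr"]),
                "m": [np.zeros_like(p.value, dtype=np.float32) for p in params],
                "v": [np.zeros_like(p.value, dtype=np.float32) for p in params],
            })
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for g in self.groups:
            lr = g["lr"]
            for p, m, v in zip(g["params"], g["m"], g["v"]):
                grad = p.grad
                if self.weight_decay:
                    grad = grad + self.weight_decay * p.value
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad * grad
                p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.zero_grad()
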