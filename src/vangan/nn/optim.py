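"""Adam optimiser with per-weight gradient-norm clipping."""
from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .tensor import Tensor

__all__ = ["Adam"]


class Adam:
    """Adam with optional per-parameter gradient-norm clip.

    Each parameter tensor's gradient is rescaled so its L2 norm does not
    exceed ``clip_norm`` before the moment updates, which guards against
    exploding gradients during adversarial training.
    """

    def __init__(self, params: Sequence[Tensor], lr: float = 2e-4,
                 betas=(0.5, 0.9), eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32, copy=False)
            if self.clip_norm is not None:
                norm = float(np.linalg.norm(g))
                if norm > self.clip_norm:
                    g = g * (self.clip_norm / norm)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> Dict[str, object]:
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v], "lr": self.lr}

    def load_state_dict(self, state: Dict[str, object]) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m) for m in state["m"]]
        self.v = [np.asarray(v) for v in state["v"]]
        self.lr = float(state["lr"])
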