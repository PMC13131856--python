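"""AdamW and a cosine-annealing warm-restart learning-rate schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "cosine_warm_restarts"]


class AdamW:
    """Decoupled weight-decay Adam over a flat parameter dict.

    Weight decay is applied to matrix-valued parameters only (projection and
    attention weights); biases, gains and positional encodings are exempt.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads.get(k)
            if g is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.ndim >= 2:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * update

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}


def cosine_warm_restarts(epoch: float, base_lr: float, t0: int = 10,
                         t_mult: int = 2, eta_min: float = 1e-6) -> float:
    """Learning rate at (possibly fractional) `epoch` under SGDR scheduling.

    The schedule restarts at epochs t0, t0*(1+t_mult), t0*(1+t_mult+t_mult^2),
    ... with each cycle t_mult times longer than the last.
    """
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    t_i = float(t0)
    t_cur = float(epoch)
    while t_cur >= t_i:
        t_cur -= t_i
        t_i *= t_mult
    return eta_min + 0.5 * (base_lr - eta_min) * (1.0 + np.cos(np.pi * t_cur / t_i))
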