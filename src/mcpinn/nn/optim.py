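"""Adam optimizer with Keras-style per-update learning-rate decay."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Adam over a list of :class:`Param`.

    ``decay`` shrinks the learning rate over updates as
    ``lr_t = lr / (1 + decay * t)`` — the "weight decay reduces the
    learning rate over each update" reading — and ``l2`` adds an optional
    conventional L2 penalty gradient for comparison.  Frozen parameters
    are skipped entirely (no moment updates), so freezing is exact.
    """

    def __init__(
        self,
        params: list[Param],
        lr: float = 5e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        decay: float = 0.0,
        l2: float = 0.0,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.decay = decay
        self.l2 = l2
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * self.t)
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in enumerate(self.params):
            if p.frozen:
                continue
            g = p.grad
            if self.l2:
                g = g + self.l2 * p.value
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            p.value -= lr_t * m_hat / (np.sqrt(v_hat) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=float).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=float).copy() for v in state["v"]]
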