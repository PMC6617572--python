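"""Loss functions operating on logits for numerical stability."""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_with_logits(
    logits: np.ndarray,
    labels: np.ndarray,
    w_pos: float = 1.0,
    w_neg: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Class-weighted binary cross-entropy and its gradient w.r.t. logits.

    With unit weights this is the plain mean cross-entropy.  Returns
    ``(loss, dloss/dlogits)``; the gradient is already averaged over the
    batch.
    """
    z = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=float)
    w = np.where(y > 0.5, w_pos, w_neg)
    # log(1+exp(-|z|)) formulation avoids overflow
    log1pexp = np.logaddexp(0.0, -np.abs(z))
    ce = np.where(z >= 0, z * (1 - y) + log1pexp, -z * y + log1pexp)
    loss = float(np.mean(w * ce))
    p = sigmoid(z)
    grad = w * (p - y) / z.size
    return loss, grad
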