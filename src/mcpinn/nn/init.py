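"""Weight initialization."""

from __future__ import annotations

import numpy as np


def lecun_uniform(fan_in: int, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Uniform draw from [-sqrt(3/fan_in), +sqrt(3/fan_in)].

    The bound shrinks with the number of input units so that layer
    pre-activations start with roughly unit variance.
    """
    if fan_in <= 0:
        raise ValueError("fan_in must be a positive integer")
    bound = np.sqrt(3.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)
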