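"""Pairwise-input neural network (PINN) architectures.

A PINN feeds each input side — compound and protein — through its own
stack of *separated* dense layers with no cross-connections, concatenates
the per-channel representations, and finishes with a *concatenated* dense
stack and a single sigmoid output.  Multi-channel variants attach several
feature channels per side (precomputed vectors, a dilated-CNN encoder over
one-hot sequences, or LSTM/BLSTM encoders); all channels merge at the
concatenated layer.  Because every channel's contribution to the merge is
its last separated width, the architecture balances features of very
different raw dimensionality, and it needs roughly half the parameters of
a plain feed-forward network on the concatenated input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    BLSTM,
    Conv1D,
    Dense,
    Dropout,
    Embedding,
    GlobalMaxPool1D,
    Identity,
    LSTM,
    OneHot,
    Param,
    Sequential,
    lecun_uniform,
    sigmoid,
)

__all__ = [
    "ChannelConfig",
    "PinnConfig",
    "ModelHandle",
    "elu",
    "lecun_uniform_init",
    "receptive_field",
    "build_channel",
    "build_pinn",
    "count_parameters",
    "feed_forward_parameter_count",
]


def elu(x, alpha: float = 1.0):
    """Exponential linear unit: x for x >= 0, alpha*(e^x - 1) otherwise."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, x, alpha * np.expm1(np.minimum(x, 0.0)))
    return out if out.ndim else float(out)


def lecun_uniform_init(fan_in: int, shape, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample a weight tensor from the Lecun uniform distribution."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return lecun_uniform(fan_in, tuple(shape), rng)


def receptive_field(kernel_size: int, dilation_rates: list[int]) -> int:
    """Receptive field of stacked valid-padding dilated convolutions."""
    return 1 + (kernel_size - 1) * sum(dilation_rates)


@dataclass
class ChannelConfig:
    """One input channel of a PINN side.

    kind 'dense' passes a precomputed feature vector straight to the
    separated stack; the sequence kinds ('dilated_cnn', 'lstm', 'blstm')
    consume fixed-length token-index arrays produced by
    :mod:`mcpinn.encoding`.
    """

    kind: str
    feature_dim: int | None = None          # dense
    fixed_length: int | None = None         # sequence kinds
    vocab_size: int | None = None
    n_filters: int = 16
    kernel_size: int = 12
    token_embedding_dim: int = 16
    dilation_rates: list[int] = field(default_factory=lambda: [1, 2, 4])
    units: int = 256                        # lstm / blstm

    def __post_init__(self):
        if self.kind not in ("dense", "dilated_cnn", "lstm", "blstm"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.kind == "dense":
            if not self.feature_dim or self.feature_dim < 1:
                raise ValueError("dense channel requires feature_dim >= 1")
        else:
            if not self.fixed_length or not self.vocab_size:
                raise ValueError("sequence channel requires fixed_length and vocab_size")
            if self.kind == "dilated_cnn":
                rf = receptive_field(self.kernel_size, self.dilation_rates)
                if rf > self.fixed_length:
                    raise ValueError(
                        f"receptive field {rf} exceeds fixed length {self.fixed_length}"
                    )


@dataclass
class PinnConfig:
    """Full architecture description for a (multi-channel) PINN."""

    compound_channels: list[ChannelConfig]
    protein_channels: list[ChannelConfig]
    separated_layer_widths: list[int] = field(default_factory=lambda: [1024, 256])
    concatenated_layer_widths: list[int] = field(default_factory=lambda: [256])
    dropout_initial: float = 0.1
    dropout_hidden: float = 0.5
    activation: str = "elu"
    elu_alpha: float = 1.0

    def __post_init__(self):
        if not self.compound_channels or not self.protein_channels:
            raise ValueError("at least one channel per side is required")
        if not self.concatenated_layer_widths:
            raise ValueError("at least one concatenated layer is required")
        if any(w < 1 for w in self.separated_layer_widths + self.concatenated_layer_widths):
            raise ValueError("layer widths must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PinnConfig":
        raw = json.loads(Path(path).read_text())
        raw["compound_channels"] = [ChannelConfig(**c) for c in raw["compound_channels"]]
        raw["protein_channels"] = [ChannelConfig(**c) for c in raw["protein_channels"]]
        return cls(**raw)


def build_channel(config: ChannelConfig, rng: np.random.Generator | None = None,
                  name: str = "channel", activation: str = "elu",
                  elu_alpha: float = 1.0) -> Sequential:
    """Build the encoder component of one channel.

    dense -> identity pass-through; dilated_cnn -> token embedding, stacked
    valid-padding dilated convolutions and global max pooling; lstm/blstm ->
    one-hot expansion followed by the recurrent encoder's final state.
    """
    rng = rng or np.random.default_rng()
    if config.kind == "dense":
        return Sequential([Identity(config.feature_dim, name=f"{name}/identity")], name=name)
    if config.kind == "dilated_cnn":
        layers = [Embedding(config.vocab_size, config.token_embedding_dim, rng,
                            name=f"{name}/embedding")]
        in_ch = config.token_embedding_dim
        length = config.fixed_length
        for k, dil in enumerate(config.dilation_rates):
            layers.append(Conv1D(in_ch, config.n_filters, config.kernel_size, dil,
                                 activation=activation, elu_alpha=elu_alpha, rng=rng,
                                 name=f"{name}/conv{k}"))
            in_ch = config.n_filters
            length -= (config.kernel_size - 1) * dil
        layers.append(GlobalMaxPool1D(config.n_filters, name=f"{name}/pool"))
        return Sequential(layers, name=name)
    onehot = OneHot(config.vocab_size, name=f"{name}/onehot")
    if config.kind == "lstm":
        rnn = LSTM(config.vocab_size, config.units, rng, name=f"{name}/lstm")
    else:
        rnn = BLSTM(config.vocab_size, config.units, rng, name=f"{name}/blstm")
    return Sequential([onehot, rnn], name=name)


class PinnNetwork:
    """Executable PINN: channels -> separated stacks -> merge -> output."""

    def __init__(self, config: PinnConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        act, alpha = config.activation, config.elu_alpha

        self._channels: list[Sequential] = []
        self._sep_stacks: list[Sequential] = []
        sides = [("compound", config.compound_channels), ("protein", config.protein_channels)]
        for side, channels in sides:
            for ci, ch_cfg in enumerate(channels):
                name = f"{side}{ci}"
                channel = build_channel(ch_cfg, rng, name=f"{name}/channel",
                                        activation=act, elu_alpha=alpha)
                layers: list = [Dropout(config.dropout_initial, name=f"{name}/drop_in")]
                n_in = channel.output_dim
                for li, width in enumerate(config.separated_layer_widths):
                    layers.append(Dense(n_in, width, activation=act, elu_alpha=alpha,
                                        rng=rng, name=f"{name}/sep{li}"))
                    layers.append(Dropout(config.dropout_hidden, name=f"{name}/drop{li}"))
                    n_in = width
                self._channels.append(channel)
                self._sep_stacks.append(Sequential(layers, name=f"{name}/separated"))

        merge_dim = sum(s.layers[-2].output_dim if len(s.layers) > 1 else c.output_dim
                        for c, s in zip(self._channels, self._sep_stacks))
        layers = []
        n_in = merge_dim
        for li, width in enumerate(config.concatenated_layer_widths):
            layers.append(Dense(n_in, width, activation=act, elu_alpha=alpha,
                                rng=rng, name=f"concat{li}"))
            layers.append(Dropout(config.dropout_hidden, name=f"concat_drop{li}"))
            n_in = width
        self._concat_stack = Sequential(layers, name="concatenated")
        self._output = Dense(n_in, 1, activation="linear", rng=rng, name="output")
        self._merge_dims = [s.layers[-2].output_dim if len(s.layers) > 1 else c.output_dim
                            for c, s in zip(self._channels, self._sep_stacks)]

    # -- structure ---------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return len(self._channels)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for c, s in zip(self._channels, self._sep_stacks):
            out.extend(c.params())
            out.extend(s.params())
        out.extend(self._concat_stack.params())
        out.extend(self._output.params())
        return out

    def containers(self) -> dict[str, Sequential | Dense]:
        """Freezable/re-initializable layer groups by name."""
        out: dict = {}
        for c, s in zip(self._channels, self._sep_stacks):
            out[c.name] = c
            out[s.name] = s
        out["concatenated"] = self._concat_stack
        out["output"] = self._output
        return out

    def set_frozen(self, group_names: list[str], frozen: bool = True) -> None:
        containers = self.containers()
        for name in group_names:
            if name not in containers:
                raise KeyError(f"no layer group named {name!r}; have {sorted(containers)}")
            for p in containers[name].params():
                p.frozen = frozen

    def reinitialize_groups(self, group_names: list[str], rng: np.random.Generator) -> None:
        containers = self.containers()
        for name in group_names:
            if name not in containers:
                raise KeyError(f"no layer group named {name!r}; have {sorted(containers)}")
            layer = containers[name]
            sublayers = layer.layers if isinstance(layer, Sequential) else [layer]
            for sub in sublayers:
                if hasattr(sub, "reinitialize"):
                    sub.reinitialize(rng)

    def layer_groups(self) -> dict[str, list[Param]]:
        """Named parameter groups used by freeze/re-init masks.

        Parameterless groups (e.g. dense pass-through channels) appear
        with empty lists so masks can reference every container.
        """
        return {name: layer.params() for name, layer in self.containers().items()}

    # -- execution ---------------------------------------------------------
    def forward(self, inputs: list[np.ndarray], train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Return logits (B,) for per-channel inputs in declaration order."""
        if len(inputs) != len(self._channels):
            raise ValueError(f"expected {len(self._channels)} channel inputs, got {len(inputs)}")
        hs = []
        for x, channel, stack in zip(inputs, self._channels, self._sep_stacks):
            h = channel.forward(np.asarray(x), train=train, rng=rng)
            hs.append(stack.forward(h, train=train, rng=rng))
        merged = np.concatenate(hs, axis=1)
        self._split = np.cumsum([h.shape[1] for h in hs])[:-1]
        h = self._concat_stack.forward(merged, train=train, rng=rng)
        return self._output.forward(h, train=train, rng=rng)[:, 0]

    def backward(self, grad_logits: np.ndarray) -> None:
        grad = self._output.backward(grad_logits[:, None])
        grad = self._concat_stack.backward(grad)
        for g, channel, stack in zip(np.split(grad, self._split, axis=1),
                                     self._channels, self._sep_stacks):
            g = stack.backward(g)
            channel.backward(g)

    def predict_proba(self, inputs: list[np.ndarray]) -> np.ndarray:
        """Probabilities in (0, 1); dropout disabled."""
        return sigmoid(self.forward(inputs, train=False))

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"checkpoint is missing parameter {p.name}")
            value = np.asarray(state[p.name], dtype=float)
            if value.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value = value.copy()
            p.grad = np.zeros_like(p.value)


@dataclass
class ModelHandle:
    """A built network plus its audit manifest (name, shape, frozen)."""

    network: PinnNetwork
    config: PinnConfig

    @property
    def n_parameters(self) -> int:
        return count_parameters(self)

    def manifest(self) -> list[tuple[str, tuple[int, ...], bool]]:
        return [(p.name, p.value.shape, p.frozen) for p in self.network.params()]

    def manifest_table(self) -> str:
        lines = ["name\tshape\tn\tfrozen"]
        for name, shape, frozen in self.manifest():
            n = int(np.prod(shape))
            lines.append(f"{name}\t{'x'.join(map(str, shape))}\t{n}\t{int(frozen)}")
        return "\n".join(lines) + "\n"


def build_pinn(config: PinnConfig, seed: int = 0) -> ModelHandle:
    """Construct a PINN with Lecun-uniform initialization everywhere."""
    return ModelHandle(network=PinnNetwork(config, seed=seed), config=config)


def count_parameters(model: ModelHandle, trainable_only: bool = False) -> int:
    """Exact element count of the model's weights and biases."""
    return sum(p.size for p in model.network.params()
               if not (trainable_only and p.frozen))


def feed_forward_parameter_count(input_dim: int, hidden_widths: list[int],
                                 output_dim: int = 1) -> int:
    """Closed-form weight+bias count of a plain dense network.

    Baseline for the parameter-reduction comparison against a PINN with
    the same total layer widths on the concatenated input.
    """
    total = 0
    n_in = input_dim
    for w in hidden_widths:
        total += n_in * w + w
        n_in = w
    return total + n_in * output_dim + output_dim
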