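"""End-to-end orchestration: featurize -> build -> train -> evaluate.

Fifteen named feature-pair presets cover the single-channel (SC_1..SC_6)
and multi-channel (MC_1..MC_9) model family; SC presets use two separated
layers per channel, MC presets one.  A run directory records the config
snapshot, seed, per-epoch history, layer manifest and final metrics, which
is enough to reproduce the run exactly on the same software stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dataset import CPIDataset, build_views
from .evaluation import ComparisonReport, evaluate_scores, zscore_ranking
from .model import ChannelConfig, PinnConfig, build_pinn, receptive_field
from .synthetic_data import SyntheticSpec, generate_dataset, load_dataset
from .training import TrainConfig, fit_normalizer, train
from .nn import sigmoid

__all__ = ["PRESETS", "RunConfig", "run_experiment", "run_comparison"]

# preset -> (compound channels, protein channels, n separated layers)
PRESETS: dict[str, tuple[list[str], list[str], int]] = {
    "SC_1": (["smiles"], ["aa"], 2),
    "SC_2": (["smiles"], ["protvec"], 2),
    "SC_3": (["mol2vec"], ["aa"], 2),
    "SC_4": (["mol2vec"], ["protvec"], 2),
    "SC_5": (["ecfp"], ["aa"], 2),
    "SC_6": (["ecfp"], ["protvec"], 2),
    "MC_1": (["smiles"], ["aa", "protvec"], 1),
    "MC_2": (["mol2vec"], ["aa", "protvec"], 1),
    "MC_3": (["ecfp"], ["aa", "protvec"], 1),
    "MC_4": (["smiles", "mol2vec"], ["aa"], 1),
    "MC_5": (["smiles", "mol2vec"], ["protvec"], 1),
    "MC_6": (["smiles", "ecfp"], ["aa"], 1),
    "MC_7": (["smiles", "ecfp"], ["protvec"], 1),
    "MC_8": (["smiles", "mol2vec"], ["aa", "protvec"], 1),
    "MC_9": (["smiles", "ecfp"], ["aa", "protvec"], 1),
}

_DENSE_VIEWS = ("ecfp", "mol2vec", "protvec")


def _fitting_dilations(length: int, kernel: int) -> list[int]:
    for dilations in ([1, 2, 4, 8], [1, 2, 4], [1, 2], [1]):
        if receptive_field(kernel, dilations) <= length:
            return dilations
    raise ValueError(f"fixed length {length} below the minimal receptive field")


@dataclass
class RunConfig:
    """Everything one training run needs, serializable to JSON."""

    preset: str = "SC_6"
    synthetic: SyntheticSpec | None = None
    dataset_dir: str | None = None
    output_dir: str = "runs/run0"
    seed: int = 0
    # featurization
    aggregation: str = "mean"
    protein_aggregation: str | None = None
    embedding_dim: int = 96
    embedding_epochs: int = 6
    smiles_fixed_length: int = 100
    protein_fixed_length: int = 150
    normalize: bool = True
    # architecture
    separated_layer_widths: list[int] = field(default_factory=lambda: [256, 64])
    concatenated_layer_widths: list[int] = field(default_factory=lambda: [64])
    dropout_initial: float = 0.1
    dropout_hidden: float = 0.5
    activation: str = "elu"
    kernel_size: int = 12
    n_filters: int = 16
    token_embedding_dim: int = 16
    lstm_units: int = 64
    # training
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        batch_size=128, max_epochs=50, early_stopping_patience=10))

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise KeyError(
                f"unknown preset {self.preset!r}; valid presets: {', '.join(sorted(PRESETS))}")
        if self.synthetic is None and self.dataset_dir is None:
            self.synthetic = SyntheticSpec(seed=self.seed)

    @property
    def channels(self) -> list[str]:
        comp, prot, _ = PRESETS[self.preset]
        return comp + prot

    def to_json_dict(self) -> dict:
        raw = asdict(self)
        return raw


def _prepare_dataset(config: RunConfig) -> CPIDataset:
    if config.dataset_dir is not None:
        dataset = load_dataset(config.dataset_dir)
        if not dataset.splits:
            dataset.make_splits(seed=config.seed)
    else:
        dataset = generate_dataset(config.synthetic).dataset
    build_views(
        dataset,
        config.channels,
        smiles_fixed_length=config.smiles_fixed_length,
        protein_fixed_length=config.protein_fixed_length,
        embedding_dim=config.embedding_dim,
        embedding_epochs=config.embedding_epochs,
        aggregation=config.aggregation,
        protein_aggregation=config.protein_aggregation,
        seed=config.seed,
    )
    if config.normalize:
        for name in config.channels:
            if name in _DENSE_VIEWS:
                norm = fit_normalizer(dataset.views[name], dataset.splits["train"])
                dataset.views[name] = norm.transform(dataset.views[name])
    return dataset


def _channel_config(config: RunConfig, name: str, dataset: CPIDataset) -> ChannelConfig:
    if name in _DENSE_VIEWS:
        return ChannelConfig(kind="dense", feature_dim=dataset.views[name].shape[1])
    length = (config.smiles_fixed_length if name == "smiles"
              else config.protein_fixed_length)
    vocab = dataset.vocabularies[name]
    return ChannelConfig(
        kind="dilated_cnn",
        fixed_length=length,
        vocab_size=vocab.size,
        n_filters=config.n_filters,
        kernel_size=config.kernel_size,
        token_embedding_dim=config.token_embedding_dim,
        dilation_rates=_fitting_dilations(length, config.kernel_size),
    )


def build_model_for(config: RunConfig, dataset: CPIDataset, seed: int | None = None):
    comp, prot, n_sep = PRESETS[config.preset]
    widths = config.separated_layer_widths[-n_sep:]
    pinn = PinnConfig(
        compound_channels=[_channel_config(config, c, dataset) for c in comp],
        protein_channels=[_channel_config(config, p, dataset) for p in prot],
        separated_layer_widths=widths,
        concatenated_layer_widths=config.concatenated_layer_widths,
        dropout_initial=config.dropout_initial,
        dropout_hidden=config.dropout_hidden,
        activation=config.activation,
    )
    return build_pinn(pinn, seed=config.seed if seed is None else seed)


def run_experiment(config: RunConfig, force: bool = False) -> Path:
    """Featurize, build, train and evaluate one preset; returns the run dir."""
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"run directory {out} exists; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    dataset = _prepare_dataset(config)
    model = build_model_for(config, dataset)
    history = train(model, dataset, config.train, config.channels,
                    extra_eval={"test": "test"} if "test" in dataset.splits else None)

    test_rows = dataset.splits.get("test")
    if test_rows is not None:
        scores = sigmoid(model.network.forward(dataset.inputs(config.channels, split="test")))
        report = evaluate_scores(scores, dataset.split_labels("test"))
    else:
        scores = sigmoid(model.network.forward(dataset.inputs(config.channels, split="valid")))
        report = evaluate_scores(scores, dataset.split_labels("valid"))

    (out / "config.json").write_text(json.dumps(config.to_json_dict(), default=str, indent=2))
    (out / "seed.txt").write_text(f"{config.seed}\n")
    (out / "history.tsv").write_text(history.to_tsv())
    (out / "manifest.tsv").write_text(model.manifest_table())
    (out / "metrics.json").write_text(json.dumps({
        "mcc": report.mcc, "roc_auc": report.roc_auc,
        "prc_auc": report.prc_auc, "threshold": report.threshold,
        "best_val_mcc": history.best("val_mcc"),
    }, indent=2) + "\n")
    return out


def run_comparison(configs: list[RunConfig], replicates: int,
                   names: list[str] | None = None) -> ComparisonReport:
    """Train each config ``replicates`` times and rank by z-scores.

    Each replicate re-seeds initialization and training; the metrics fed to
    the ranking are the best validation MCC and the validation ROC at that
    epoch.
    """
    if len(configs) < 2:
        raise ValueError("need at least two configs to compare")
    if replicates < 2:
        raise ValueError("need at least two replicates (SEM undefined otherwise)")
    names = names or [c.preset for c in configs]
    values = np.empty((len(configs), replicates, 2))
    for i, config in enumerate(configs):
        dataset = _prepare_dataset(config)
        for r in range(replicates):
            seed = config.seed + 1000 * r
            model = build_model_for(config, dataset, seed=seed)
            run_cfg = TrainConfig(**{**config.train.__dict__, "seed": seed})
            if run_cfg.max_epochs > 0:
                history = train(model, dataset, run_cfg, config.channels)
                series_mcc = history.series("val_mcc")
                best_epoch = max(series_mcc, key=lambda t: t[1])[0]
                values[i, r, 0] = dict(series_mcc)[best_epoch]
                values[i, r, 1] = dict(history.series("val_roc"))[best_epoch]
            else:  # untrained baseline
                scores = sigmoid(model.network.forward(
                    dataset.inputs(config.channels, split="valid")))
                rep = evaluate_scores(scores, dataset.split_labels("valid"))
                values[i, r, 0] = rep.mcc
                values[i, r, 1] = rep.roc_auc
    return zscore_ranking(values, model_names=names, metric_names=["mcc", "roc"])
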