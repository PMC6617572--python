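"""Training harness: normalization, class weighting, Adam, early stopping, CV.

Training minimizes class-weighted binary cross-entropy with Adam
(learning rate 5e-4, betas 0.9/0.999, mini-batch 1024 at full scale) and
per-update learning-rate decay of 1e-5.  Validation MCC is monitored for
early stopping.  Imbalanced tasks get the balanced positive-class weight
w_pos = n_neg / n_pos with w_neg = 1.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .dataset import CPIDataset
from .evaluation import mcc_from_scores, prc_auc, roc_auc
from .model import ModelHandle
from .nn import Adam, sigmoid, weighted_bce_with_logits

__all__ = [
    "TrainConfig",
    "Normalizer",
    "TrainingHistory",
    "EpochRecord",
    "TrainingDivergedError",
    "fit_normalizer",
    "compute_class_weights",
    "train",
    "cross_validate",
]


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"loss became non-finite at epoch {epoch}")


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-5       # per-update learning-rate decay
    l2: float = 0.0                  # optional conventional L2 penalty
    batch_size: int = 1024
    max_epochs: int = 400
    early_stopping_patience: int = 20
    use_class_weights: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.beta1, self.beta2, self.batch_size) <= 0:
            raise ValueError("rates and batch size must be positive")
        if self.early_stopping_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class Normalizer:
    """Per-feature standardization fitted on one split only.

    Zero-variance features transform to 0, keeping constant columns from
    producing NaNs.
    """

    mean_: np.ndarray
    scale_: np.ndarray
    fitted_on: str = "train"

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.scale_ + self.mean_


def fit_normalizer(features: np.ndarray, split: np.ndarray | None = None,
                   fitted_on: str = "train") -> Normalizer:
    """Fit mean/sd on the rows of ``split`` (all rows if None)."""
    features = np.asarray(features, dtype=float)
    rows = features if split is None else features[np.asarray(split)]
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a normalizer")
    scaler = StandardScaler().fit(rows)
    return Normalizer(mean_=scaler.mean_.copy(), scale_=scaler.scale_.copy(),
                      fitted_on=fitted_on)


def compute_class_weights(labels: np.ndarray) -> tuple[float, float]:
    """(w_pos, w_neg) with w_neg = 1 and w_pos = n_neg / n_pos."""
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to weight them")
    return n_neg / n_pos, 1.0


@dataclass
class EpochRecord:
    epoch: int
    loss: float
    val_mcc: float
    val_roc: float
    seconds: float
    extras: dict[str, float] = field(default_factory=dict)


@dataclass
class TrainingHistory:
    """Per-epoch trajectory; epoch indices are strictly increasing from 1."""

    records: list[EpochRecord] = field(default_factory=list)
    monitored: str = "val_mcc"

    def append(self, record: EpochRecord) -> None:
        expected = 1 if not self.records else self.records[-1].epoch + 1
        if record.epoch != expected:
            raise ValueError(f"epoch {record.epoch} out of order (expected {expected})")
        self.records.append(record)

    def series(self, metric: str | None = None) -> list[tuple[int, float]]:
        metric = metric or self.monitored
        out = []
        for r in self.records:
            value = getattr(r, metric, None)
            if value is None:
                value = r.extras[metric]
            out.append((r.epoch, float(value)))
        return out

    def best(self, metric: str | None = None) -> float:
        return max(v for _, v in self.series(metric))

    def to_tsv(self) -> str:
        extras = sorted({k for r in self.records for k in r.extras})
        header = ["epoch", "loss", "val_mcc", "val_roc", "seconds"] + extras
        lines = ["\t".join(header)]
        for r in self.records:
            row = [str(r.epoch), f"{r.loss:.6f}", f"{r.val_mcc:.6f}",
                   f"{r.val_roc:.6f}", f"{r.seconds:.3f}"]
            row += [f"{r.extras.get(k, float('nan')):.6f}" for k in extras]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def _predict(network, inputs: list[np.ndarray], batch_size: int) -> np.ndarray:
    n = inputs[0].shape[0]
    out = np.empty(n)
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        out[sl] = sigmoid(network.forward([x[sl] for x in inputs], train=False))
    return out


def train(
    model: ModelHandle,
    dataset: CPIDataset,
    config: TrainConfig,
    channels: list[str],
    train_split: str = "train",
    valid_split: str = "valid",
    extra_eval: dict[str, str] | None = None,
    optimizer: Adam | None = None,
    epoch_callback=None,
) -> TrainingHistory:
    """Train a PINN on a dataset's splits; returns the per-epoch history.

    ``extra_eval`` maps a record prefix to a split name (e.g.
    ``{"test": "test"}`` adds ``test_mcc``/``test_prc`` per epoch, the
    readouts the finetuning protocol reports).  A caller-supplied
    ``optimizer`` lets pretraining checkpoints capture optimizer state.
    """
    rng = np.random.default_rng(config.seed)
    net = model.network
    x_train = dataset.inputs(channels, split=train_split)
    y_train = dataset.split_labels(train_split)
    x_valid = dataset.inputs(channels, split=valid_split)
    y_valid = dataset.split_labels(valid_split)

    if config.use_class_weights:
        w_pos, w_neg = compute_class_weights(y_train)
    else:
        w_pos = w_neg = 1.0
    opt = optimizer or Adam(net.params(), lr=config.learning_rate, beta1=config.beta1,
                            beta2=config.beta2, decay=config.weight_decay, l2=config.l2)

    history = TrainingHistory()
    best = -np.inf
    stale = 0
    n = y_train.size
    for epoch in range(1, config.max_epochs + 1):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            rows = order[start : start + config.batch_size]
            logits = net.forward([x[rows] for x in x_train], train=True, rng=rng)
            loss, dlogits = weighted_bce_with_logits(logits, y_train[rows], w_pos, w_neg)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)

        p_valid = _predict(net, x_valid, config.batch_size)
        val_mcc = mcc_from_scores(p_valid, y_valid)
        try:
            val_roc = roc_auc(p_valid, y_valid)
        except ValueError:
            val_roc = float("nan")
        extras: dict[str, float] = {}
        for prefix, split in (extra_eval or {}).items():
            p = _predict(net, dataset.inputs(channels, split=split), config.batch_size)
            y = dataset.split_labels(split)
            extras[f"{prefix}_mcc"] = mcc_from_scores(p, y)
            extras[f"{prefix}_prc"] = prc_auc(p, y)
        history.append(EpochRecord(epoch=epoch, loss=float(np.mean(losses)),
                                   val_mcc=val_mcc, val_roc=val_roc,
                                   seconds=time.perf_counter() - t0, extras=extras))
        if epoch_callback is not None and epoch_callback(epoch, net, opt, history):
            break

        if val_mcc > best:
            best = val_mcc
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stopping_patience:
                break
    return history


def cross_validate(
    model_factory,
    dataset: CPIDataset,
    config: TrainConfig,
    channels: list[str],
    k: int = 5,
) -> tuple[list[TrainingHistory], dict[str, float]]:
    """Stratified k-fold cross-validation; folds are seeded and disjoint.

    ``model_factory(fold_index)`` must return a fresh ModelHandle.  Returns
    the per-fold histories and a summary with the mean and SEM of the best
    validation MCC across folds.
    """
    rows = dataset.splits.get("train", np.arange(dataset.n_pairs))
    y = dataset.labels[rows]
    if np.unique(y).size < 2:
        raise ValueError("cross-validation needs both classes")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    saved_splits = dataset.splits
    histories: list[TrainingHistory] = []
    fold_scores = []
    try:
        for fold, (tr, va) in enumerate(skf.split(np.zeros(rows.size), y)):
            if np.unique(y[va]).size < 2 or np.unique(y[tr]).size < 2:
                raise ValueError(f"fold {fold} is missing a class")
            dataset.splits = {"train": rows[tr], "valid": rows[va]}
            model = model_factory(fold)
            hist = train(model, dataset, config, channels)
            histories.append(hist)
            fold_scores.append(hist.best("val_mcc"))
    finally:
        dataset.splits = saved_splits
    scores = np.asarray(fold_scores)
    return histories, {
        "mean_val_mcc": float(scores.mean()),
        "sem_val_mcc": float(scores.std(ddof=1) / np.sqrt(k)),
        "fold_val_mcc": [float(s) for s in scores],
    }
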