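"""Pretrain-checkpoint / finetune transfer protocol.

A model is pretrained on a source task with a checkpoint saved every
``checkpoint_interval`` epochs (PM_i = the model after i pretraining
epochs; PM_0 is the untrained initialization).  Each checkpoint is then
finetuned on a target task under one of four strategies:

1. finetune the full network (large, similar target data);
2. finetune the full network (large, dissimilar target data);
3. freeze everything but the output classifier (small, similar);
4. freeze the layers below the concatenated stack and re-initialize the
   concatenated stack + output (small, dissimilar) — the scenario that
   fits a balanced pretraining task and a small imbalanced target task.

Finetuned checkpoints are compared on initial performance (epoch-1
metric), epochs to a fraction of the best metric, and the highest metric,
with paired t tests against PM_0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CPIDataset
from .evaluation import convergence_epoch, initial_performance
from .model import ModelHandle, PinnConfig, build_pinn
from .nn import Adam
from .training import TrainConfig, TrainingHistory, train

__all__ = [
    "PretrainSchedule",
    "FinetuneStrategy",
    "Checkpoint",
    "pretrain_with_checkpoints",
    "finetune",
    "compare_pretraining",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class PretrainSchedule:
    total_epochs: int = 140
    checkpoint_interval: int = 5

    def __post_init__(self):
        if self.total_epochs < 1 or self.checkpoint_interval < 1:
            raise ValueError("schedule values must be positive")

    @property
    def checkpoint_epochs(self) -> list[int]:
        """PM_0 plus every multiple of the interval up to the total."""
        return list(range(0, self.total_epochs + 1, self.checkpoint_interval))


@dataclass
class Checkpoint:
    """Restorable snapshot of model parameters and optimizer state."""

    epoch: int
    params: dict[str, np.ndarray]
    optimizer_state: dict | None = None
    seed: int | None = None

    def restore(self, model: ModelHandle, optimizer: Adam | None = None) -> None:
        model.network.load_state_dict(self.params)
        if optimizer is not None and self.optimizer_state is not None:
            optimizer.load_state_dict(self.optimizer_state)


@dataclass
class FinetuneStrategy:
    scenario: int
    freeze_groups: list[str] = field(default_factory=list)
    reinitialize_groups: list[str] = field(default_factory=list)

    @classmethod
    def for_scenario(cls, model: ModelHandle, scenario: int) -> "FinetuneStrategy":
        groups = sorted(model.network.containers())
        below = [g for g in groups if g not in ("concatenated", "output")]
        if scenario in (1, 2):
            return cls(scenario=scenario)
        if scenario == 3:
            return cls(scenario=scenario,
                       freeze_groups=[g for g in groups if g != "output"])
        if scenario == 4:
            return cls(scenario=scenario, freeze_groups=below,
                       reinitialize_groups=["concatenated", "output"])
        raise ValueError("scenario must be 1, 2, 3, or 4")

    def validate(self, model: ModelHandle) -> None:
        groups = model.network.containers()
        for name in self.freeze_groups + self.reinitialize_groups:
            if name not in groups:
                raise KeyError(f"strategy references unknown layer group {name!r}")


def pretrain_with_checkpoints(
    model: ModelHandle,
    source_dataset: CPIDataset,
    schedule: PretrainSchedule,
    config: TrainConfig,
    channels: list[str],
    directory: str | Path | None = None,
) -> tuple[dict[int, Checkpoint], TrainingHistory]:
    """Train on the source task, snapshotting PM_i at every schedule point.

    Early stopping is disabled so every scheduled checkpoint is produced.
    Returns the checkpoints keyed by pretraining epoch and the source-task
    history.
    """
    net = model.network
    opt = Adam(net.params(), lr=config.learning_rate, beta1=config.beta1,
               beta2=config.beta2, decay=config.weight_decay, l2=config.l2)
    wanted = set(schedule.checkpoint_epochs)
    checkpoints: dict[int, Checkpoint] = {
        0: Checkpoint(epoch=0, params=net.state_dict(),
                      optimizer_state=opt.state_dict(), seed=config.seed)
    }

    def snapshot(epoch, network, optimizer, history):
        if epoch in wanted:
            checkpoints[epoch] = Checkpoint(
                epoch=epoch, params=network.state_dict(),
                optimizer_state=optimizer.state_dict(), seed=config.seed)

    run_config = TrainConfig(**{**config.__dict__,
                                "max_epochs": schedule.total_epochs,
                                "early_stopping_patience": schedule.total_epochs})
    history = train(model, source_dataset, run_config, channels,
                    optimizer=opt, epoch_callback=snapshot)
    if directory is not None:
        for cp in checkpoints.values():
            save_checkpoint(cp, Path(directory) / f"pm_{cp.epoch}")
    return checkpoints, history


def finetune(
    pm: Checkpoint,
    architecture: PinnConfig,
    target_dataset: CPIDataset,
    strategy: FinetuneStrategy,
    config: TrainConfig,
    channels: list[str],
    reinit_seed: int = 0,
) -> tuple[TrainingHistory, ModelHandle]:
    """Finetune a pretrained checkpoint on the target task.

    The model is rebuilt from the architecture config, the checkpoint
    weights are restored, the strategy's re-initialized groups are redrawn
    with Lecun uniform and its frozen groups receive no updates.  The
    optimizer starts fresh; test-set MCC and PRC are recorded per epoch.
    """
    model = build_pinn(architecture, seed=reinit_seed)
    strategy.validate(model)
    pm.restore(model)
    if strategy.reinitialize_groups:
        model.network.reinitialize_groups(strategy.reinitialize_groups,
                                          np.random.default_rng(reinit_seed))
    if strategy.freeze_groups:
        model.network.set_frozen(strategy.freeze_groups, True)
    extra = {"test": "test"} if "test" in target_dataset.splits else None
    history = train(model, target_dataset, config, channels, extra_eval=extra)
    return history, model


def compare_pretraining(
    histories: dict[int, list[TrainingHistory]],
    fraction: float = 0.95,
    metric: str = "val_mcc",
) -> pd.DataFrame:
    """Per-checkpoint transfer report with paired t tests against PM_0.

    ``histories`` maps the pretraining epoch i of PM_i to one finetuning
    history per replicate; all PM_i must have the same replicate count.
    Columns: initial and best metric (mean over replicates), epochs to
    ``fraction`` of best, and the paired-t p-value of best-metric
    differences vs. PM_0 (1.0 when degenerate or unreplicated).
    """
    if len(histories) < 2:
        raise ValueError("need at least two checkpoints to compare")
    if 0 not in histories:
        raise ValueError("comparison requires the PM_0 baseline")
    as_lists = {pm: (h if isinstance(h, list) else [h]) for pm, h in histories.items()}
    n_reps = {len(v) for v in as_lists.values()}
    if len(n_reps) != 1:
        raise ValueError("all checkpoints need the same number of replicates")

    def stats_for(runs):
        initial = [initial_performance(h.series(metric)) for h in runs]
        best = [max(v for _, v in h.series(metric)) for h in runs]
        conv = [convergence_epoch(h.series(metric), fraction) for h in runs]
        return np.array(initial), np.array(best), np.array(conv)

    base_best = stats_for(as_lists[0])[1]
    rows = []
    for pm in sorted(as_lists):
        initial, best, conv = stats_for(as_lists[pm])
        if pm == 0 or best.size < 2 or np.allclose(best - base_best, 0):
            p = 1.0
        else:
            p = float(stats.ttest_rel(best, base_best).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append({
            "pm_epoch": pm,
            f"initial_{metric}": float(initial.mean()),
            f"epochs_to_{int(fraction * 100)}": float(np.median(conv)),
            f"best_{metric}": float(best.mean()),
            "p_vs_pm0": p,
        })
    return pd.DataFrame(rows)


def save_checkpoint(cp: Checkpoint, directory: str | Path) -> None:
    """pm_<epoch>/ directory with weights, optimizer state and a seed record."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **cp.params)
    meta = {"epoch": cp.epoch, "seed": cp.seed}
    (directory / "meta.json").write_text(json.dumps(meta) + "\n")
    if cp.optimizer_state is not None:
        state = cp.optimizer_state
        arrays = {f"m_{i}": m for i, m in enumerate(state["m"])}
        arrays.update({f"v_{i}": v for i, v in enumerate(state["v"])})
        np.savez(directory / "optimizer.npz", t=np.array(state["t"]), **arrays)


def load_checkpoint(directory: str | Path) -> Checkpoint:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    with np.load(directory / "weights.npz") as npz:
        params = {k: npz[k].copy() for k in npz.files}
    opt_state = None
    opt_path = directory / "optimizer.npz"
    if opt_path.exists():
        with np.load(opt_path) as npz:
            n = sum(1 for k in npz.files if k.startswith("m_"))
            opt_state = {
                "t": int(npz["t"]),
                "m": [npz[f"m_{i}"].copy() for i in range(n)],
                "v": [npz[f"v_{i}"].copy() for i in range(n)],
            }
    return Checkpoint(epoch=int(meta["epoch"]), params=params,
                      optimizer_state=opt_state, seed=meta.get("seed"))
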