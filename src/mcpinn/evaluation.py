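"""Binary-classification metrics, model ranking, and convergence readouts.

Three metrics drive every comparison: the Matthews correlation coefficient
(MCC) on thresholded predictions, the ROC AUC, and the precision-recall
AUC computed by the step-wise average-precision rule.  Models are ranked by
standardizing each metric across models within every replicate (z-scores),
averaging over metrics and replicates, and testing pairwise differences
with the paired Student t test (means) and the variance-ratio F test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ComparisonReport",
    "confusion_from_scores",
    "mcc",
    "mcc_from_scores",
    "roc_auc",
    "prc_auc",
    "evaluate_scores",
    "zscore_ranking",
    "initial_performance",
    "convergence_epoch",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion table is empty")


@dataclass(frozen=True)
class MetricsReport:
    mcc: float
    roc_auc: float
    prc_auc: float
    threshold: float = 0.5


def confusion_from_scores(scores: np.ndarray, labels: np.ndarray,
                          threshold: float = 0.5) -> ConfusionCounts:
    y = np.asarray(labels).astype(bool)
    pred = np.asarray(scores) >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_from_scores(scores, labels, threshold: float = 0.5) -> float:
    return mcc(confusion_from_scores(scores, labels, threshold))


def roc_auc(scores, labels) -> float:
    """Area under TPR vs. FPR over all thresholds (ties averaged)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC AUC requires both classes")
    return float(roc_auc_score(labels, scores))


def prc_auc(scores, labels) -> float:
    """Precision-recall AUC by the step-wise average-precision rule."""
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise ValueError("PRC AUC requires at least one positive label")
    return float(average_precision_score(labels, scores))


def evaluate_scores(scores, labels, threshold: float = 0.5) -> MetricsReport:
    return MetricsReport(
        mcc=mcc_from_scores(scores, labels, threshold),
        roc_auc=roc_auc(scores, labels),
        prc_auc=prc_auc(scores, labels),
        threshold=threshold,
    )


@dataclass
class ComparisonReport:
    """Ranked z-score comparison across models."""

    model_names: list[str]
    mean_z: np.ndarray                     # per model
    sem_z: np.ndarray                      # SEM over replicates
    per_metric_mean_z: np.ndarray          # models x metrics
    paired_t_p: np.ndarray                 # models x models
    f_test_p: np.ndarray                   # models x models
    metric_names: list[str] = field(default_factory=lambda: ["mcc", "roc"])

    def ranking(self) -> list[tuple[str, float, float]]:
        order = np.argsort(-self.mean_z)
        return [(self.model_names[i], float(self.mean_z[i]), float(self.sem_z[i]))
                for i in order]

    def to_tsv(self) -> str:
        lines = ["model\t" + "\t".join(f"z_{m}" for m in self.metric_names)
                 + "\taverage\tsem"]
        for name, z, sem in self.ranking():
            i = self.model_names.index(name)
            per = "\t".join(f"{v:.4f}" for v in self.per_metric_mean_z[i])
            lines.append(f"{name}\t{per}\t{z:.4f}\t{sem:.4f}")
        return "\n".join(lines) + "\n"


def _variance_ratio_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided two-sample F test on the variance ratio."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == vb:
        return 1.0
    if va < vb:
        a, b = b, a
        va, vb = vb, va
    if vb == 0:
        return 0.0
    f = va / vb
    dfn, dfd = a.size - 1, b.size - 1
    p = 2.0 * stats.f.sf(f, dfn, dfd)
    return float(min(p, 1.0))


def zscore_ranking(metric_values: np.ndarray,
                   model_names: list[str] | None = None,
                   metric_names: list[str] | None = None,
                   pooled: bool = False) -> ComparisonReport:
    """Rank models by z-scores standardized across models per slice.

    ``metric_values`` has shape (models, replicates, metrics).  Within each
    (replicate, metric) slice the model values are standardized with the
    population standard deviation, so every slice's z-scores have mean 0
    and unit variance; ``pooled=True`` instead standardizes each metric
    over all models and replicates jointly.
    """
    values = np.asarray(metric_values, dtype=float)
    if values.ndim != 3:
        raise ValueError("metric_values must be (models, replicates, metrics)")
    n_models, n_reps, n_metrics = values.shape
    if n_models < 2 or n_reps < 2:
        raise ValueError("need >= 2 models and >= 2 replicates")
    model_names = model_names or [f"model{i}" for i in range(n_models)]
    metric_names = metric_names or [f"metric{j}" for j in range(n_metrics)]

    if pooled:
        mean = values.mean(axis=(0, 1), keepdims=True)
        sd = values.std(axis=(0, 1), keepdims=True)
    else:
        mean = values.mean(axis=0, keepdims=True)
        sd = values.std(axis=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero variance across models in a (replicate, metric) slice")
    z = (values - mean) / sd

    per_model_rep = z.mean(axis=2)                       # models x replicates
    mean_z = per_model_rep.mean(axis=1)
    sem_z = per_model_rep.std(axis=1, ddof=1) / np.sqrt(n_reps)
    per_metric_mean_z = z.mean(axis=1)

    t_p = np.ones((n_models, n_models))
    f_p = np.ones((n_models, n_models))
    for i in range(n_models):
        for j in range(i + 1, n_models):
            d = per_model_rep[i] - per_model_rep[j]
            if np.allclose(d, 0):
                p = 1.0
            else:
                p = float(stats.ttest_rel(per_model_rep[i], per_model_rep[j]).pvalue)
                if math.isnan(p):
                    p = 1.0
            t_p[i, j] = t_p[j, i] = p
            fp = _variance_ratio_test(per_model_rep[i], per_model_rep[j])
            f_p[i, j] = f_p[j, i] = fp

    return ComparisonReport(
        model_names=list(model_names),
        mean_z=mean_z,
        sem_z=sem_z,
        per_metric_mean_z=per_metric_mean_z,
        paired_t_p=t_p,
        f_test_p=f_p,
        metric_names=list(metric_names),
    )


def _metric_series(history) -> list[tuple[int, float]]:
    """(epoch, metric) pairs from a TrainingHistory or a plain sequence."""
    if hasattr(history, "series"):
        return history.series()
    return [(int(e), float(m)) for e, m in history]


def initial_performance(history) -> float:
    """Validation metric at the first epoch."""
    records = _metric_series(history)
    if not records:
        raise ValueError("empty training history")
    return float(records[0][1])


def convergence_epoch(history, fraction: float = 0.98) -> int:
    """Smallest epoch whose metric reaches ``fraction`` of the history's best."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    records = _metric_series(history)
    if not records:
        raise ValueError("empty training history")
    epochs = [e for e, _ in records]
    metrics = [m for _, m in records]
    target = fraction * max(metrics)
    for e, m in zip(epochs, metrics):
        if m >= target:
            return e
    return epochs[-1]
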