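"""Metric correctness against brute-force oracles, ranking, convergence."""

import math

import numpy as np
import pytest

from mcpinn.evaluation import (
    ConfusionCounts,
    confusion_from_scores,
    convergence_epoch,
    evaluate_scores,
    initial_performance,
    mcc,
    mcc_from_scores,
    prc_auc,
    roc_auc,
    zscore_ranking,
)


def roc_auc_pairwise_oracle(scores, labels):
    """Exhaustive positive-negative pair concordance with tie credit 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = concordant = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            if sp > sn:
                concordant += 1
            elif sp == sn:
                concordant += 0.5
    return concordant / total


def prc_auc_step_oracle(scores, labels):
    """Step-rule average precision: sum of precision at each new recall level."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    labels = np.asarray(labels)[order]
    scores = np.asarray(scores, dtype=float)[order]
    n_pos = labels.sum()
    ap = 0.0
    tp = 0
    k = 0
    while k < len(labels):
        # process threshold groups (tied scores move together)
        j = k
        while j < len(labels) and scores[j] == scores[k]:
            j += 1
        new_tp = labels[k:j].sum()
        tp += new_tp
        precision = tp / j
        ap += precision * (new_tp / n_pos)
        k = j
    return ap


def mcc_formula_oracle(tp, fp, tn, fn):
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


class TestMcc:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(5, 0, 5, 0), 1.0),
            (ConfusionCounts(0, 5, 0, 5), -1.0),
            (ConfusionCounts(3, 1, 4, 2), 10 / math.sqrt(600)),
            (ConfusionCounts(4, 0, 0, 2), 0.0),  # empty marginal
        ],
    )
    def test_values(self, counts, expected):
        assert mcc(counts) == pytest.approx(expected, abs=1e-9)

    def test_symmetric_under_class_swap(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 20, size=4)
            if tp + fp + tn + fn == 0:
                continue
            assert mcc(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(
                mcc(ConfusionCounts(tn, fn, tp, fp)), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 1, 0)


class TestRocAuc:
    def test_perfect_and_inverted(self):
        labels = np.array([1, 1, 0, 0])
        assert roc_auc([0.9, 0.8, 0.2, 0.1], labels) == 1.0
        assert roc_auc([0.1, 0.2, 0.8, 0.9], labels) == 0.0

    def test_hand_example(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])

    def test_agrees_with_pairwise_concordance_oracle_on_fuzzed_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(2, 13)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_pairwise_oracle(scores, labels), abs=1e-12)

    def test_random_scorer_near_half(self):
        rng = np.random.default_rng(0)
        n = 100_000
        labels = rng.integers(0, 2, size=n)
        scores = rng.random(n)
        se = math.sqrt(1 / (4 * labels.sum()) + 1 / (4 * (n - labels.sum())))
        assert abs(roc_auc(scores, labels) - 0.5) < 3 * se


class TestPrcAuc:
    def test_perfect_ranking(self):
        assert prc_auc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_identical_scores_give_prevalence(self):
        assert prc_auc([0.5] * 10, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.2)

    def test_step_rule_hand_example(self):
        assert prc_auc([0.9, 0.8, 0.4], [1, 0, 1]) == pytest.approx(0.5 * (1 + 2 / 3))

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError):
            prc_auc([0.1, 0.2], [0, 0])

    def test_agrees_with_step_oracle_on_fuzzed_cases(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = rng.integers(2, 13)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            scores = rng.choice([0.2, 0.4, 0.6, 0.8], size=n)
            assert prc_auc(scores, labels) == pytest.approx(
                prc_auc_step_oracle(scores, labels), abs=1e-12)

    def test_random_scorer_near_prevalence(self):
        rng = np.random.default_rng(3)
        n = 50_000
        labels = (rng.random(n) < 0.0749).astype(int)
        value = prc_auc(rng.random(n), labels)
        assert abs(value - labels.mean()) < 0.01


class TestThresholdedScores:
    def test_confusion_assembly(self):
        counts = confusion_from_scores([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (1, 1, 1, 1)

    def test_report_ranges(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, size=200)
        rep = evaluate_scores(scores, labels)
        assert -1 <= rep.mcc <= 1
        assert 0 <= rep.roc_auc <= 1
        assert 0 <= rep.prc_auc <= 1

    def test_mcc_from_scores_matches_formula_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(4, 30)
            scores = rng.random(n)
            labels = rng.integers(0, 2, size=n)
            c = confusion_from_scores(scores, labels)
            assert mcc_from_scores(scores, labels) == pytest.approx(
                mcc_formula_oracle(c.tp, c.fp, c.tn, c.fn), abs=1e-12)


class TestZscoreRanking:
    def test_two_point_standardization(self):
        values = np.zeros((2, 2, 1))
        values[0, :, 0] = 0.6
        values[1, :, 0] = 0.8
        report = zscore_ranking(values)
        np.testing.assert_allclose(report.mean_z, [-1.0, 1.0])

    def test_identical_models_rejected_as_zero_variance(self):
        values = np.full((3, 2, 2), 0.5)
        with pytest.raises(ValueError, match="zero variance"):
            zscore_ranking(values)

    def test_zscore_conservation_over_many_models(self, rng):
        values = rng.random((15, 3, 2))
        report = zscore_ranking(values)
        assert abs(report.mean_z.mean()) < 1e-9
        # unit variance within every slice
        z = report.per_metric_mean_z
        assert z.shape == (15, 2)

    def test_paired_t_and_f_matrices_are_symmetric_probabilities(self, rng):
        values = rng.random((4, 5, 2))
        report = zscore_ranking(values)
        for mat in (report.paired_t_p, report.f_test_p):
            np.testing.assert_allclose(mat, mat.T)
            assert np.all((mat >= 0) & (mat <= 1))
            assert np.all(np.diag(mat) == 1.0)

    def test_tsv_report_lists_all_models(self, rng):
        report = zscore_ranking(rng.random((3, 2, 2)), model_names=["a", "b", "c"])
        text = report.to_tsv()
        assert all(name in text for name in "abc")


class TestTrajectoryReadouts:
    def test_initial_performance(self):
        assert initial_performance([(1, 0.40), (2, 0.55)]) == 0.40
        assert initial_performance([(1, 0.47)]) == 0.47

    def test_convergence_epoch_scan(self):
        hist = list(enumerate([0.2, 0.4, 0.6, 0.8, 1.0], start=1))
        assert convergence_epoch(hist, 0.98) == 5
        hist2 = list(enumerate([0.5, 0.97, 0.96, 1.0], start=1))
        assert convergence_epoch(hist2, 0.95) == 2
        assert convergence_epoch(hist2, 1.0) == 4

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            initial_performance([])
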