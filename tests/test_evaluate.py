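"""Metric suite against brute-force recounts and the pairwise AUC oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctgkit.evaluate import (
    EvalReport,
    TrainConfig,
    compute_metrics,
    gdr,
    roc_auc,
    split_dataset,
)
from ctgkit.records import BinaryLabel


def pairwise_auc(labels, scores):
    """O(n^2) oracle: P(score_pos > score_neg), ties counted 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def brute_force_counts(y, p):
    """Element-by-element recount of the confusion cells (normal=0=positive)."""
    tp = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
    fn = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
    fp = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
    tn = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
    return tp, fn, fp, tn


class TestSplitDataset:
    def test_cohort_counts_largest_remainder(self):
        records = [BinaryLabel.NORMAL] * 224 + [BinaryLabel.ABNORMAL] * 102
        tr, te = split_dataset(records, (0.7, 0.3), seed=0)
        assert (len(tr), len(te)) == (228, 98)
        assert tr.count(BinaryLabel.NORMAL) == 157
        assert te.count(BinaryLabel.NORMAL) == 67

    def test_all_train_fraction(self):
        records = [BinaryLabel.NORMAL] * 5 + [BinaryLabel.ABNORMAL] * 5
        tr, te = split_dataset(records, (1.0, 0.0), seed=0)
        assert len(tr) == 10 and not te

    def test_same_seed_identical_partition(self):
        records = list(np.random.default_rng(0).integers(0, 2, 50))
        a = split_dataset(records, (0.7, 0.3), seed=3)
        b = split_dataset(records, (0.7, 0.3), seed=3)
        assert a == b

    def test_disjoint_and_exhaustive(self):
        records = [(i, BinaryLabel.NORMAL if i % 3 else BinaryLabel.ABNORMAL) for i in range(40)]
        tr, te = split_dataset(records, (0.7, 0.3), seed=1, labels=[r[1] for r in records])
        assert sorted([r[0] for r in tr] + [r[0] for r in te]) == list(range(40))

    def test_vanishing_class_rejected(self):
        records = [BinaryLabel.NORMAL] * 50 + [BinaryLabel.ABNORMAL]
        with pytest.raises(ValueError, match="absent"):
            split_dataset(records, (0.7, 0.3), seed=0)


class TestComputeMetrics:
    def test_worked_confusion_example(self):
        # TP=3 FN=1 FP=2 TN=4 with normal as the positive class
        y = [0] * 4 + [1] * 6
        p = [0, 0, 0, 1] + [0, 0, 1, 1, 1, 1]
        rep = compute_metrics(y, p)
        assert rep.confusion.tolist() == [[3, 1], [2, 4]]
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.precision_normal == pytest.approx(3 / 5)
        assert rep.recall_normal == pytest.approx(3 / 4)
        assert rep.precision_abnormal == pytest.approx(4 / 5)
        assert rep.recall_abnormal == pytest.approx(4 / 6)

    def test_equal_precision_recall_f1(self):
        prec = rec = 0.9
        f1 = 2 * prec * rec / (prec + rec)
        assert f1 == pytest.approx(0.9)
        y = [0] * 9 + [1] + [1] * 9 + [0]
        p = [0] * 10 + [1] * 10
        rep = compute_metrics(y, p)
        assert rep.f1_normal == pytest.approx(0.9)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(5, 60)
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            rep = compute_metrics(y, p)
            tp, fn, fp, tn = brute_force_counts(y, p)
            assert rep.confusion.tolist() == [[tp, fn], [fp, tn]]
            assert rep.confusion.sum() == rep.n == n
            assert rep.accuracy == pytest.approx((tp + tn) / n)

    def test_matches_sklearn(self):
        from sklearn.metrics import precision_score, recall_score

        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 300)
        p = rng.integers(0, 2, 300)
        rep = compute_metrics(y, p)
        # sklearn with pos_label=0 mirrors the normal-positive convention
        assert rep.precision_normal == pytest.approx(precision_score(y, p, pos_label=0))
        assert rep.recall_normal == pytest.approx(recall_score(y, p, pos_label=0))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


class TestRocAuc:
    def test_perfect_separation_auc_one(self):
        roc, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 4000)
        s = rng.random(4000)
        _roc, auc = roc_auc(y, s)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(10, 80))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = rng.integers(0, 5, n).astype(float)  # heavy ties
            _roc, auc = roc_auc(y, s)
            assert abs(auc - pairwise_auc(y, s)) < 1e-9

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 500)
        s = rng.random(500)
        _roc, auc = roc_auc(y, s)
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 50)
        if len(np.unique(y)) < 2:
            return
        s = rng.random(50)
        _r1, a1 = roc_auc(y, s)
        _r2, a2 = roc_auc(y, np.exp(3 * s) + 7)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_curve_shape_invariants(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 100)
        s = rng.random(100)
        roc, _auc = roc_auc(y, s)
        fpr = [p[0] for p in roc]
        tpr = [p[1] for p in roc]
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestGDR:
    @pytest.mark.parametrize("a,b,expected,flag", [
        (0.9, 0.72, 20.0, True),
        (0.9, 0.9, 0.0, False),
        (0.9, 0.80, 100 * (0.9 - 0.8) / 0.9, False),
    ])
    def test_worked_values(self, a, b, expected, flag):
        value, adapted = gdr(a, b)
        assert value == pytest.approx(expected)
        assert adapted is flag

    def test_zero_training_auc_rejected(self):
        with pytest.raises(ValueError):
            gdr(0.0, 0.5)


class TestTrainConfig:
    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(split=(0.8, 0.3))

    def test_zero_epochs_leaves_model_unchanged(self):
        from ctgkit.evaluate import train
        from ctgkit.model import ModelConfig, SKConfig, build_model

        model, _ = build_model(
            ModelConfig(growth_rate=8, block_layout=(1,), num_classes=2, in_channels=1),
            SKConfig(), seed=0)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        X = np.random.default_rng(0).random((8, 1, 16, 16), dtype=np.float32)
        model, history = train(model, (X, np.zeros(8, int)), TrainConfig(epochs=0))
        assert not history["loss"]
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)
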