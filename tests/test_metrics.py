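"""Metric correctness against exhaustive counting, dual-formula Pearson,
and library cross-checks; subject splitting; NASA-TLX label rules."""

import numpy as np
import pytest
from scipy import stats
from sklearn import metrics as skm

from facephys.metrics import classification_metrics, regression_metrics
from facephys.training import nasa_tlx_label, subject_split


def counting_oracle(probs, labels, thr=0.5):
    """Element-by-element confusion counting, no vectorization."""
    tp = fp = fn = tn = 0
    for p, y in zip(probs, labels):
        pred = 1 if p >= thr else 0
        if pred == 1 and y == 1:
            tp += 1
        elif pred == 1 and y == 0:
            fp += 1
        elif pred == 0 and y == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def pearson_dual(x, y):
    """Second, independent Pearson formula: mean of z-score products."""
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    return float((zx * zy).mean())


class TestClassificationMetrics:
    def test_hand_computed_confusion(self):
        # TP=3, FP=1, FN=2, TN=4
        probs = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1, 0.15, 0.05])
        labels = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
        m = classification_metrics(probs, labels)
        assert (m.tp, m.fp, m.fn, m.tn) == (3, 1, 2, 4)
        assert m.accuracy == pytest.approx(0.7)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)
        assert m.f1 == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        m = classification_metrics(np.array([0.9, 0.1, 0.8]), np.array([1, 0, 1]))
        assert m.accuracy == m.f1 == m.sensitivity == m.specificity == 1.0

    def test_all_positive_on_balanced_set(self):
        m = classification_metrics(np.array([0.9] * 4), np.array([1, 1, 0, 0]))
        assert m.sensitivity == 1.0 and m.specificity == 0.0
        assert m.accuracy == 0.5

    def test_undefined_ratios_flagged_not_nan(self):
        m = classification_metrics(np.array([0.1, 0.2]), np.array([0, 0]))
        assert m.sensitivity is None
        assert m.specificity == 1.0

    def test_thousand_random_instances_vs_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 20))
            probs = rng.uniform(0, 1, n)
            labels = rng.integers(0, 2, n)
            m = classification_metrics(probs, labels)
            assert (m.tp, m.fp, m.fn, m.tn) == counting_oracle(probs, labels)

    def test_against_sklearn(self):
        rng = np.random.default_rng(1)
        probs = rng.uniform(0, 1, 500)
        labels = rng.integers(0, 2, 500)
        m = classification_metrics(probs, labels)
        pred = (probs >= 0.5).astype(int)
        assert m.accuracy == pytest.approx(skm.accuracy_score(labels, pred))
        assert m.f1 == pytest.approx(skm.f1_score(labels, pred))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.array([]), np.array([]))


class TestRegressionMetrics:
    def test_perfect(self):
        m = regression_metrics(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert m.mae == 0 and m.rmse == 0 and m.pearson_r == pytest.approx(1.0)

    def test_constant_shift(self):
        t = np.array([5.0, 6.0, 9.0])
        m = regression_metrics(t + 2.0, t)
        assert m.mae == pytest.approx(2.0)
        assert m.rmse == pytest.approx(2.0)
        assert m.pearson_r == pytest.approx(1.0)

    def test_small_example_dual_formula(self):
        preds = np.array([1.0, 2.0, 3.0])
        targets = np.array([1.0, 2.0, 4.0])
        m = regression_metrics(preds, targets)
        assert m.mae == pytest.approx(1 / 3)
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))
        assert m.pearson_r == pytest.approx(pearson_dual(preds, targets))

    def test_constant_series_flagged(self):
        m = regression_metrics(np.array([2.0, 2.0]), np.array([1.0, 3.0]))
        assert m.pearson_r is None

    def test_thousand_random_instances_dual_pearson(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            p = rng.normal(0, 1, n)
            t = rng.normal(0, 1, n)
            m = regression_metrics(p, t)
            if m.pearson_r is not None:
                assert m.pearson_r == pytest.approx(pearson_dual(p, t), abs=1e-10)
                assert m.pearson_r == pytest.approx(stats.pearsonr(p, t)[0], abs=1e-10)


class TestSubjectSplit:
    def test_ten_subjects_six_two_two(self):
        subjects = [f"S{i}" for i in range(10)]
        assign = subject_split(subjects, seed=0)
        counts = {v: list(assign.values()).count(v) for v in ("train", "val", "test")}
        assert counts == {"train": 6, "val": 2, "test": 2}

    def test_deterministic_given_seed(self):
        subjects = [f"S{i}" for i in range(13)]
        assert subject_split(subjects, seed=7) == subject_split(subjects, seed=7)
        assert subject_split(subjects, seed=7) != subject_split(subjects, seed=8)

    def test_partition_law(self):
        subjects = {f"S{i}" for i in range(17)}
        assign = subject_split(subjects, seed=3)
        assert set(assign) == subjects  # exhaustive, disjoint by construction

    def test_no_window_leakage(self):
        """Every window inherits its subject's split; no subject appears in
        two splits."""
        rng = np.random.default_rng(0)
        win_subjects = np.array([f"S{i}" for i in rng.integers(0, 10, 200)])
        assign = subject_split(win_subjects, seed=1)
        per_subject = {s: {assign[s]} for s in set(win_subjects)}
        assert all(len(v) == 1 for v in per_subject.values())

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            subject_split(["a", "b", "c"], seed=0)


class TestNasaTlx:
    @pytest.mark.parametrize(
        "score,expected", [(25, "low"), (65, "high"), (45, "excluded"),
                           (29.9, "low"), (60.1, "high")]
    )
    def test_edream_bands(self, score, expected):
        assert nasa_tlx_label(score, "edream") == expected

    @pytest.mark.parametrize(
        "score,ndrt,expected",
        [(15, True, "high"), (15, False, "low"), (5, True, "low")],
    )
    def test_mcdd_rule(self, score, ndrt, expected):
        assert nasa_tlx_label(score, "mcdd", ndrt_present=ndrt) == expected

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            nasa_tlx_label(float("nan"), "edream")
        with pytest.raises(ValueError):
            nasa_tlx_label(50, "unknown")
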