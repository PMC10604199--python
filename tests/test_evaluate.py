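"""Confusion counting, metric formulas, AUC and fold construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epifuse.evaluate import (
    ConfusionCounts,
    confusion,
    metrics_from_counts,
    roc_auc,
    stratified_folds,
)
from epifuse.io_manifest import ValidationError


def brute_force_confusion(pred, lab):
    tp = tn = fp = fn = 0
    for p, y in zip(pred, lab):
        if p == 1 and y == 1:
            tp += 1
        elif p == 0 and y == 0:
            tn += 1
        elif p == 1 and y == 0:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def brute_force_auc(scores, labels):
    """All-pairs comparison; ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_all_positive_predictions(self):
        c = confusion([1, 1], [1, 0])
        assert (c.TP, c.FP, c.TN, c.FN) == (1, 1, 0, 0)

    def test_random_hundred_matches_loop_recount(self, rng):
        pred = rng.integers(0, 2, 100)
        lab = rng.integers(0, 2, 100)
        c = confusion(pred, lab)
        assert (c.TP, c.TN, c.FP, c.FN) == brute_force_confusion(pred, lab)
        assert c.total == 100

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            confusion([1, 0], [1])


class TestMetricFormulas:
    def test_hand_computed_example(self):
        m = metrics_from_counts(ConfusionCounts(TP=8, TN=7, FP=3, FN=2))
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity_as_printed"] == pytest.approx(8 / 11)
        assert m["f1_as_printed"] == pytest.approx(2 * 0.8 * (8 / 11) / (0.8 + 8 / 11))
        assert m["f1_as_printed"] == pytest.approx(0.7619, abs=2e-4)
        assert m["specificity_standard"] == pytest.approx(0.7)

    def test_perfect_classifier_all_ones(self):
        m = metrics_from_counts(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        for name in ("accuracy", "sensitivity", "specificity_as_printed",
                     "f1_as_printed", "specificity_standard", "f1_standard"):
            assert m[name] == 1.0

    def test_zero_denominator_reported_undefined(self):
        m = metrics_from_counts(ConfusionCounts(TP=0, TN=4, FP=0, FN=0))
        assert np.isnan(m["sensitivity"])
        assert np.isnan(m["specificity_as_printed"])
        assert m["accuracy"] == 1.0

    def test_printed_specificity_is_precision_so_f1s_coincide(self, rng):
        """The nonstandard printed specificity TP/(TP+FP) is precision,
        which forces the printed F1 to equal the standard F1 exactly."""
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 30, 4)
            m = metrics_from_counts(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            if np.isnan(m["f1_as_printed"]) or np.isnan(m["f1_standard"]):
                assert np.isnan(m["f1_as_printed"]) == np.isnan(m["f1_standard"])
            else:
                assert m["f1_as_printed"] == m["f1_standard"]

    def test_against_brute_force_oracle(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 50, 4))
            m = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
            total = tp + tn + fp + fn
            if total:
                assert m["accuracy"] == pytest.approx((tp + tn) / total)
            if tp + fn:
                assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m["specificity_standard"] == pytest.approx(tn / (tn + fp))


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_fifty_random_sets_match_all_pairs_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            labels = np.concatenate([[0, 1], rng.integers(0, 2, n - 2)])
            scores = np.round(rng.random(n), 2)  # rounding forces some ties
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores.tolist(), labels.tolist())
            )

    def test_matches_reference_implementation(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="both classes"):
            roc_auc([0.1, 0.9], [1, 1])


class TestFolds:
    def test_ten_plus_ten_gives_balanced_folds(self):
        labels = np.array([1] * 10 + [0] * 10)
        folds = stratified_folds(labels, k=5, seed=0)
        assert len(folds) == 5
        for _, te in folds:
            assert len(te) == 4
            assert labels[te].sum() == 2  # 2 EP + 2 HC per fold

    def test_partition_property(self):
        labels = np.array([1] * 8 + [0] * 7)
        folds = stratified_folds(labels, k=5, seed=3)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(15))  # disjoint + exhaustive
        for tr, te in folds:
            assert set(tr) | set(te) == set(range(15))
            assert not set(tr) & set(te)

    def test_seeded_assignment_reproducible(self):
        labels = np.array([1] * 10 + [0] * 10)
        a = stratified_folds(labels, k=5, seed=42)
        b = stratified_folds(labels, k=5, seed=42)
        for (tra, tea), (trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tea, teb)

    def test_too_few_per_class(self):
        labels = np.array([1] * 3 + [0] * 10)
        with pytest.raises(ValidationError, match="stratified"):
            stratified_folds(labels, k=5, seed=0)


@settings(max_examples=50, deadline=None)
@given(st.data())
def test_auc_equals_normalised_mann_whitney(data):
    n = data.draw(st.integers(4, 25))
    labels = np.array(data.draw(
        st.lists(st.integers(0, 1), min_size=n, max_size=n)
    ))
    if labels.sum() in (0, n):
        labels[0], labels[1] = 0, 1
    scores = np.array(data.draw(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)
    ))
    from scipy.stats import mannwhitneyu

    u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
    n1, n0 = labels.sum(), n - labels.sum()
    assert roc_auc(scores, labels) == pytest.approx(u / (n1 * n0))
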