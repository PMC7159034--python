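"""Confusion-matrix metrics, stratified folds and Welch comparison."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef, precision_score, recall_score

from triagecap import (
    ConfusionCounts,
    Corpus,
    Document,
    compare_runs,
    confusion,
    metrics,
    stratified_folds,
)

R, I = "relevant", "irrelevant"


def labels_from_counts(c: ConfusionCounts):
    gold = [R] * (c.tp + c.fn) + [I] * (c.fp + c.tn)
    pred = [R] * c.tp + [I] * c.fn + [R] * c.fp + [I] * c.tn
    return gold, pred


class TestConfusion:
    def test_perfect_agreement(self):
        gold = [R] * 4 + [I] * 6
        c = confusion(gold, gold)
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 0, 0, 6)

    def test_total_disagreement(self):
        gold = [R, R, I, I]
        pred = [I, I, R, R]
        c = confusion(gold, pred)
        assert c.tp == 0 and c.tn == 0

    def test_enumeration(self):
        c = confusion([R, R, R, I, I], [R, R, I, R, I])
        assert (c.tp, c.fn, c.fp, c.tn) == (2, 1, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([R], [R, I])

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            confusion([R], ["maybe"])


class TestMetrics:
    def test_perfect(self):
        m = metrics(ConfusionCounts(10, 0, 0, 30))
        assert (m.precision, m.recall, m.f_measure, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_random_equivalent(self):
        m = metrics(ConfusionCounts(5, 5, 5, 5))
        assert m.mcc == pytest.approx(0.0)

    def test_total_disagreement_mcc(self):
        m = metrics(ConfusionCounts(0, 10, 10, 0))
        assert m.mcc == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # tp=5 fp=2 fn=3 tn=10: P=5/7, R=5/8, MCC=(50-6)/sqrt(7*8*12*13)
        m = metrics(ConfusionCounts(5, 2, 3, 10))
        assert m.precision == pytest.approx(5 / 7)
        assert m.recall == pytest.approx(0.625)
        assert m.mcc == pytest.approx(44 / math.sqrt(7 * 8 * 12 * 13), abs=1e-12)
        assert m.mcc == pytest.approx(0.4708, abs=1e-4)

    def test_zero_over_zero_convention(self):
        with pytest.warns(UserWarning):
            m = metrics(ConfusionCounts(0, 0, 0, 10))
        assert m.precision == 0.0 and m.recall == 0.0 and m.mcc == 0.0

    def test_matches_sklearn_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            c = ConfusionCounts(*(int(x) for x in rng.integers(1, 50, size=4)))
            gold, pred = labels_from_counts(c)
            m = metrics(c)
            assert m.precision == pytest.approx(
                precision_score(gold, pred, pos_label=R), abs=1e-9)
            assert m.recall == pytest.approx(
                recall_score(gold, pred, pos_label=R), abs=1e-9)
            assert m.mcc == pytest.approx(matthews_corrcoef(gold, pred), abs=1e-9)

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariants(self, counts):
        tp, fp, fn, tn = counts
        c = ConfusionCounts(tp, fp, fn, tn)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = metrics(c)
            swapped = metrics(ConfusionCounts(tn, fn, fp, tp))
        # class swap leaves |MCC| unchanged; F lies between P and R
        assert abs(m.mcc) == pytest.approx(abs(swapped.mcc), abs=1e-12)
        if m.precision + m.recall > 0:
            assert min(m.precision, m.recall) - 1e-12 <= m.f_measure
            assert m.f_measure <= max(m.precision, m.recall) + 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        gold = [R if x else I for x in rng.integers(0, 2, 30)]
        pred = [R if x else I for x in rng.integers(0, 2, 30)]
        m1 = metrics(confusion(gold, pred))
        order = rng.permutation(30)
        m2 = metrics(confusion([gold[i] for i in order], [pred[i] for i in order]))
        assert m1 == m2


def _corpus(n_rel, n_irr):
    docs = [Document(id=f"r{j}", title="t", label=R) for j in range(n_rel)]
    docs += [Document(id=f"i{j}", title="t", label=I) for j in range(n_irr)]
    return Corpus(docs)


class TestStratifiedFolds:
    def test_exact_division(self):
        corpus = _corpus(10, 100)
        assign = stratified_folds(corpus, 5, seed=1)
        labels = np.array([d.label for d in corpus], dtype=object)
        for j in range(5):
            fold = assign == j
            assert int(np.sum(fold & (labels == R))) == 2
            assert int(np.sum(fold & (labels == I))) == 20

    def test_fold_sizes_twenty_percent(self):
        corpus = _corpus(13, 118)
        assign = stratified_folds(corpus, 5, seed=0)
        sizes = np.bincount(assign)
        assert sizes.sum() == 131
        assert sizes.max() - sizes.min() <= 2

    def test_determinism(self):
        corpus = _corpus(10, 40)
        np.testing.assert_array_equal(
            stratified_folds(corpus, 5, seed=7), stratified_folds(corpus, 5, seed=7)
        )

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(_corpus(3, 50), 5, seed=0)


class TestCompareRuns:
    def test_identical_sequences(self):
        assert compare_runs([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]) == (0.0, 1.0)

    def test_separated_samples(self):
        t, p = compare_runs([0.9, 0.91, 0.89], [0.1, 0.11, 0.09])
        assert p < 1e-4

    def test_matches_welch_formula(self):
        a = [0.70, 0.72, 0.71, 0.73, 0.69]
        b = [0.60, 0.62, 0.61, 0.63, 0.59]
        t, p = compare_runs(a, b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        se = math.sqrt(va / len(a) + vb / len(b))
        t_ref = (ma - mb) / se
        df = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        from scipy.stats import t as t_dist
        p_ref = 2 * t_dist.sf(abs(t_ref), df)
        assert t == pytest.approx(t_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            compare_runs([0.5], [0.5, 0.6])
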