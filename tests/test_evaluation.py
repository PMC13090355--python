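"""Splitting and metric formulas against independent counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinopt.evaluation import (
    ConfusionTable,
    basic_metrics,
    binary_cross_entropy,
    confusion,
    metric_report,
    rank_auc,
    stratified_split,
)


class TestSplit:
    def test_exact_fractions_per_class(self):
        labels = np.array([0] * 100 + [1] * 100)
        sp = stratified_split(labels, (0.70, 0.15, 0.15), seed=0)
        for idx, expected in ((sp.train, 140), (sp.val, 30), (sp.test, 30)):
            assert len(idx) == expected
            assert np.sum(labels[idx] == 0) == expected // 2

    def test_partition_is_disjoint_and_complete(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=137)
        sp = stratified_split(labels, seed=3)
        all_idx = np.concatenate([sp.train, sp.val, sp.test])
        assert len(all_idx) == len(labels)
        assert len(np.unique(all_idx)) == len(labels)

    def test_fundus_cohort_counts_match_largest_remainder(self):
        # 396 glaucoma / 309 normal at 70/15/15
        labels = np.array([1] * 396 + [0] * 309)
        sp = stratified_split(labels, seed=0)
        # hand largest-remainder: 396 -> 277.2/59.4/59.4; the leftover item
        # goes to the earlier of the tied remainders (val): (277, 60, 59)
        assert np.sum(labels[sp.train] == 1) == 277
        assert np.sum(labels[sp.val] == 1) == 60
        assert np.sum(labels[sp.test] == 1) == 59
        # 309 -> 216.3/46.35/46.35 -> (216, 47, 46): largest remainders .35 >= .3
        assert np.sum(labels[sp.train] == 0) == 216
        assert np.sum(labels[sp.val] == 0) == 47
        assert np.sum(labels[sp.test] == 0) == 46

    def test_deterministic_and_seed_sensitive(self):
        labels = np.random.default_rng(0).integers(0, 2, 60)
        a = stratified_split(labels, seed=5)
        b = stratified_split(labels, seed=5)
        c = stratified_split(labels, seed=6)
        assert np.array_equal(a.train, b.train)
        assert not np.array_equal(a.train, c.train)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 0, 1, 1]), seed=0)

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(0, 1), min_size=20, max_size=200))
    def test_class_proportions_within_one_item(self, raw):
        labels = np.array(raw)
        if min(np.sum(labels == 0), np.sum(labels == 1)) < 3:
            return
        sp = stratified_split(labels, seed=0)
        for cls in (0, 1):
            n = np.sum(labels == cls)
            for idx, frac in ((sp.train, 0.70), (sp.val, 0.15), (sp.test, 0.15)):
                assert abs(np.sum(labels[idx] == cls) - frac * n) <= 1


class TestConfusion:
    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0])
        ct = confusion(y, y)
        assert ct.fp == ct.fn == 0 and ct.tp == 2 and ct.tn == 2

    def test_all_positive_predictions(self):
        y = np.array([1, 0, 0, 1, 0])
        ct = confusion(y, np.ones(5, int))
        assert ct.tn == 0 and ct.fp == 3 and ct.tp == 2

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        ct = confusion(y, p)
        tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
        fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
        fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
        tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (tp, fn, fp, tn)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([0, 2]), np.array([0, 1]))


class TestBasicMetrics:
    def test_perfect_table(self):
        acc, prec, rec = basic_metrics(ConfusionTable(tp=50, fn=0, fp=0, tn=50))
        assert acc == prec == rec == 1.0

    def test_hand_arithmetic_example(self):
        acc, prec, rec = basic_metrics(ConfusionTable(tp=9, fn=1, fp=2, tn=8))
        assert acc == pytest.approx(0.85)
        assert prec == pytest.approx(9 / 11)
        assert rec == pytest.approx(0.9)

    def test_degenerate_precision_is_nan_not_zero(self):
        with pytest.warns(UserWarning):
            _, prec, _ = basic_metrics(ConfusionTable(tp=0, fn=5, fp=0, tn=5))
        assert np.isnan(prec)

    @settings(deadline=None, max_examples=100)
    @given(tp=st.integers(0, 50), fn=st.integers(0, 50),
           fp=st.integers(0, 50), tn=st.integers(0, 50))
    def test_fuzzed_tables_match_formulas(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            acc, prec, rec = basic_metrics(ConfusionTable(tp, fn, fp, tn))
        assert acc == pytest.approx((tp + tn) / (tp + fn + fp + tn))
        if tp + fp:
            assert prec == pytest.approx(tp / (tp + fp))
        if tp + fn:
            assert rec == pytest.approx(tp / (tp + fn))


def _pairwise_auc(scores, labels):
    """All-pairs oracle: P(s+ > s-) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRankAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert rank_auc(scores, labels) == 1.0

    def test_identical_scores_give_half(self):
        scores = np.full(10, 0.5)
        labels = np.array([0, 1] * 5)
        assert rank_auc(scores, labels) == pytest.approx(0.5)

    def test_matches_all_pairs_oracle_on_fuzzed_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.uniform(size=n), 2)  # rounding makes ties likely
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert rank_auc(scores, labels) == pytest.approx(
                _pairwise_auc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(size=25)
        labels = rng.integers(0, 2, 25)
        a = rank_auc(scores, labels)
        b = rank_auc(np.exp(3 * scores) + 7, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_auc(np.array([0.1, 0.2]), np.array([1, 1]))


def test_metric_report_roundtrip():
    y = np.array([1, 1, 0, 0, 1, 0])
    p = np.array([0.9, 0.7, 0.3, 0.2, 0.4, 0.6])
    rep = metric_report(y, p)
    assert rep.accuracy == pytest.approx(4 / 6)
    assert rep.auc == pytest.approx(_pairwise_auc(p, y))
    assert rep.loss == pytest.approx(binary_cross_entropy(y, p))
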