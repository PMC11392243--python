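"""Confusion-matrix metrics, ROC/AUC vs pairwise oracle, label fusion,
and fold aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echoflow.evaluation import (ConfusionMatrix, MetricReport, ViewLabelPair,
                                 aggregate_folds, confusion, fuse_view_labels,
                                 metrics, roc_auc, round2)

COUNTS = st.integers(min_value=0, max_value=200)


class TestConfusion:
    def test_perfect_prediction(self):
        truth = ["RWMA"] * 60 + ["non-RWMA"] * 42
        cm = confusion(truth, truth)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (60, 42, 0, 0)

    def test_all_positive_prediction(self):
        truth = ["RWMA"] * 60 + ["non-RWMA"] * 42
        cm = confusion(truth, ["RWMA"] * 102)
        assert cm.fp == 42 and cm.fn == 0

    def test_matches_bruteforce_pair_counting(self, rng):
        truth = [("RWMA" if rng.random() < 0.5 else "non-RWMA") for _ in range(20)]
        pred = [("RWMA" if rng.random() < 0.5 else "non-RWMA") for _ in range(20)]
        tp = sum(1 for t, p in zip(truth, pred) if t == "RWMA" and p == "RWMA")
        tn = sum(1 for t, p in zip(truth, pred) if t != "RWMA" and p != "RWMA")
        fp = sum(1 for t, p in zip(truth, pred) if t != "RWMA" and p == "RWMA")
        fn = sum(1 for t, p in zip(truth, pred) if t == "RWMA" and p != "RWMA")
        cm = confusion(truth, pred)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)
        assert cm.total == 20

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["RWMA"], ["RWMA", "RWMA"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, tn=0, fp=0, fn=0)


class TestMetrics:
    """The printed multi-view classifier table is reproduced exactly from its
    underlying confusion counts over 60 positives / 42 negatives."""

    @pytest.mark.parametrize("cm,field,expect", [
        (ConfusionMatrix(tp=55, fn=5, tn=34, fp=8), "sensitivity", 91.67),   # KNN
        (ConfusionMatrix(tp=57, fn=3, tn=34, fp=8), "sensitivity", 95.00),   # SVM
        (ConfusionMatrix(tp=53, fn=7, tn=35, fp=7), "specificity", 83.33),   # RF
        (ConfusionMatrix(tp=53, fn=7, tn=35, fp=7), "accuracy", 86.27),      # RF
        (ConfusionMatrix(tp=53, fn=7, tn=35, fp=7), "f1", 88.33),            # RF
        (ConfusionMatrix(tp=51, fn=9, tn=32, fp=10), "accuracy", 81.37),     # DT
        (ConfusionMatrix(tp=50, fn=10, tn=34, fp=8), "specificity", 80.95),  # MLP
        (ConfusionMatrix(tp=50, fn=10, tn=34, fp=8), "precision", 86.21),    # MLP
    ])
    def test_reproduces_printed_classifier_metrics(self, cm, field, expect):
        assert round2(getattr(metrics(cm), field)) == expect

    @given(tp=COUNTS, tn=COUNTS, fp=COUNTS, fn=COUNTS)
    @settings(max_examples=200, deadline=None)
    def test_fpr_plus_specificity_is_100(self, tp, tn, fp, fn):
        if fp + tn == 0:
            return
        rep = metrics(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn))
        assert rep.fpr + rep.specificity == pytest.approx(100.0)

    @given(tp=st.integers(1, 200), tn=COUNTS, fp=COUNTS, fn=COUNTS)
    @settings(max_examples=200, deadline=None)
    def test_f1_is_harmonic_mean_of_precision_and_sensitivity(self, tp, tn, fp, fn):
        rep = metrics(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn))
        h = 2 * rep.precision * rep.sensitivity / (rep.precision + rep.sensitivity)
        assert rep.f1 == pytest.approx(h)

    @given(tp=COUNTS, tn=COUNTS, fp=COUNTS, fn=COUNTS)
    @settings(max_examples=100, deadline=None)
    def test_count_conservation(self, tp, tn, fp, fn):
        cm = ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
        assert cm.total == tp + tn + fp + fn

    def test_zero_denominator_reports_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="precision"):
            rep = metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=5))
        assert np.isnan(rep.precision)


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        auc, fpr, tpr = roc_auc([0.9, 0.8, 0.2, 0.1],
                                ["RWMA", "RWMA", "non-RWMA", "non-RWMA"])
        assert auc == pytest.approx(1.0)
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    def test_constant_scores_give_half(self):
        auc, _, _ = roc_auc([0.5] * 6, ["RWMA"] * 3 + ["non-RWMA"] * 3)
        assert auc == pytest.approx(0.5)

    def test_matches_pairwise_concordance_oracle(self, rng):
        scores = rng.normal(size=12)
        labels = ["RWMA"] * 5 + ["non-RWMA"] * 7
        pos = scores[:5]
        neg = scores[5:]
        conc = sum((1.0 if p > n else 0.5 if p == n else 0.0)
                   for p in pos for n in neg)
        assert roc_auc(scores, labels)[0] == pytest.approx(conc / 35)

    def test_monotone_curve_endpoints(self, rng):
        scores = rng.normal(size=20)
        labels = ["RWMA"] * 8 + ["non-RWMA"] * 12
        _, fpr, tpr = roc_auc(scores, labels)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], ["RWMA", "RWMA"])


class TestViewLabelFusion:
    @pytest.mark.parametrize("a4c,a2c,expect", [
        ("MI", "MI", "RWMA"),
        ("non-MI", "non-MI", "non-RWMA"),
        ("MI", "non-MI", "RWMA"),
        ("non-MI", "MI", "RWMA"),
    ])
    def test_or_rule(self, a4c, a2c, expect):
        assert ViewLabelPair(a4c_label=a4c, a2c_label=a2c).fused_label == expect

    def test_published_cohort_counts(self):
        """60 + 42 + 20 + 8 per-view label rows fuse to 88 RWMA / 42 normal."""
        pairs = ([ViewLabelPair("MI", "MI")] * 60 +
                 [ViewLabelPair("non-MI", "non-MI")] * 42 +
                 [ViewLabelPair("MI", "non-MI")] * 20 +
                 [ViewLabelPair("non-MI", "MI")] * 8)
        fused, counts = fuse_view_labels(pairs)
        assert counts["RWMA"] == 88
        assert counts["non-RWMA"] == 42
        assert len(fused) == 130

    def test_fusion_monotone_in_single_view_upgrade(self):
        """Flipping any one view from non-MI to MI never loses the RWMA label."""
        for a4c in ("MI", "non-MI"):
            for a2c in ("MI", "non-MI"):
                base = ViewLabelPair(a4c, a2c).fused_label
                up1 = ViewLabelPair("MI", a2c).fused_label
                up2 = ViewLabelPair(a4c, "MI").fused_label
                if base == "RWMA":
                    assert up1 == "RWMA" and up2 == "RWMA"


class TestAggregation:
    def _rep(self, acc):
        return MetricReport(sensitivity=acc, fpr=100 - acc, specificity=acc,
                            precision=acc, f1=acc, accuracy=acc)

    def test_identical_folds_collapse(self):
        agg = aggregate_folds([self._rep(90.0)] * 3)
        assert agg["accuracy"] == {"max": 90.0, "mean": 90.0, "min": 90.0}

    def test_known_values(self):
        agg = aggregate_folds([self._rep(80.0), self._rep(90.0), self._rep(100.0)])
        assert agg["accuracy"] == {"max": 100.0, "mean": 90.0, "min": 80.0}

    def test_order_property(self, rng):
        reps = [self._rep(float(a)) for a in rng.uniform(0, 100, 7)]
        for agg in aggregate_folds(reps).values():
            assert agg["max"] >= agg["mean"] >= agg["min"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([])


def test_round2_is_half_up():
    assert round2(86.265) == 86.27
    assert round2(91.666666) == 91.67
    assert round2(79.0) == 79.0
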