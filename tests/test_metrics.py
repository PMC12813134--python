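"""Metric battery: published-table oracles, identities, and pairwise AUC."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vqrefine.metrics import (
    ConfusionCounts,
    accuracy,
    confusion,
    mcc,
    roc_auc,
    weighted_metrics,
)
from vqrefine.vcf_io import FAIL, PASS

# Published per-sample confusion counts for the two refined callers and
# the metric values they must reproduce (support-weighted convention).
TABLE_ROWS = {
    "HG006-bcftools": dict(
        counts=ConfusionCounts(tp=3_551_084, fp=442_903, fn=143_576, tn=383_270),
        accuracy_pct=87.03, precision=0.85957, recall=0.87027, f1=0.85845,
        mcc=0.51194,
    ),
    "HG006-gatk4": dict(
        counts=ConfusionCounts(tp=3_548_098, fp=479_240, fn=118_249, tn=587_039),
        accuracy_pct=87.38, precision=0.87004, recall=0.87375, f1=0.86385,
        mcc=0.60805,
    ),
    "HG007-bcftools": dict(
        counts=ConfusionCounts(tp=3_562_660, fp=481_380, fn=122_394, tn=365_755),
        accuracy_pct=86.68, precision=0.85635, recall=0.86678, f1=0.85197,
        mcc=0.50117,
    ),
    "HG007-gatk4": dict(
        counts=ConfusionCounts(tp=3_548_979, fp=511_493, fn=101_163, tn=530_891),
        accuracy_pct=86.94, precision=0.86646, recall=0.86944, f1=0.85692,
        mcc=0.58638,
    ),
}


def _random_label_pairs(rng, n):
    labels = [PASS if x else FAIL for x in rng.integers(0, 2, n)]
    preds = [PASS if x else FAIL for x in rng.integers(0, 2, n)]
    return labels, preds


class TestConfusion:
    def test_enumerated_example(self):
        c = confusion([PASS, PASS, FAIL], [PASS, FAIL, FAIL])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 0)

    def test_all_correct(self):
        c = confusion([PASS, FAIL], [PASS, FAIL])
        assert c.fp == 0 and c.fn == 0

    def test_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        labels, preds = _random_label_pairs(rng, 200)
        c = confusion(labels, preds)
        tp = sum(1 for y, p in zip(labels, preds) if y == PASS and p == PASS)
        fp = sum(1 for y, p in zip(labels, preds) if y == FAIL and p == PASS)
        fn = sum(1 for y, p in zip(labels, preds) if y == PASS and p == FAIL)
        tn = sum(1 for y, p in zip(labels, preds) if y == FAIL and p == FAIL)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
        assert c.total == 200

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion([PASS], [PASS, FAIL])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestPublishedTableOracles:
    """The four sample x caller rows reproduce to printed precision."""

    @pytest.mark.parametrize("row", TABLE_ROWS.values(), ids=TABLE_ROWS.keys())
    def test_accuracy(self, row):
        assert round(100 * accuracy(row["counts"]), 2) == row["accuracy_pct"]

    @pytest.mark.parametrize("row", TABLE_ROWS.values(), ids=TABLE_ROWS.keys())
    def test_weighted_precision_recall_f1(self, row):
        rep = weighted_metrics(row["counts"])
        assert round(rep.precision_weighted, 5) == row["precision"]
        assert round(rep.recall_weighted, 5) == row["recall"]
        assert round(rep.f1_weighted, 5) == row["f1"]

    @pytest.mark.parametrize("row", TABLE_ROWS.values(), ids=TABLE_ROWS.keys())
    def test_mcc(self, row):
        assert round(mcc(row["counts"]), 5) == row["mcc"]

    def test_weighted_convention_is_not_pass_only(self):
        # PASS-only precision for the HG006 BCFTools row is ~0.889, far
        # from the printed 0.85957: the printed values are support-weighted
        rep = weighted_metrics(TABLE_ROWS["HG006-bcftools"]["counts"])
        assert abs(rep.precision_pass - 0.889) < 0.001
        assert rep.precision_weighted != pytest.approx(rep.precision_pass, abs=0.01)


counts_strategy = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 10**7),
    fp=st.integers(0, 10**7),
    fn=st.integers(0, 10**7),
    tn=st.integers(0, 10**7),
)


class TestMetricIdentities:
    def test_perfect_prediction(self):
        rep = weighted_metrics(ConfusionCounts(5, 0, 0, 5))
        for value in (rep.accuracy, rep.precision_weighted, rep.recall_weighted,
                      rep.f1_weighted):
            assert value == 1.0
        assert rep.mcc == pytest.approx(1.0, abs=1e-12)

    def test_all_one_class_mcc_zero(self):
        assert mcc(ConfusionCounts(10, 5, 0, 0)) == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(c=counts_strategy)
    def test_weighted_recall_equals_accuracy(self, c):
        if c.total == 0:
            return
        rep = weighted_metrics(c)
        assert rep.recall_weighted == pytest.approx(rep.accuracy, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(c=counts_strategy)
    def test_bounds_and_mcc_sign_flip(self, c):
        rep = weighted_metrics(c)
        for value in (rep.accuracy, rep.precision_weighted, rep.recall_weighted,
                      rep.f1_weighted):
            assert 0.0 <= value <= 1.0
        assert -1.0 <= rep.mcc <= 1.0
        inverted = ConfusionCounts(tp=c.fn, fp=c.tn, fn=c.tp, tn=c.fp)
        assert mcc(inverted) == pytest.approx(-mcc(c), abs=1e-12)

    def test_mcc_extremes(self):
        assert mcc(ConfusionCounts(7, 0, 0, 3)) == 1.0
        assert mcc(ConfusionCounts(0, 3, 7, 0)) == -1.0

    def test_sklearn_cross_check(self):
        """Independent oracle: sklearn on expanded label arrays."""
        from sklearn.metrics import (
            accuracy_score,
            matthews_corrcoef,
            precision_recall_fscore_support,
        )

        rng = np.random.default_rng(7)
        labels, preds = _random_label_pairs(rng, 500)
        c = confusion(labels, preds)
        rep = weighted_metrics(c)
        y = np.array([1 if l == PASS else 0 for l in labels])
        p = np.array([1 if l == PASS else 0 for l in preds])
        prec, rec, f1, _ = precision_recall_fscore_support(
            y, p, average="weighted", zero_division=0
        )
        assert rep.accuracy == pytest.approx(accuracy_score(y, p))
        assert rep.precision_weighted == pytest.approx(prec)
        assert rep.recall_weighted == pytest.approx(rec)
        assert rep.f1_weighted == pytest.approx(f1)
        assert rep.mcc == pytest.approx(matthews_corrcoef(y, p))


def pairwise_auc_oracle(labels, scores):
    """Exhaustive Mann-Whitney enumeration over all PASS x FAIL pairs."""
    pos = [s for l, s in zip(labels, scores) if l == PASS]
    neg = [s for l, s in zip(labels, scores) if l == FAIL]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        labels = [PASS, PASS, FAIL, FAIL]
        assert roc_auc(labels, [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_four_pair_enumeration(self):
        labels = [PASS, FAIL, PASS, FAIL]
        scores = [0.9, 0.8, 0.7, 0.1]
        assert roc_auc(labels, scores) == pairwise_auc_oracle(labels, scores)

    def test_all_ties_give_half(self):
        labels = [PASS, FAIL, PASS, FAIL]
        assert roc_auc(labels, [0.5] * 4) == 0.5

    def test_single_class_warns_zero(self):
        with pytest.warns(UserWarning):
            assert roc_auc([PASS, PASS], [0.1, 0.9]) == 0.0

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([PASS, FAIL], [1.2, 0.1])

    @pytest.mark.parametrize("n,tie_grid", [(100, None), (500, None), (300, 10)])
    def test_matches_pairwise_oracle(self, n, tie_grid):
        rng = np.random.default_rng(n)
        labels = [PASS if x else FAIL for x in rng.integers(0, 2, n)]
        if tie_grid:  # heavy ties: scores quantized to a coarse grid
            scores = rng.integers(0, tie_grid, n) / (tie_grid - 1)
        else:
            scores = rng.random(n)
        scores = list(scores)
        assert roc_auc(labels, scores) == pytest.approx(
            pairwise_auc_oracle(labels, scores), abs=1e-12
        )

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        labels = [PASS if x else FAIL for x in rng.integers(0, 2, 200)]
        scores = list(rng.integers(0, 8, 200) / 7.0)
        y = [1 if l == PASS else 0 for l in labels]
        assert roc_auc(labels, scores) == pytest.approx(roc_auc_score(y, scores))


class TestBatchAdditivity:
    def test_global_from_summed_counts_not_mean_of_metrics(self):
        c1 = ConfusionCounts(90, 5, 3, 2)
        c2 = ConfusionCounts(5, 20, 10, 15)
        total = c1 + c2
        assert (total.tp, total.fp, total.fn, total.tn) == (95, 25, 13, 17)
        mean_of_accs = 0.5 * (accuracy(c1) + accuracy(c2))
        assert accuracy(total) != pytest.approx(mean_of_accs, abs=1e-3)
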