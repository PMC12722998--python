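"""Metrics, ROC/AUC, threshold sweep and McNemar against brute-force oracles."""

import math

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from conftest import make_record, random_records
from fastpool.metrics import (compute_metrics, confusion_matrix_normalized,
                              mcnemar_test, roc_auc, threshold_sweep)


def records_from_counts(tp, fp, fn, tn, threshold=0.5):
    recs = []
    i = 0
    for _ in range(tp):
        recs.append(make_record(f"v{i}", 0.9, "positive", threshold)); i += 1
    for _ in range(fn):
        recs.append(make_record(f"v{i}", 0.1, "positive", threshold)); i += 1
    for _ in range(fp):
        recs.append(make_record(f"v{i}", 0.9, "negative", threshold)); i += 1
    for _ in range(tn):
        recs.append(make_record(f"v{i}", 0.1, "negative", threshold)); i += 1
    return recs


class TestComputeMetrics:
    def test_all_correct(self):
        rep = compute_metrics(records_from_counts(3, 0, 0, 3), 0.5)
        assert rep.accuracy == 1.0 and rep.f1 == 1.0

    def test_hand_worked_example(self):
        rep = compute_metrics(records_from_counts(3, 1, 1, 5), 0.5)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 1, 5)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.precision == pytest.approx(0.75)
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.f1 == pytest.approx(0.75)

    def test_undefined_precision_flagged_not_zero(self):
        rep = compute_metrics(records_from_counts(0, 0, 2, 3), 0.5)
        assert math.isnan(rep.precision)
        assert "precision" in rep.undefined

    def test_brute_force_recount_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            recs = random_records(rng, int(rng.integers(2, 40)),
                                  informative=False)
            thr = float(rng.uniform())
            rep = compute_metrics(recs, thr)
            tp = sum(r.video_score >= thr and r.true_label == "positive"
                     for r in recs)
            fp = sum(r.video_score >= thr and r.true_label == "negative"
                     for r in recs)
            fn = sum(r.video_score < thr and r.true_label == "positive"
                     for r in recs)
            tn = sum(r.video_score < thr and r.true_label == "negative"
                     for r in recs)
            assert (rep.tp, rep.fp, rep.fn, rep.tn) == (tp, fp, fn, tn)
            assert rep.accuracy == pytest.approx((tp + tn) / len(recs))


class TestConfusionMatrix:
    def test_row_normalization(self):
        cm = confusion_matrix_normalized(records_from_counts(3, 1, 1, 5), 0.5)
        np.testing.assert_allclose(cm[0], [0.75, 0.25])
        np.testing.assert_allclose(cm[1], [1 / 6, 5 / 6], atol=1e-4)

    def test_absent_class_row_is_nan(self):
        cm = confusion_matrix_normalized(records_from_counts(0, 1, 0, 5), 0.5)
        assert np.isnan(cm[0]).all()

    def test_perfect_predictions_give_identity(self):
        cm = confusion_matrix_normalized(records_from_counts(4, 0, 0, 4), 0.5)
        np.testing.assert_allclose(cm, np.eye(2))


def pairwise_auc(records):
    """Exhaustive Mann-Whitney: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [r.video_score for r in records if r.true_label == "positive"]
    neg = [r.video_score for r in records if r.true_label == "negative"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        recs = records_from_counts(3, 0, 0, 3)
        assert roc_auc(recs).auc == pytest.approx(1.0)

    def test_constant_scores_chance_line(self):
        recs = [make_record(f"v{i}", 0.5, lab) for i, lab in
                enumerate(["positive", "negative", "positive", "negative"])]
        curve = roc_auc(recs)
        assert curve.auc == pytest.approx(0.5)
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)

    def test_hand_worked_pairwise_example(self):
        # pos scores {0.9, 0.6}, neg {0.7, 0.2}: 3 of 4 pairs concordant
        recs = [make_record("a", 0.9, "positive"),
                make_record("b", 0.6, "positive"),
                make_record("c", 0.7, "negative"),
                make_record("d", 0.2, "negative")]
        assert roc_auc(recs).auc == pytest.approx(0.75)

    def test_trapezoid_equals_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            recs = random_records(rng, int(rng.integers(4, 50)))
            if len({r.true_label for r in recs}) < 2:
                continue
            assert roc_auc(recs).auc == pytest.approx(pairwise_auc(recs),
                                                      abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        recs = random_records(rng, 30)
        before = roc_auc(recs).auc
        for r in recs:
            r.video_score = float(np.tanh(3 * r.video_score) ** 3)
        assert roc_auc(recs).auc == pytest.approx(before, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(records_from_counts(2, 0, 1, 0))


class TestThresholdSweep:
    def test_extreme_grid_points(self):
        recs = records_from_counts(2, 1, 1, 2)
        reports, _ = threshold_sweep(recs, [0.0, 1.0])
        assert reports[0].sensitivity == 1.0   # threshold 0: everything positive
        assert reports[1].sensitivity <= 0.5   # threshold 1: only scores >= 1

    def test_selected_threshold_attains_grid_max_f1(self):
        rng = np.random.default_rng(3)
        grid = np.round(np.linspace(0, 1, 21), 10)
        for _ in range(100):
            recs = random_records(rng, 20)
            reports, chosen = threshold_sweep(recs, grid)
            best = np.nanmax([r.f1 for r in reports])
            chosen_rep = compute_metrics(recs, chosen)
            assert chosen_rep.f1 == pytest.approx(best)

    def test_ties_break_toward_lower_threshold(self):
        recs = records_from_counts(2, 0, 0, 2)
        # any threshold in (0.1, 0.9] is perfect; grid has several
        _, chosen = threshold_sweep(recs, [0.2, 0.5, 0.8])
        assert chosen == 0.2

    def test_override_bypasses_selection(self):
        recs = records_from_counts(2, 0, 0, 2)
        _, chosen = threshold_sweep(recs, [0.2, 0.5], override=0.75)
        assert chosen == 0.75

    def test_grid_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep(records_from_counts(1, 0, 0, 1), [0.5, 1.5])


def paired_records(correct_a, correct_b):
    """Construct record pairs with given per-video correctness patterns."""
    ra, rb = [], []
    for i, (ca, cb) in enumerate(zip(correct_a, correct_b)):
        truth = "positive"
        ra.append(make_record(f"v{i}", 0.9 if ca else 0.1, truth))
        rb.append(make_record(f"v{i}", 0.9 if cb else 0.1, truth))
    return ra, rb


class TestMcNemar:
    def test_balanced_discordance_gives_p_one(self):
        ra, rb = paired_records([1, 1, 0, 0, 1], [0, 0, 1, 1, 1])
        assert mcnemar_test(ra, rb).p_value == 1.0

    def test_one_sided_discordance_binomial_tail(self):
        ra, rb = paired_records([0] * 10, [1] * 10)
        res = mcnemar_test(ra, rb)
        assert res.p_value == pytest.approx(2 * 0.5 ** 10)

    def test_direct_summation_example(self):
        # b=2, c=8: p = 2 * sum_{k<=2} C(10,k) / 2^10 = 0.109375
        ra, rb = paired_records([1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
                                [0, 0, 1, 1, 1, 1, 1, 1, 1, 1])
        res = mcnemar_test(ra, rb)
        assert (res.b, res.c) == (2, 8)
        assert res.p_value == pytest.approx(0.109375)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            ca = rng.integers(0, 2, 12)
            cb = rng.integers(0, 2, 12)
            ra, rb = paired_records(ca, cb)
            assert (mcnemar_test(ra, rb).p_value
                    == pytest.approx(mcnemar_test(rb, ra).p_value))

    def test_no_discordance_degenerate(self):
        ra, rb = paired_records([1, 0, 1], [1, 0, 1])
        res = mcnemar_test(ra, rb)
        assert res.degenerate and res.p_value == 1.0

    def test_matches_statsmodels_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            ca = rng.integers(0, 2, 15)
            cb = rng.integers(0, 2, 15)
            ra, rb = paired_records(ca, cb)
            res = mcnemar_test(ra, rb)
            if res.b + res.c == 0:
                continue
            table = [[0, res.b], [res.c, 0]]
            expected = sm_mcnemar(table, exact=True).pvalue
            assert res.p_value == pytest.approx(float(expected))

    def test_chi2_option_cross_check(self):
        ra, rb = paired_records([1] * 9 + [0] * 6, [0] * 9 + [1] * 6)
        res = mcnemar_test(ra, rb, method="chi2-corrected")
        table = [[0, res.b], [res.c, 0]]
        expected = sm_mcnemar(table, exact=False, correction=True)
        assert res.p_value == pytest.approx(float(expected.pvalue))

    def test_mismatched_videos_rejected(self):
        ra, rb = paired_records([1, 0], [1, 1])
        rb[0].video_id = "other"
        with pytest.raises(ValueError):
            mcnemar_test(ra, rb)
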