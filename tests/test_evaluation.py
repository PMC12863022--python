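"""Evaluation stack: metrics arithmetic, matching, ROC, pathways, agreement."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from endosin import (
    ClassLabel,
    EndoscopyFrame,
    InputError,
    Laterality,
    TriggerTally,
    agreement,
    classification_metrics,
    f1_from_pr,
    pathway_stats,
    roc_analysis,
    round_pct,
    segmentation_metrics,
)
from conftest import rect_detection


class TestClassificationMetrics:
    def test_hand_counted_example(self):
        calls = ["positive"] * 4 + ["negative"] * 6
        gts = ["positive"] * 3 + ["negative"] + ["negative"] * 5 + ["positive"]
        m = classification_metrics(calls, gts)
        assert m["counts"].tp == 3 and m["counts"].fp == 1
        assert m["counts"].tn == 5 and m["counts"].fn == 1
        assert m["sensitivity"] == pytest.approx(75.0)
        assert m["specificity"] == pytest.approx(83.3, abs=0.05)
        assert m["precision"] == pytest.approx(75.0)
        assert m["accuracy"] == pytest.approx(80.0)

    def test_all_correct_gives_100(self):
        m = classification_metrics(["positive", "negative"], ["positive", "negative"])
        for key in ("sensitivity", "specificity", "precision", "accuracy", "f1"):
            assert m[key] == pytest.approx(100.0)

    def test_undefined_ratios_are_none_not_zero(self):
        m = classification_metrics(["negative", "negative"], ["negative", "negative"])
        assert m["precision"] is None and m["sensitivity"] is None
        assert m["specificity"] == pytest.approx(100.0)

    def test_missing_gt_errors(self):
        with pytest.raises(InputError):
            classification_metrics(["positive"], [None])

    def test_matches_brute_force_on_random_draws(self, rng):
        """Agrees exactly with pairwise counting on 1000 random label vectors."""
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            calls = ["positive" if v else "negative" for v in rng.random(n) < 0.5]
            gts = ["positive" if v else "negative" for v in rng.random(n) < 0.5]
            m = classification_metrics(calls, gts)
            tp = sum(c == "positive" and g == "positive" for c, g in zip(calls, gts))
            fp = sum(c == "positive" and g == "negative" for c, g in zip(calls, gts))
            tn = sum(c == "negative" and g == "negative" for c, g in zip(calls, gts))
            fn = sum(c == "negative" and g == "positive" for c, g in zip(calls, gts))
            assert (m["counts"].tp, m["counts"].fp, m["counts"].tn, m["counts"].fn) == (
                tp, fp, tn, fn,
            )
            if m["precision"] is not None and m["sensitivity"] is not None:
                p, r = m["precision"], m["sensitivity"]
                expected_f1 = f1_from_pr(p, r)
                if expected_f1 is not None:
                    assert m["f1"] == pytest.approx(expected_f1)

    def test_f1_is_harmonic_mean_of_reported_pr(self):
        assert f1_from_pr(90.0, 75.0) == pytest.approx(81.8, abs=0.05)
        assert f1_from_pr(0.0, 0.0) is None


class TestSegmentationMetrics:
    def frame(self, dets, fid="f"):
        return EndoscopyFrame(fid, 1024, 768, Laterality.RIGHT, detections=tuple(dets))

    def test_single_match(self):
        gt = self.frame([rect_detection("MT", 0, 0, 100, 100)])
        pred = self.frame([rect_detection("MT", 0, 0, 100, 80)])  # IoU 0.8
        (mt, _, _) = segmentation_metrics([pred], [gt])
        assert (mt.tp, mt.fp, mt.fn) == (1, 0, 0)
        assert mt.precision == mt.recall == mt.f1 == pytest.approx(100.0)
        assert mt.mean_iou == pytest.approx(0.8)

    def test_two_predictions_one_gt_greedy(self):
        gt = self.frame([rect_detection("MT", 0, 0, 100, 100)])
        pred = self.frame(
            [
                rect_detection("MT", 0, 0, 100, 70, confidence=0.6),  # IoU 0.7
                rect_detection("MT", 0, 0, 100, 60, confidence=0.9),  # IoU 0.6
            ]
        )
        (mt, _, _) = segmentation_metrics([pred], [gt])
        assert (mt.tp, mt.fp, mt.fn) == (1, 1, 0)
        # the higher-confidence prediction claims the instance
        assert mt.mean_iou == pytest.approx(0.6)

    def test_below_match_iou_is_fp_and_fn(self):
        gt = self.frame([rect_detection("IT", 0, 0, 100, 100)])
        pred = self.frame([rect_detection("IT", 0, 0, 100, 30)])  # IoU 0.3
        (_, it, _) = segmentation_metrics([pred], [gt])
        assert (it.tp, it.fp, it.fn) == (0, 1, 1)
        assert it.precision == 0.0 and it.recall == 0.0

    def test_unpaired_frame_errors(self):
        with pytest.raises(InputError):
            segmentation_metrics([self.frame([], fid="a")], [self.frame([], fid="b")])


class TestRoc:
    def test_perfect_separation(self):
        curve = roc_analysis([0.9, 0.8, 0.2, 0.1], ["positive"] * 2 + ["negative"] * 2,
                             n_boot=0)
        assert curve.auc == pytest.approx(1.0)

    def test_enumerated_pairs(self):
        curve = roc_analysis(
            [0.9, 0.4, 0.5, 0.1],
            ["positive", "positive", "negative", "negative"],
            n_boot=0,
        )
        assert curve.auc == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(InputError):
            roc_analysis([0.5, 0.6], ["positive", "positive"], n_boot=0)

    def test_random_scores_near_half(self, rng):
        n = 10_000
        scores = rng.random(n)
        gts = ["positive" if v else "negative" for v in rng.random(n) < 0.5]
        curve = roc_analysis(scores, gts, n_boot=0)
        assert curve.auc == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_concordance_estimator(self, rng):
        """Trapezoid AUC matches the tie-aware pair-counting estimator to 1e-9."""
        for _ in range(20):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            gts = ["positive" if v else "negative" for v in y]
            curve = roc_analysis(scores, gts, n_boot=0)
            pos, neg = scores[y], scores[~y]
            pairs = [
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p, q in itertools.product(pos, neg)
            ]
            assert curve.auc == pytest.approx(np.mean(pairs), abs=1e-9)

    def test_curve_monotone_and_ci_ordered(self, rng):
        scores = rng.random(60)
        gts = ["positive" if v else "negative" for v in rng.random(60) < 0.6]
        curve = roc_analysis(scores, gts, n_boot=200, seed=1)
        assert list(curve.tpr) == sorted(curve.tpr)
        assert list(curve.fpr) == sorted(curve.fpr)
        assert curve.ci_low <= curve.auc <= curve.ci_high


TABLE3 = {
    ("left", "positive"): (30, 32),
    ("left", "negative"): (1, 2),
    ("right", "positive"): (6, 31),
    ("right", "negative"): (1, 7),
}


class TestPathwayStats:
    def test_published_style_counts(self):
        stats = pathway_stats(TriggerTally.from_counts(TABLE3))
        assert round_pct(stats["MM_mucus"]["precision"]) == 94.7
        assert round_pct(stats["MT_mucus"]["precision"]) == 87.5
        assert round_pct(stats["MT_mucus"]["fp_share"]) == 81.8
        # 72/110 and 38/110; reported in the field to roughly one decimal
        assert stats["MT_mucus"]["usage_share"] == pytest.approx(65.45, abs=0.05)
        assert stats["MM_mucus"]["usage_share"] == pytest.approx(34.55, abs=0.05)

    def test_shares_sum_to_100(self):
        stats = pathway_stats(TriggerTally.from_counts(TABLE3))
        for key in ("usage_share", "fp_share"):
            total = sum(stats[p][key] for p in stats)
            assert total == pytest.approx(100.0, abs=0.1)

    def test_pathway_never_firing_in_negatives_is_fully_precise(self):
        tally = TriggerTally.from_counts({("left", "positive"): (5, 3),
                                          ("left", "negative"): (0, 2)})
        stats = pathway_stats(tally)
        assert stats["MM_mucus"]["precision"] == pytest.approx(100.0)

    def test_zero_grand_total_gives_none(self):
        stats = pathway_stats(TriggerTally.from_counts({("left", "positive"): (0, 0)}))
        assert stats["MM_mucus"]["precision"] is None
        assert stats["MM_mucus"]["usage_share"] is None


class TestAgreement:
    def test_identical_raters_give_kappa_one(self):
        ratings = np.tile(np.array([[0], [1], [1], [0], [1]]), (1, 3))
        out = agreement(ratings)
        assert out["fleiss_kappa"] == pytest.approx(1.0)
        assert out["pairwise_f1_mean"] == pytest.approx(1.0)

    def test_complete_disagreement_is_below_chance(self):
        out = agreement(np.array([[0, 1], [1, 0], [0, 1], [1, 0]]))
        assert out["fleiss_kappa"] <= 0

    def test_kappa_matches_hand_formula(self):
        """Three raters, six items: kappa equals the brute-force P-bar computation."""
        ratings = np.array(
            [[0, 0, 1], [1, 1, 1], [0, 1, 1], [0, 0, 0], [1, 1, 0], [1, 1, 1]]
        )
        n_items, n_raters = ratings.shape
        cats = [0, 1]
        counts = np.array(
            [[np.sum(row == c) for c in cats] for row in ratings], dtype=float
        )
        p_i = ((counts**2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
        p_bar = p_i.mean()
        p_j = counts.sum(axis=0) / (n_items * n_raters)
        p_e = (p_j**2).sum()
        expected = (p_bar - p_e) / (1 - p_e)
        assert agreement(ratings)["fleiss_kappa"] == pytest.approx(expected)

    def test_missing_ratings_rejected(self):
        with pytest.raises(InputError):
            agreement(np.array([[0.0, np.nan], [1.0, 0.0]]))

    def test_single_rater_rejected(self):
        with pytest.raises(InputError):
            agreement(np.array([[1], [0]]))


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected", [(79.25, 79.3), (81.818, 81.8), (94.736, 94.7), (None, None)]
    )
    def test_half_up_to_one_decimal(self, value, expected):
        assert round_pct(value) == expected
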