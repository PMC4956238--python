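"""Diagnostic-validity engine: confusion matrices, ROC coordinates, AUC,
Youden cut-off, likelihood ratios, Bayes prevalence adjustment and the
classification bands — each against an independent oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from bpscreen.errors import DegenerateDataError
from bpscreen.validity import (
    ConfusionMatrix,
    adjust_pv,
    auc_exact_p,
    auc_stats,
    candidate_cutoffs,
    classify_nlr,
    classify_plr,
    classify_quality,
    classify_quality_sum,
    confusion_at_cutoff,
    metrics,
    roc_coordinates,
    round2,
    youden_optimal,
)
from conftest import brute_confusion, pairwise_auc


def _sample(rng, n=40, ties=True):
    scores = rng.integers(0, 15, n).astype(float) if ties else rng.normal(size=n)
    diseased = rng.random(n) < 0.5
    if diseased.all():
        diseased[0] = False
    if not diseased.any():
        diseased[0] = True
    return scores, diseased


class TestConfusion:
    def test_perfect_split(self):
        cm = confusion_at_cutoff([1, 2, 3, 4], [False, False, True, True], 3)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 0, 2, 0)

    def test_cutoff_below_min_makes_all_positive(self):
        cm = confusion_at_cutoff([1, 2, 3], [True, False, False], 0)
        assert cm.fp == 2 and cm.tp == 1 and cm.tn == 0 and cm.fn == 0

    def test_strict_positivity_flag(self):
        cm = confusion_at_cutoff([3, 3], [True, False], 3, positive_ge=False)
        assert cm.tp == 0 and cm.fn == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_element_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores, diseased = _sample(rng)
        for cutoff in [0, 5.5, 7, 14.1]:
            cm = confusion_at_cutoff(scores, diseased, cutoff)
            assert (cm.tp, cm.fp, cm.tn, cm.fn) == brute_confusion(scores, diseased, cutoff)
            assert cm.n == len(scores)

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            confusion_at_cutoff([], [], 1.0)


class TestMetrics:
    def test_perfect_matrix(self):
        m = metrics(ConfusionMatrix(tp=1, fn=0, tn=1, fp=0))
        assert m.sensitivity == 1 and m.specificity == 1 and m.accuracy == 1
        assert math.isinf(m.plr) and m.nlr == 0

    def test_published_pain_matrix(self):
        m = metrics(ConfusionMatrix(tp=44, fn=17, tn=46, fp=15))
        assert round2(m.sensitivity) == 0.72
        assert round2(m.specificity) == 0.75
        assert round2(m.plr) == 2.93
        assert round2(m.nlr) == 0.37
        assert round2(m.ppv) == 0.75
        assert round2(m.npv) == 0.73
        assert round2(m.accuracy) == 0.74
        assert m.prevalence == 0.5

    def test_published_sickleave_matrix(self):
        m = metrics(ConfusionMatrix(tp=25, fn=15, tn=58, fp=10))
        assert round2(m.sensitivity) == 0.63
        assert round2(m.specificity) == 0.85
        assert round2(m.plr) == 4.25

    def test_all_negative_predictions_flag_ppv_undefined(self):
        m = metrics(ConfusionMatrix(tp=0, fn=3, tn=4, fp=0))
        assert math.isnan(m.ppv) and not math.isnan(m.npv)

    def test_sensitivity_prevalence_identity(self):
        cm = ConfusionMatrix(tp=7, fn=3, tn=11, fp=4)
        m = metrics(cm)
        assert m.sensitivity * m.prevalence * cm.n == pytest.approx(cm.tp, abs=1e-9)

    def test_single_state_rejected(self):
        with pytest.raises(DegenerateDataError):
            metrics(ConfusionMatrix(tp=3, fn=1, tn=0, fp=0))


class TestAuc:
    def test_perfect_separation(self):
        auc, se, p, ci = auc_stats([1, 2, 8, 9], [False, False, True, True])
        assert auc == 1.0 and ci[1] == 1.0

    def test_all_tied_scores(self):
        auc, se, p, ci = auc_stats([5, 5, 5, 5], [False, True, False, True])
        assert auc == 0.5 and p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores, diseased = _sample(rng, n=50)
        auc, *_ = auc_stats(scores, diseased)
        assert auc == pytest.approx(pairwise_auc(scores, diseased), abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(11)
        scores, diseased = _sample(rng, n=80)
        auc, *_ = auc_stats(scores, diseased)
        assert auc == pytest.approx(roc_auc_score(diseased, scores), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores, diseased = _sample(rng, n=60)
        a1, *_ = auc_stats(scores, diseased)
        a2, *_ = auc_stats(np.exp(scores / 5.0), diseased)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_trapezoid_area_of_coordinates_equals_auc(self):
        rng = np.random.default_rng(4)
        scores, diseased = _sample(rng, n=45)
        curve = roc_coordinates(scores, diseased)
        fpr = np.array([1 - p.specificity for p in curve.points])
        tpr = np.array([p.sensitivity for p in curve.points])
        area = -np.trapezoid(tpr, fpr)  # cutoff ascending => fpr descending
        assert area == pytest.approx(curve.auc, abs=1e-12)

    def test_exact_p_close_to_asymptotic_at_moderate_n(self):
        rng = np.random.default_rng(5)
        scores, diseased = _sample(rng, n=26, ties=False)
        _, _, p_asym, _ = auc_stats(scores, diseased)
        p_exact = auc_exact_p(scores, diseased)
        assert abs(p_exact - p_asym) < 0.15

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            auc_stats([1, 2], [True, True])


class TestCoordinates:
    def test_candidate_count_is_distinct_plus_one(self):
        scores = [1.0, 2.0, 2.0, 5.0]
        assert len(candidate_cutoffs(scores)) == 4  # 3 distinct + 1

    def test_points_match_brute_force_recomputation(self):
        rng = np.random.default_rng(6)
        scores, diseased = _sample(rng, n=30)
        curve = roc_coordinates(scores, diseased)
        assert len(curve.points) == len(np.unique(scores)) + 1
        for p in curve.points:
            tp, fp, tn, fn = brute_confusion(scores, diseased, p.cutoff)
            m = metrics(ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn), p.cutoff)
            assert p.sensitivity == m.sensitivity and p.specificity == m.specificity
            assert p.youden_j == pytest.approx(p.sensitivity + p.specificity - 1, abs=1e-12)

    def test_cutoffs_increase_and_sensitivity_decreases(self):
        rng = np.random.default_rng(7)
        scores, diseased = _sample(rng, n=40)
        curve = roc_coordinates(scores, diseased)
        cuts = [p.cutoff for p in curve.points]
        sens = [p.sensitivity for p in curve.points]
        assert cuts == sorted(cuts)
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))

    def test_perfect_separation_has_ideal_point(self):
        curve = roc_coordinates([1, 2, 8, 9], [False, False, True, True])
        assert any(p.sensitivity == 1.0 and p.specificity == 1.0 for p in curve.points)


class TestYouden:
    def test_formula_example(self):
        # the printed J derives from the printed 2-dp sens/spec: 0.72 + 0.75 - 1
        m = metrics(ConfusionMatrix(tp=44, fn=17, tn=46, fp=15))
        assert round2(round2(m.sensitivity) + round2(m.specificity) - 1) == 0.47
        assert m.youden_j == pytest.approx(m.sensitivity + m.specificity - 1, abs=1e-12)

    def test_perfect_separation_reaches_j_one(self):
        curve = roc_coordinates([1, 2, 8, 9], [False, False, True, True])
        assert youden_optimal(curve).youden_j == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores, diseased = _sample(rng, n=50)
        curve = roc_coordinates(scores, diseased)
        best = youden_optimal(curve)
        assert best.youden_j == max(p.youden_j for p in curve.points)
        ties = [p.cutoff for p in curve.points if p.youden_j == best.youden_j]
        assert best.cutoff == min(ties)


class TestAdjustPv:
    def test_very_high_efficiency_grid(self):
        adj = adjust_pv(19.0, 0.05 / 0.95, 0.10)
        assert round2(100 * adj.ppv, 1) == 67.9
        assert round2(100 * adj.npv, 1) == 99.4

    def test_moderate_efficiency_grid(self):
        plr, nlr = 0.7 / 0.3, 0.3 / 0.7
        adj = adjust_pv(plr, nlr, 0.90)
        assert round2(100 * adj.ppv, 1) == 95.5
        assert abs(100 * adj.npv - 21.0) < 0.5

    def test_symmetric_at_half_prevalence(self):
        adj = adjust_pv(19.0, 0.05 / 0.95, 0.50)
        assert round2(100 * adj.ppv, 1) == 95.0 and round2(100 * adj.npv, 1) == 95.0

    def test_pain_row_at_population_prevalence(self):
        m = metrics(ConfusionMatrix(tp=44, fn=17, tn=46, fp=15))
        adj = adjust_pv(m.plr, m.nlr, 0.10)
        assert round2(adj.ppv) == 0.25 and round2(adj.npv) == 0.96

    @pytest.mark.parametrize("seed", range(3))
    def test_bayes_consistency_at_sample_prevalence(self, seed):
        rng = np.random.default_rng(seed)
        cm = ConfusionMatrix(*(int(v) for v in rng.integers(1, 60, 4)))
        m = metrics(cm)
        adj = adjust_pv(m.plr, m.nlr, m.prevalence)
        assert adj.ppv == pytest.approx(m.ppv, abs=1e-12)
        assert adj.npv == pytest.approx(m.npv, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        st.floats(0.01, 50, allow_nan=False),
        st.floats(0.0, 1.0, allow_nan=False),
        st.floats(0.01, 0.98),
        st.floats(0.001, 0.019),
    )
    def test_ppv_monotone_in_prevalence_and_plr(self, plr, nlr, prev, dprev):
        a = adjust_pv(plr, nlr, prev)
        b = adjust_pv(plr, nlr, prev + dprev)
        assert b.ppv >= a.ppv - 1e-12
        assert b.npv <= a.npv + 1e-12
        c = adjust_pv(plr * 1.5, nlr, prev)
        assert c.ppv >= a.ppv - 1e-12

    def test_infinite_plr_gives_certain_ppv(self):
        assert adjust_pv(math.inf, 0.1, 0.2).ppv == 1.0

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            adjust_pv(2.0, 0.5, 1.0)


class TestClassifications:
    @pytest.mark.parametrize(
        "plr,band",
        [(0.5, "uninformative"), (1.0, "low"), (1.99, "low"), (2.0, "moderate"),
         (4.25, "moderate"), (5.0, "high"), (10.0, "very_high"), (19.0, "very_high")],
    )
    def test_plr_bands(self, plr, band):
        assert classify_plr(plr) == band

    @pytest.mark.parametrize(
        "nlr,band",
        [(1.5, "uninformative"), (1.0, "low"), (0.5, "low"), (0.49, "moderate"),
         (0.2, "moderate"), (0.19, "high"), (0.1, "high"), (0.06, "very_high")],
    )
    def test_nlr_bands(self, nlr, band):
        assert classify_nlr(nlr) == band

    @pytest.mark.parametrize(
        "pct,band",
        [(69.9, "low"), (70.0, "moderate"), (78.5, "moderate"), (80.0, "good"),
         (89.9, "good"), (90.0, "very_good")],
    )
    def test_quality_bands(self, pct, band):
        assert classify_quality(pct) == band

    @pytest.mark.parametrize(
        "pct,band",
        [(139.9, "low"), (140.0, "moderate"), (147.0, "moderate"),
         (160.0, "good"), (180.0, "very_good")],
    )
    def test_quality_sum_bands(self, pct, band):
        assert classify_quality_sum(pct) == band
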