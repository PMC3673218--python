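"""Normalized metrics, cumulative ROC, threshold derivation, CV, odds ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmmdriver import (
    ConfusionCounts,
    compute_metrics,
    confusion_from_predictions,
    cumulative_roc,
    derive_threshold,
    kfold_weights_cv,
    odds_ratio,
)
from hmmdriver.errors import DimensionError, StratificationError, ValidationError
from hmmdriver.evaluation import stratified_folds


def brute_force_confusion(scores, labels, tau):
    tp = sum(1 for s, l in zip(scores, labels) if l and s <= tau)
    fp = sum(1 for s, l in zip(scores, labels) if not l and s <= tau)
    fn = sum(1 for s, l in zip(scores, labels) if l and s > tau)
    tn = sum(1 for s, l in zip(scores, labels) if not l and s > tau)
    return tp, fp, tn, fn


class TestConfusionFromPredictions:
    def test_four_point_example(self):
        # -2 and -1 both fall at or below -0.75 -> both positives are caught
        c = confusion_from_predictions([-2, -1, 0, 1], [True, True, False, False], -0.75)
        assert (c.tp, c.fn, c.tn, c.fp) == (2, 0, 2, 0)

    def test_all_positives_deeply_negative(self):
        c = confusion_from_predictions([-10] * 7, [True] * 7 , -0.75)
        assert (c.tp, c.fn) == (7, 0)

    def test_degenerate_threshold_above_max(self):
        scores = [-2.0, -1.0, 0.5, 1.5]
        labels = [True, False, True, False]
        c = confusion_from_predictions(scores, labels, 100.0)
        assert (c.fp, c.fn) == (2, 0)

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            confusion_from_predictions([1.0], [True, False], 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_per_item_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        scores = rng.normal(-1, 2, n)
        labels = rng.random(n) < 0.5
        tau = float(rng.normal(-0.75, 1))
        c = confusion_from_predictions(scores, labels, tau)
        assert (c.tp, c.fp, c.tn, c.fn) == brute_force_confusion(scores, labels, tau)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(50, 0, 50, 0))
        assert all(v == pytest.approx(1.0) for v in m.as_dict().values())

    def test_symmetric_chance(self):
        m = compute_metrics(ConfusionCounts(10, 10, 10, 10))
        assert m.sensitivity == pytest.approx(0.5)
        assert m.specificity == pytest.approx(0.5)
        assert m.mcc == pytest.approx(0.0, abs=1e-12)

    def test_normalized_equals_raw_on_balanced_classes(self):
        c = ConfusionCounts(tp=420, fp=37, tn=463, fn=80)  # 500 per class
        norm = compute_metrics(c, normalized=True)
        raw = compute_metrics(c, normalized=False)
        for k, v in norm.as_dict().items():
            assert v == pytest.approx(raw.as_dict()[k], abs=1e-12), k

    def test_normalized_accuracy_is_mean_of_rates(self):
        c = ConfusionCounts(tp=90, fp=30, tn=370, fn=10)
        m = compute_metrics(c, normalized=True)
        assert m.accuracy == pytest.approx((m.sensitivity + m.specificity) / 2, abs=1e-12)

    def test_undefined_ratios_become_none(self):
        # nothing predicted positive: normalized precision = s/(s+f) = 0/0
        m = compute_metrics(ConfusionCounts(0, 0, 10, 10))
        assert m.precision is None
        assert m.sensitivity == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(ConfusionCounts(5, 0, 0, 5))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_oracle_equivalence_on_random_tables(self, seed):
        """Normalized metrics recomputed from first principles per table."""
        rng = np.random.default_rng(seed)
        tp, fp, tn, fn = (int(x) for x in rng.integers(0, 500, 4))
        if tp + fn == 0 or tn + fp == 0:
            return
        m = compute_metrics(ConfusionCounts(tp, fp, tn, fn), normalized=True)
        s = tp / (tp + fn)
        e = tn / (tn + fp)
        f = fp / (tn + fp)
        mm = fn / (tp + fn)
        assert m.sensitivity == pytest.approx(s, abs=1e-12)
        assert m.specificity == pytest.approx(e, abs=1e-12)
        assert m.accuracy == pytest.approx((s + e) / 2, abs=1e-12)
        if s + f > 0:
            assert m.precision == pytest.approx(s / (s + f), abs=1e-12)
        if e + mm > 0:
            assert m.npv == pytest.approx(e / (e + mm), abs=1e-12)
        denom = (s + f) * (s + mm) * (e + f) * (e + mm)
        if denom > 0:
            assert m.mcc == pytest.approx((s * e - f * mm) / math.sqrt(denom), abs=1e-12)


def brute_force_roc(scores, labels):
    """Oracle: sweep every distinct threshold, most damaging first."""
    points = [(0, 0)]
    for tau in sorted(set(scores)):
        fp = sum(1 for s, l in zip(scores, labels) if not l and s <= tau)
        tp = sum(1 for s, l in zip(scores, labels) if l and s <= tau)
        points.append((fp, tp))
    return points


def mann_whitney_concordance(scores, labels):
    """P(driver scored more damaging than non-driver), ties count half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if p < n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestCumulativeROC:
    def test_perfect_separation_rises_before_any_fp(self):
        scores = [-5, -4, -3, 1, 2, 3]
        labels = [True, True, True, False, False, False]
        roc = cumulative_roc(scores, labels)
        fp, tp = roc.fp, roc.tp
        assert tp[3] == 3 and fp[3] == 0
        assert (fp[-1], tp[-1]) == (3, 3)
        assert roc.auc() == pytest.approx(1.0)

    def test_all_tied_scores_one_block(self):
        roc = cumulative_roc([0.5] * 6, [True, False] * 3)
        assert len(roc.fp) == 2  # origin plus the single tie block
        assert (roc.fp[-1], roc.tp[-1]) == (3, 3)

    def test_monotone_and_complete(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.4
        roc = cumulative_roc(scores, labels)
        assert (np.diff(roc.fp) >= 0).all() and (np.diff(roc.tp) >= 0).all()
        assert roc.fp[-1] == (~labels).sum() and roc.tp[-1] == labels.sum()

    def test_fp_cap_truncates(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=400)
        labels = rng.random(400) < 0.5
        capped = cumulative_roc(scores, labels, fp_fraction_cap=0.01)
        assert capped.fp[-2] <= 0.01 * (~labels).sum()

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            cumulative_roc([1.0, 2.0], [True, True])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_equals_brute_force_sweep(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            return
        roc = cumulative_roc(scores, labels)
        assert list(zip(roc.fp, roc.tp)) == brute_force_roc(scores, labels)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_auc_equals_mann_whitney_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 500))
        scores = np.round(rng.normal(size=n), 1)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            return
        roc = cumulative_roc(scores, labels)
        assert roc.auc() == pytest.approx(mann_whitney_concordance(scores, labels), abs=1e-12)

    def test_auc_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.5
        roc = cumulative_roc(scores, labels)
        expected = sklearn_metrics.roc_auc_score(labels, -scores)
        assert roc.auc() == pytest.approx(expected, abs=1e-12)


class TestDeriveThreshold:
    def test_falls_in_planted_gap(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-6, -2, 200)
        neg = rng.uniform(0, 4, 200)
        scores = np.concatenate([pos, neg])
        labels = np.array([True] * 200 + [False] * 200)
        tau = derive_threshold([(scores, labels)])
        assert max(pos) <= tau < min(neg)

    def test_two_dataset_objective_matches_brute_force(self):
        rng = np.random.default_rng(1)
        datasets = []
        for mu in (-1.0, -0.5):
            pos = rng.normal(mu - 0.8, 0.5, 120)
            neg = rng.normal(mu + 0.8, 0.5, 120)
            scores = np.concatenate([pos, neg])
            labels = np.array([True] * 120 + [False] * 120)
            datasets.append((scores, labels))
        tau = derive_threshold(datasets, grid_step=0.05)
        lo = min(s.min() for s, _ in datasets)
        hi = max(s.max() for s, _ in datasets)
        grid = np.arange(lo, hi + 0.05, 0.05)

        def objective(t):
            total = 0.0
            for scores, labels in datasets:
                total += (scores[labels] <= t).mean() + (scores[~labels] > t).mean()
            return total

        best = max(objective(t) for t in grid)
        assert objective(tau) == pytest.approx(best, abs=1e-9)

    def test_dataset_permutation_invariance(self):
        rng = np.random.default_rng(2)
        datasets = []
        for mu in (-2.0, -1.0, 0.0):
            scores = np.concatenate([rng.normal(mu - 1, 0.6, 80), rng.normal(mu + 1, 0.6, 80)])
            labels = np.array([True] * 80 + [False] * 80)
            datasets.append((scores, labels))
        tau1 = derive_threshold(datasets)
        tau2 = derive_threshold(datasets[::-1])
        assert tau1 == tau2

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            derive_threshold([])

    def test_single_class_dataset_rejected(self):
        with pytest.raises(ValidationError):
            derive_threshold([(np.array([1.0, 2.0]), np.array([True, True]))])


class TestCrossValidation:
    def test_loo_excludes_only_itself(self, default_bundle, background):
        b = default_bundle
        variants = b.variants[:30] + b.variants[-30:]  # 30 per class
        result = kfold_weights_cv(
            variants, k=len(variants), seed=1,
            assignments=b.assignments, registry=b.registry, bg=background,
        )
        assert len(result.predictions) == len(variants)
        assert result.predictions["fold"].nunique() == len(variants)

    def test_fold_membership_ignores_input_order(self, default_bundle, background):
        b = default_bundle
        variants = b.variants[:40] + b.variants[-40:]
        f1 = stratified_folds(variants, 4, seed=9)
        f2 = stratified_folds(variants[::-1], 4, seed=9)
        key = lambda fold: sorted(v.key for v in fold)
        assert [key(f) for f in f1] == [key(f) for f in f2]

    def test_two_fold_accuracy_close_to_no_cv(self, default_bundle, background, fitted):
        """Held-out re-estimation barely moves the pooled accuracy: the
        weight table is stable under halving the catalogue."""
        b = default_bundle
        result = kfold_weights_cv(
            b.variants, k=2, seed=7,
            assignments=b.assignments, registry=b.registry, bg=background,
        )
        no_cv = fitted.training_metrics()
        assert result.pooled_metrics.accuracy == pytest.approx(no_cv.accuracy, abs=0.05)

    def test_stratification_guards_single_class_folds(self, default_bundle):
        b = default_bundle
        cancer_only = [v for v in b.variants if v.label.value == "CANCER"][:10]
        with pytest.raises((StratificationError, ValidationError)):
            stratified_folds(cancer_only, 2, seed=0)


class TestOddsRatio:
    def test_symmetry_gives_one(self):
        assert odds_ratio(10, 10, 10, 10).odds_ratio == pytest.approx(1.0)

    def test_closed_form_with_ci(self):
        result = odds_ratio(20, 5, 10, 10)
        assert result.odds_ratio == pytest.approx(4.0)
        se = math.sqrt(1 / 20 + 1 / 5 + 1 / 10 + 1 / 10)
        assert result.ci_low == pytest.approx(math.exp(math.log(4) - 1.96 * se), abs=1e-9)
        assert result.ci_high == pytest.approx(math.exp(math.log(4) + 1.96 * se), abs=1e-9)
        assert result.ci_low == pytest.approx(1.074, abs=0.01)
        assert result.ci_high == pytest.approx(14.897, abs=0.01)
        assert not result.haldane_corrected

    def test_doubling_narrows_ci(self):
        base = odds_ratio(20, 5, 10, 10)
        double = odds_ratio(40, 10, 20, 20)
        assert double.odds_ratio == pytest.approx(base.odds_ratio)
        assert double.ci_high - double.ci_low < base.ci_high - base.ci_low

    def test_zero_cell_haldane_correction(self):
        result = odds_ratio(10, 0, 5, 5)
        assert result.haldane_corrected
        assert math.isfinite(result.odds_ratio)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            odds_ratio(-1, 2, 3, 4)
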