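"""ROC construction, cut-point selection, confusion metrics, group tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vldlc import (
    compare_groups,
    confusion_metrics,
    match_operating_point,
    optimal_cutpoint,
    roc_curve,
)
from vldlc.phenotyping import PhenotypeCall


def brute_force_auc(scores, labels):
    """Concordant-pair counting with ties worth one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def brute_force_best(scores, labels):
    """Exhaustive scan of every threshold for max sens+spec (tie: higher)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2
    grid = np.concatenate(([-np.inf], mids, [np.inf]))
    best_t, best_sum = None, -1.0
    for t in grid:
        sens = np.mean(s[y] >= t)
        spec = np.mean(s[~y] < t)
        if sens + spec >= best_sum:
            best_sum, best_t = sens + spec, t
    return best_t, best_sum


def random_instance(rng, n):
    labels = np.zeros(n, bool)
    labels[: max(1, n // 4)] = True
    rng.shuffle(labels)
    scores = np.where(
        labels, rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n)
    ).round(2)  # rounding forces ties
    return scores, labels


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_curve([0.4, 0.3, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.optimal_sens == 1.0 and roc.optimal_spec == 1.0
        assert 0.2 < roc.optimal_cutpoint <= 0.3

    def test_three_of_four_pairs_concordant(self):
        assert roc_curve([0.3, 0.1, 0.2, 0.05], [1, 1, 0, 0]).auc == 0.75

    def test_single_tied_pair_counts_half(self):
        assert roc_curve([0.2, 0.2], [1, 0]).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_curve_monotone_along_thresholds(self, rng):
        scores, labels = random_instance(rng, 300)
        roc = roc_curve(scores, labels)
        assert np.all(np.diff(roc.sens) <= 0)
        assert np.all(np.diff(roc.spec) >= 0)

    def test_auc_equals_brute_force_pair_counting(self, rng):
        for n in (10, 37, 120, 400):
            scores, labels = random_instance(rng, n)
            roc = roc_curve(scores, labels)
            assert roc.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores, labels = random_instance(rng, 500)
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_label_swap_maps_auc_to_complement(self, rng):
        scores, labels = random_instance(rng, 200)
        a = roc_curve(scores, labels).auc
        b = roc_curve(scores, ~labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestCutpoint:
    def test_equals_exhaustive_scan(self, rng):
        for n in (15, 60, 200):
            scores, labels = random_instance(rng, n)
            roc = roc_curve(scores, labels)
            t, total = brute_force_best(scores, labels)
            assert optimal_cutpoint(roc) == t
            assert roc.optimal_sens + roc.optimal_spec == pytest.approx(total)

    def test_youden_sum_at_least_one_when_auc_decent(self, rng):
        scores, labels = random_instance(rng, 300)
        roc = roc_curve(scores, labels)
        if roc.auc >= 0.5:
            assert roc.optimal_sens + roc.optimal_spec >= 1.0

    def test_degenerate_scores_return_sentinel_with_warning(self):
        with pytest.warns(UserWarning):
            roc = roc_curve([0.2, 0.2, 0.2], [1, 0, 0])
        assert roc.degenerate
        assert np.isinf(roc.optimal_cutpoint)


class TestMatchOperatingPoint:
    def test_perfect_curve_full_sensitivity(self):
        roc = roc_curve([0.4, 0.3, 0.2, 0.1], [1, 1, 0, 0])
        t = match_operating_point(roc, "sensitivity", 1.0)
        assert 0.2 < t <= 0.3

    def test_half_sensitivity_on_four_point_curve(self):
        roc = roc_curve([0.3, 0.1, 0.2, 0.05], [1, 1, 0, 0])
        t = match_operating_point(roc, "sensitivity", 0.5)
        assert 0.2 < t <= 0.3
        assert np.mean(np.array([0.3, 0.1]) >= t) >= 0.5

    def test_unachievable_target_reports_extreme(self):
        roc = roc_curve([0.3, 0.1, 0.2, 0.05], [1, 1, 0, 0])
        with pytest.raises(ValueError, match="maximum"):
            match_operating_point(roc, "specificity", 1.1)

    def test_specificity_target_picks_smallest_threshold(self, rng):
        scores, labels = random_instance(rng, 200)
        roc = roc_curve(scores, labels)
        t = match_operating_point(roc, "specificity", 0.9)
        i = int(np.flatnonzero(roc.thresholds == t)[0])
        assert roc.spec[i] >= 0.9
        if i > 0:
            assert roc.spec[i - 1] < 0.9


class TestConfusion:
    def test_perfect_and_inverted_tables(self):
        perfect = confusion_metrics(["positive", "negative"], [1, 0])
        assert (perfect.sensitivity, perfect.specificity) == (1.0, 1.0)
        assert perfect.concordance == 1.0 and perfect.mcc == 1.0 and perfect.nmcc == 1.0
        inverted = confusion_metrics(["negative", "positive"], [1, 0])
        assert inverted.mcc == -1.0 and inverted.nmcc == 0.0

    def test_hand_formula_on_mixed_table(self):
        calls = (["positive"] * 90 + ["negative"] * 10
                 + ["negative"] * 80 + ["positive"] * 20)
        truth = [1] * 100 + [0] * 100
        cm = confusion_metrics(calls, truth)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (90, 10, 80, 20)
        assert cm.sensitivity == pytest.approx(0.90)
        assert cm.specificity == pytest.approx(0.80)
        assert cm.concordance == pytest.approx(0.85)
        mcc = (90 * 80 - 20 * 10) / np.sqrt(110 * 100 * 100 * 90)
        assert cm.mcc == pytest.approx(mcc)
        assert cm.nmcc == pytest.approx((mcc + 1) / 2)
        assert cm.balanced == pytest.approx(0.85)

    def test_zero_margin_mcc_is_zero(self):
        cm = confusion_metrics(["positive", "positive"], [1, 0])
        assert cm.mcc == 0.0

    def test_not_evaluable_policies(self):
        calls = [
            PhenotypeCall("positive", "es_ratio"),
            PhenotypeCall("not_evaluable", "es_ratio", reason="apoB missing"),
            PhenotypeCall("negative", "es_ratio"),
        ]
        excl = confusion_metrics(calls, [1, 1, 0])
        assert excl.total == 2 and excl.n_not_evaluable == 1
        strict = confusion_metrics(calls, [1, 1, 0], not_evaluable="negative")
        assert strict.total == 3 and strict.fn == 1

    def test_concordance_invariant_to_order(self, rng):
        calls = list(rng.choice(["positive", "negative"], 60))
        truth = list(rng.integers(0, 2, 60))
        base = confusion_metrics(calls, truth).concordance
        perm = rng.permutation(60)
        shuffled = confusion_metrics([calls[i] for i in perm],
                                     [truth[i] for i in perm]).concordance
        assert base == shuffled

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(["positive"], [1, 0])


class TestGroupComparison:
    def test_identical_groups_give_p_one(self):
        g = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert g.p_value == pytest.approx(1.0)
        assert g.mean_a == g.mean_b == 2.0
        assert g.iqr_a == pytest.approx((1.5, 2.5))

    def test_separated_groups_give_tiny_p(self, rng):
        a = rng.normal(0, 1, 500)
        b = rng.normal(5, 1, 500)
        assert compare_groups(a, b).p_value < 1e-6

    def test_welch_matches_scipy(self, rng):
        from scipy import stats

        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 2, 60)
        assert compare_groups(a, b).p_value == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue
        )

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
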