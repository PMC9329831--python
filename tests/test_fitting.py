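"""Design matrices, OLS derivation, splits, accuracy diagnostics."""

import math

import numpy as np
import pytest

from vldlc import (
    ENHANCED_BASIS,
    LipidPanel,
    SplitSpec,
    TermBasis,
    build_design_matrix,
    estimate_accuracy,
    fit_ratio_call,
    fit_vldlc_equation,
    hlp3_subset_fit,
    random_split,
    sample_noiseless_panels,
)
from vldlc.errors import (
    MissingAnalyteError,
    RankDeficientError,
    TooFewRecordsError,
)
from vldlc.fitting import intercept, linear, product, square

#: The published denominator presentation of the apoB-augmented equation.
PUBLISHED_RECIPROCALS = {
    "non_hdl_c": 3.81,
    "hdl_c": -8.93,
    "tg": 7.73,
    "non_hdl_c*tg": 2050.0,
    "tg^2": -13300.0,
    "apob": -2.49,
    "apob*tg": -3550.0,
    "intercept": 7.46,
}


class TestDesignMatrix:
    def test_enhanced_row_matches_hand_evaluation(self):
        panel = LipidPanel(tc=341, hdl_c=40, tg=375, apob=118)  # non-HDL-C 301
        row = build_design_matrix([panel], ENHANCED_BASIS)[0]
        assert list(row) == [301, 40, 375, 112875, 140625, 118, 44250, 1]

    def test_intercept_only_basis_gives_ones(self):
        basis = TermBasis("const", (intercept(),))
        X = build_design_matrix([LipidPanel(100, 40, 80)] * 3, basis)
        assert np.array_equal(X, np.ones((3, 1)))

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrix([], ENHANCED_BASIS)

    def test_missing_apob_names_record_and_term(self):
        panels = [LipidPanel(341, 40, 375, 118), LipidPanel(200, 50, 100)]
        with pytest.raises(MissingAnalyteError, match="record 1.*apob"):
            build_design_matrix(panels, ENHANCED_BASIS)

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError):
            TermBasis("bad", (linear("tg"), linear("tg")))


class TestFit:
    def test_noise_free_refit_recovers_published_equation(self):
        pairs = sample_noiseless_panels(200, seed=3)
        fit = fit_vldlc_equation(pairs, ENHANCED_BASIS)
        for label, target in PUBLISHED_RECIPROCALS.items():
            assert fit.reciprocal_form[label] == pytest.approx(target, rel=1e-8)
        assert fit.diagnostics.rmse < 1e-8
        assert fit.diagnostics.r2 == pytest.approx(1.0)

    def test_noisy_refit_close_to_truth(self):
        pairs = sample_noiseless_panels(10_000, seed=1)
        rng = np.random.default_rng(501)
        noisy = [(p, y + rng.normal(0, 5)) for p, y in pairs]
        fit = fit_vldlc_equation(noisy, ENHANCED_BASIS)
        for label, target in PUBLISHED_RECIPROCALS.items():
            tol = 0.10 if label == "intercept" else 0.05
            assert fit.reciprocal_form[label] == pytest.approx(target, rel=tol)

    def test_exact_recovery_for_arbitrary_coefficients(self, rng):
        """Noise-free OLS must return whatever coefficients generated the data."""
        truth = np.array([0.3, -0.1, 0.12, 5e-4, -8e-5, -0.4, -3e-4, 5.0])
        panels = [p for p, _ in sample_noiseless_panels(100, seed=9)]
        X = build_design_matrix(panels, ENHANCED_BASIS)
        y = X @ truth
        fit = fit_vldlc_equation(list(zip(panels, y)), ENHANCED_BASIS)
        assert np.allclose(fit.coefficients, truth, rtol=1e-8)

    def test_too_few_records_rejected(self):
        pairs = sample_noiseless_panels(20, seed=0)[:8]
        with pytest.raises(TooFewRecordsError):
            fit_vldlc_equation(pairs, ENHANCED_BASIS)

    def test_collinear_terms_raise_rank_error(self):
        # product(tg, tg) duplicates square(tg) exactly
        basis = TermBasis("collinear", (linear("tg"), square("tg"),
                                        product("tg", "tg"), intercept()))
        pairs = [(p, 1.0) for p, _ in sample_noiseless_panels(50, seed=2)]
        with pytest.raises(RankDeficientError):
            fit_vldlc_equation(pairs, basis)

    def test_reciprocal_form_round_trips(self):
        fit = fit_vldlc_equation(sample_noiseless_panels(100, seed=4), ENHANCED_BASIS)
        for term, coef in zip(fit.basis.terms, fit.coefficients):
            if term.kind == "intercept":
                assert fit.reciprocal_form[term.label] == coef
            else:
                assert 1.0 / fit.reciprocal_form[term.label] == pytest.approx(
                    coef, rel=1e-12
                )

    def test_extra_noise_term_never_increases_training_rmse(self):
        pairs = sample_noiseless_panels(500, seed=6)
        rng = np.random.default_rng(7)
        noisy = [(p, y + rng.normal(0, 10)) for p, y in pairs]
        base = fit_vldlc_equation(noisy, ENHANCED_BASIS)
        wider = TermBasis("wider", ENHANCED_BASIS.terms + (square("apob"),))
        assert fit_vldlc_equation(noisy, wider).diagnostics.rmse <= (
            base.diagnostics.rmse + 1e-9
        )

    def test_stepwise_drops_an_irrelevant_term(self):
        rng = np.random.default_rng(8)
        panels = [p for p, _ in sample_noiseless_panels(2000, seed=5)]
        X = build_design_matrix(panels, ENHANCED_BASIS)
        # outcome ignores apob^2 entirely
        y = X @ np.array([0.26, -0.11, 0.13, 4.9e-4, -7.5e-5, -0.4, -2.8e-4, 7.5])
        y = y + rng.normal(0, 5, y.size)
        wider = TermBasis("wider", ENHANCED_BASIS.terms + (square("apob"),))
        fit = fit_vldlc_equation(list(zip(panels, y)), wider, stepwise=True)
        assert "apob^2" not in fit.basis.labels


class TestSplit:
    def test_even_partition_sizes(self):
        train, valid = random_split(list(range(24_546)), SplitSpec(0.5, seed=1))
        assert {len(train), len(valid)} == {12_273}
        assert sorted(train + valid) == list(range(24_546))
        assert not set(train) & set(valid)

    def test_reproducible_under_seed(self):
        data = list(range(1001))
        assert random_split(data, SplitSpec(0.5, 42)) == random_split(
            data, SplitSpec(0.5, 42)
        )
        assert random_split(data, SplitSpec(0.5, 42)) != random_split(
            data, SplitSpec(0.5, 43)
        )

    def test_full_fraction_warns_and_empties_validation(self):
        with pytest.warns(UserWarning):
            train, valid = random_split([1, 2, 3], SplitSpec(1.0, 0))
        assert valid == []
        assert sorted(train) == [1, 2, 3]


class TestHlp3SubsetFit:
    def test_fits_on_positives_only(self, small_cohort):
        fit = hlp3_subset_fit(small_cohort, "vldl_c")
        from vldlc import bq_hlp3_call

        n_pos = sum(
            bq_hlp3_call(r.vldl_c, r.panel.tg).is_positive for r in small_cohort
        )
        assert fit.n_train == n_pos
        assert fit.hlp3_specific
        assert fit.outcome == "vldl_c"

    def test_exact_recovery_on_known_outcome(self, small_cohort):
        from dataclasses import replace
        from vldlc import bq_hlp3_call

        truth = np.array([0.5, -0.2, 0.3, 1e-4, -5e-5, -0.6, -1e-4, 3.0])
        doctored = []
        for r in small_cohort:
            if bq_hlp3_call(r.vldl_c, r.panel.tg).is_positive:
                X = build_design_matrix([r.panel], ENHANCED_BASIS)
                doctored.append(replace(r, vldl_tg=float(X[0] @ truth)))
            else:
                doctored.append(r)
        fit = hlp3_subset_fit(doctored, "vldl_tg")
        assert np.allclose(fit.coefficients, truth, rtol=1e-8)

    def test_too_few_positives_errors_with_minimum(self, small_cohort):
        negatives = [r for r in small_cohort if r.vldl_c / r.panel.tg < 0.2][:30]
        with pytest.raises(TooFewRecordsError, match="at least 16"):
            hlp3_subset_fit(negatives, "vldl_c")

    def test_monitoring_fit_rejected_for_screening(self, small_cohort):
        fit = hlp3_subset_fit(small_cohort, "vldl_c")
        with pytest.raises(ValueError, match="screening"):
            fit_ratio_call(LipidPanel(340, 40, 375, 118), fit, 0.209)


class TestAccuracy:
    def test_identical_vectors(self):
        d = estimate_accuracy([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (d.mad, d.rmse) == (0.0, 0.0)
        assert d.slope == pytest.approx(1.0)
        assert d.intercept == pytest.approx(0.0)
        assert d.r2 == pytest.approx(1.0)

    def test_constant_offset(self):
        ref = np.array([10.0, 20.0, 30.0])
        d = estimate_accuracy(ref + 5, ref)
        assert d.mad == pytest.approx(5.0)
        assert d.rmse == pytest.approx(5.0)
        assert d.slope == pytest.approx(1.0)
        assert d.intercept == pytest.approx(-5.0)

    def test_four_point_hand_oracle(self):
        # est=[10,20,30,40], ref=[12,18,33,37]: Sxx=500, Sxy=450, Syy=426
        d = estimate_accuracy([10, 20, 30, 40], [12, 18, 33, 37])
        assert d.mad == pytest.approx(2.5)
        assert d.rmse == pytest.approx(math.sqrt(6.5))
        assert d.slope == pytest.approx(450 / 500)
        assert d.intercept == pytest.approx(25 - 0.9 * 25)
        assert d.r2 == pytest.approx(450**2 / (500 * 426))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_accuracy([1, 2], [1, 2, 3])

    def test_rmse_dominates_mad(self, rng):
        for _ in range(20):
            est = rng.normal(50, 20, 40)
            ref = rng.normal(50, 20, 40)
            d = estimate_accuracy(est, ref)
            assert d.rmse >= d.mad

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        est = rng.uniform(0, 100, 60)
        ref = 0.8 * est + rng.normal(0, 5, 60)
        d = estimate_accuracy(est, ref)
        model = sm.OLS(ref, sm.add_constant(est)).fit()
        assert d.intercept == pytest.approx(model.params[0])
        assert d.slope == pytest.approx(model.params[1])
        assert d.r2 == pytest.approx(model.rsquared)
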