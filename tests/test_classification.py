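"""Threshold fitting, classification rule, paired t-test and evaluation."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from tmpulse import (
    ClassificationResult,
    RecordingSR,
    ThresholdModel,
    classify,
    evaluate,
    fit_threshold,
    paired_t_test,
)


def rec(sr: float, rid: str = "r", state: str | None = None) -> RecordingSR:
    return RecordingSR(recording_id=rid, state=state, sr=sr, n_windows=3)


class TestFitThreshold:
    def test_toy_arithmetic(self):
        model = fit_threshold([-8.0, -10.0, -12.0], k=3.0)
        assert model.baseline_mean == pytest.approx(-10.0)
        assert model.baseline_sd == pytest.approx(2.0)
        assert model.threshold == pytest.approx(-16.0)
        assert model.n_train == 3

    def test_degenerate_zero_spread_warns(self):
        with pytest.warns(UserWarning, match="zero spread"):
            model = fit_threshold([-5.0, -5.0, -5.0], k=3.0)
        assert model.threshold == pytest.approx(-5.0)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            fit_threshold([-7.0])

    def test_large_sample_concentration(self):
        rng = np.random.default_rng(123)
        draws = rng.normal(-10.0, 2.0, 10_000)
        model = fit_threshold(draws, k=3.0)
        assert -16.3 <= model.threshold <= -15.7

    def test_parameter_recovery_within_monte_carlo_error(self):
        # threshold estimator converges to mu - 3*sigma
        mu, sigma, n = -4.0, 0.5, 10_000
        rng = np.random.default_rng(7)
        model = fit_threshold(rng.normal(mu, sigma, n), k=3.0)
        # SE of (mean - 3 SD) ~ sigma * sqrt(1/n + 9/(2n))
        se = sigma * math.sqrt(1.0 / n + 9.0 / (2.0 * n))
        assert abs(model.threshold - (mu - 3 * sigma)) <= 3 * se


class TestClassify:
    MODEL = ThresholdModel(
        baseline_mean=-30.0, baseline_sd=7.0, k=3.0, threshold=-51.0, n_train=6
    )

    @pytest.mark.parametrize(
        "sr, predicted",
        [(-60.0, "elevated"), (-40.0, "normal"), (-51.0, "normal")],
    )
    def test_threshold_rule_with_tie_to_normal(self, sr, predicted):
        assert classify(rec(sr), self.MODEL).predicted == predicted

    def test_non_finite_sr_is_unclassifiable(self):
        result = classify(rec(float("nan")), self.MODEL)
        assert result.predicted == "unclassifiable"

    @given(
        srs=st.lists(st.floats(min_value=-100, max_value=0), min_size=2, max_size=8),
        shift=st.floats(min_value=-500, max_value=500),
        test_sr=st.floats(min_value=-100, max_value=0),
    )
    def test_threshold_shift_consistency(self, srs, shift, test_sr):
        # adding c to every SR shifts the threshold by c, predictions fixed
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-spread draws are fine here
            m0 = fit_threshold(srs, k=3.0)
            m1 = fit_threshold([v + shift for v in srs], k=3.0)
        assert m1.threshold == pytest.approx(m0.threshold + shift, abs=1e-6)
        assert (
            classify(rec(test_sr), m0).predicted
            == classify(rec(test_sr + shift), m1).predicted
        )

    @given(
        sr=st.floats(min_value=-100, max_value=0),
        drop=st.floats(min_value=0, max_value=100),
    )
    def test_lowering_sr_never_flips_elevated_to_normal(self, sr, drop):
        if classify(rec(sr), self.MODEL).predicted == "elevated":
            assert classify(rec(sr - drop), self.MODEL).predicted == "elevated"


class TestPairedTTest:
    def test_identical_samples_give_t_zero_p_one(self):
        out = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.t == 0.0 and out.p == 1.0

    def test_matches_brute_force_formula_and_scipy(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 2.0, 4.0, 5.0]
        out = paired_t_test(a, b)
        d = np.array(a) - np.array(b)
        t_manual = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_manual = 2 * stats.t.sf(abs(t_manual), len(d) - 1)
        ref = stats.ttest_rel(a, b)
        assert out.t == pytest.approx(t_manual, abs=1e-10)
        assert out.p == pytest.approx(p_manual, abs=1e-10)
        assert out.t == pytest.approx(ref.statistic, abs=1e-10)
        assert out.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert out.df == 3

    @given(
        pairs=st.lists(
            st.tuples(
                st.floats(min_value=-50, max_value=50),
                st.floats(min_value=-50, max_value=50),
            ),
            min_size=3,
            max_size=20,
        )
    )
    def test_matches_scipy_on_random_pairs(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        d = np.array(a) - np.array(b)
        if np.std(d, ddof=1) == 0:
            return  # degenerate branch covered elsewhere
        out = paired_t_test(a, b)
        ref = stats.ttest_rel(a, b)
        assert out.t == pytest.approx(ref.statistic, abs=1e-10)
        assert out.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_antisymmetry(self):
        a = [3.0, 1.0, 4.0, 1.5]
        b = [2.0, 2.5, 3.0, 0.5]
        assert paired_t_test(a, b).t == pytest.approx(-paired_t_test(b, a).t)

    def test_constant_nonzero_difference_is_degenerate(self):
        out = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert out.degenerate
        assert out.p == 0.0 and math.isinf(out.t)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            paired_t_test([1.0, 2.0], [1.0])


def result(truth: str, predicted: str, rid: str = "r") -> ClassificationResult:
    return ClassificationResult(recording_id=rid, sr=-1.0, predicted=predicted,
                                truth=truth)


class TestEvaluate:
    def test_perfect_heldout_table(self):
        results = [result("elevated", "elevated", f"e{i}") for i in range(14)]
        results += [result("normal", "normal", f"n{i}") for i in range(28)]
        m = evaluate(results)
        assert (m.tp, m.tn, m.fp, m.fn) == (14, 28, 0, 0)
        assert m.sensitivity == pytest.approx(100.0)
        assert m.specificity == pytest.approx(100.0)

    def test_all_predicted_normal_gives_zero_sensitivity(self):
        results = [result("elevated", "normal", f"e{i}") for i in range(6)]
        results += [result("normal", "normal", f"n{i}") for i in range(12)]
        m = evaluate(results)
        assert m.sensitivity == pytest.approx(0.0)

    def test_sensitivity_undefined_without_positives(self):
        m = evaluate([result("normal", "normal")])
        assert m.sensitivity is None
        assert m.specificity == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate([])

    def test_unclassifiable_result_rejected(self):
        bad = ClassificationResult("r", None, "unclassifiable", truth="normal")
        with pytest.raises(ValueError, match="unclassifiable"):
            evaluate([bad])
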