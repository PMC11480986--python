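"""Metric equations, Tropsha statistics and the Y-scrambling machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn import metrics as skm

from fragqsar import validation as va
from fragqsar.pipeline import load_external_fixture


@pytest.fixture(scope="module")
def external():
    return load_external_fixture()


class TestConfusionAndBinaryMetrics:
    def test_external_table_counts(self, external):
        c = va.confusion_counts(external["binary_observed"],
                                external["binary_predicted"])
        assert (c.tp, c.tn, c.fp, c.fn) == (4, 14, 0, 3)

    def test_perfect_and_inverted(self):
        y = [0, 1, 1, 0, 1]
        c = va.confusion_counts(y, y)
        assert c.fp == c.fn == 0
        c = va.confusion_counts(y, [1 - v for v in y])
        assert c.tp == c.tn == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            va.confusion_counts([0, 1], [0])

    def test_external_table_metrics(self, external):
        c = va.confusion_counts(external["binary_observed"],
                                external["binary_predicted"])
        m = va.binary_metrics(c)
        assert round(m.accuracy, 2) == 0.86
        assert m.sensitivity == pytest.approx(4 / 7)
        assert m.precision == pytest.approx(1.0)
        assert m.f1 == pytest.approx(8 / 11)  # 0.7273

    def test_perfect_classifier(self):
        m = va.binary_metrics(va.ConfusionCounts(5, 5, 0, 0))
        assert (m.sensitivity, m.specificity, m.precision, m.accuracy, m.f1) \
            == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_convention(self):
        m = va.binary_metrics(va.ConfusionCounts(0, 10, 0, 0))
        assert m.sensitivity == 0.0 and m.f1 == 0.0
        assert m.degenerate

    def test_accuracy_decomposition_identity(self):
        """accuracy = (sens*(TP+FN) + spec*(TN+FP)) / n for all counts."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 20, size=4)
            if tp + tn + fp + fn == 0:
                continue
            c = va.ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            m = va.binary_metrics(c)
            lhs = m.accuracy * c.total
            rhs = m.sensitivity * (tp + fn) + m.specificity * (tn + fp)
            assert lhs == pytest.approx(rhs)

    def test_f1_harmonic_mean_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 20, size=4))
            m = va.binary_metrics(va.ConfusionCounts(tp, tn, fp, fn))
            assert m.f1 == pytest.approx(
                2 / (1 / m.precision + 1 / m.sensitivity))


class TestRocAuc:
    def test_examples(self):
        assert va.roc_auc([0, 0, 1, 1], [1, 2, 3, 4]) == 1.0
        assert va.roc_auc([0, 1, 0, 1], [0.5] * 4) == 0.5
        assert va.roc_auc([0, 0, 1, 1], [0.1, 0.8, 0.4, 0.9]) == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            va.roc_auc([1, 1], [0.1, 0.2])

    def test_pairwise_oracle(self):
        """AUC equals the brute-force positive/negative pair comparison."""
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            oracle = wins / (len(pos) * len(neg))
            assert va.roc_auc(y, s) == pytest.approx(oracle)
            assert va.roc_auc(y, s) == pytest.approx(skm.roc_auc_score(y, s))


class TestLogLoss:
    def test_perfect_predictions_near_zero(self):
        Y = np.eye(3)[[0, 1, 2]]
        assert va.multiclass_log_loss(Y, Y) < 1e-12

    def test_uniform_is_ln3(self):
        Y = np.eye(3)[[0, 1, 2, 0]]
        P = np.full((4, 3), 1 / 3)
        assert va.multiclass_log_loss(Y, P) == pytest.approx(math.log(3))

    def test_half_probability_is_ln2(self):
        assert va.multiclass_log_loss([[1, 0]], [[0.5, 0.5]]) \
            == pytest.approx(math.log(2))

    def test_invalid_rows_error(self):
        with pytest.raises(ValueError):
            va.multiclass_log_loss([[1, 0]], [[0.7, 0.6]])

    def test_balanced_accuracy_is_mean_sensitivity(self):
        y = [1, 1, 1, 2, 2, 3]
        p = [1, 1, 2, 2, 2, 1]
        expected = np.mean([2 / 3, 1.0, 0.0])
        assert va.balanced_accuracy(y, p) == pytest.approx(expected)


class TestRegressionMetrics:
    def test_external_table_r2(self, external):
        m = va.regression_metrics(external["pic50_observed"],
                                  external["pic50_predicted"])
        assert round(m.r2, 2) == 0.69

    def test_perfect_and_mean_predictor(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = va.regression_metrics(y, y)
        assert (m.r2, m.rmse, m.mae) == (1.0, 0.0, 0.0)
        m = va.regression_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_rmse_dominates_mae(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(2, 40))
            y = rng.normal(size=n)
            yh = y + rng.normal(size=n)
            if np.allclose(y, y[0]):
                continue
            m = va.regression_metrics(y, yh)
            assert m.rmse >= m.mae >= 0.0

    def test_constant_y_errors(self):
        with pytest.raises(ValueError):
            va.regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(
        st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
        min_size=2, max_size=40))
    def test_metric_inequalities_hold_for_all_inputs(self, pairs):
        y = np.array([a for a, _ in pairs])
        yh = np.array([b for _, b in pairs])
        if np.all(y == y[0]):
            return
        m = va.regression_metrics(y, yh)
        assert m.rmse >= m.mae >= 0.0
        assert m.r2 <= 1.0 + 1e-12
        np.testing.assert_allclose(m.residuals, y - yh)


class TestTropsha:
    def test_identity_predictions_pass(self):
        y = np.array([5.0, 6.0, 7.0, 8.0])
        rep = va.tropsha_validation(y, y, r2_cv=0.9)
        assert rep.k == rep.k_prime == 1.0
        assert rep.r0_sq == pytest.approx(1.0)
        assert rep.r0_prime_sq == pytest.approx(1.0)
        assert rep.overall_pass

    def test_negated_predictions_fail_slope_criterion(self):
        y = np.array([5.0, 6.0, 7.0, 8.0])
        rep = va.tropsha_validation(y, -y, r2_cv=0.9)
        assert not rep.criteria[3]
        assert not rep.overall_pass

    def test_through_origin_slopes_match_closed_form(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(4, 9, 30)
        yh = y + rng.normal(0, 0.4, 30)
        rep = va.tropsha_validation(y, yh, r2_cv=0.8)
        assert rep.k == pytest.approx(np.sum(y * yh) / np.sum(yh**2))
        assert rep.k_prime == pytest.approx(np.sum(y * yh) / np.sum(y**2))

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            va.tropsha_validation([0.0, 0.0, 0.0], [0.0, 0.0, 0.0], 0.5)


class TestScrambling:
    def test_scramble_differs_from_original(self):
        rng = np.random.default_rng(5)
        y = np.arange(10, dtype=float)
        for _ in range(10):
            ys = va.scramble_y(y, rng)
            assert sorted(ys) == sorted(y)
            assert np.any(ys != y)

    def test_empty_report_max_undefined(self):
        rep = va.YScramblingReport([], 0, 0)
        with pytest.raises(ValueError):
            _ = rep.max_r2

    def test_report_tsv(self, tmp_path):
        rep = va.YScramblingReport([(0.02, 0.001), (0.01, 0.009)], 2, 0)
        va.write_scrambling_tsv(rep, tmp_path / "s.tsv")
        lines = (tmp_path / "s.tsv").read_text().strip().split("\n")
        assert lines[0] == "run\tr2_cross_validation\tr2_test"
        assert len(lines) == 3
        assert rep.max_r2 == 0.02
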