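"""Confusion-matrix metrics, repeat protocol and the Welch t-test."""

import numpy as np
import pytest

from myofatigue.evaluate import (
    ConfusionMatrix,
    classification_metrics,
    confusion_matrix,
    mean_sd_table,
    repeat_runs,
    ttest_table,
    two_sample_ttest,
)


def _random_cm(rng):
    return ConfusionMatrix(rng.integers(0, 30, size=(6, 6)))


class TestConfusionMatrix:
    def test_hand_counted_toy_pairing(self):
        y_true = [0, 0, 1, 1, 2, 2, 3, 4, 5, 5]
        y_pred = [0, 1, 1, 1, 2, 0, 3, 4, 5, 4]
        cm = confusion_matrix(y_true, y_pred)
        expected = np.zeros((6, 6), dtype=int)
        for t, p in zip(y_true, y_pred):
            expected[t, p] += 1
        assert np.array_equal(cm.matrix, expected)
        assert cm.total == 10

    def test_perfect_predictions_diagonal(self, rng):
        y = rng.integers(0, 6, size=50)
        cm = confusion_matrix(y, y)
        assert np.array_equal(np.diag(np.diag(cm.matrix)), cm.matrix)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0])

    def test_tally_identities_on_random_matrices(self, rng):
        for _ in range(200):
            cm = _random_cm(rng)
            for c in range(6):
                tp, tn, fp, fn = cm.tallies(c)
                assert tp + fn == cm.matrix[c].sum()
                assert tp + fp == cm.matrix[:, c].sum()
                assert tp + tn + fp + fn == cm.total


class TestMetrics:
    def test_worked_tally_example(self):
        # TP=50, FP=10, FN=5, TN=35 embedded in a 2-class corner of the matrix
        m = np.zeros((6, 6), dtype=int)
        m[0, 0] = 50
        m[0, 1] = 5
        m[1, 0] = 10
        m[1, 1] = 35
        rep = classification_metrics(ConfusionMatrix(m))
        c0 = rep.per_class[0]
        assert c0["precision"] == pytest.approx(0.8333, abs=1e-4)
        assert c0["recall"] == pytest.approx(0.9091, abs=1e-4)
        assert c0["specificity"] == pytest.approx(0.7778, abs=1e-4)
        assert c0["accuracy"] == pytest.approx(0.85, abs=1e-4)
        assert c0["f1"] == pytest.approx(0.8696, abs=1e-4)

    def test_perfect_matrix_all_ones(self):
        rep = classification_metrics(ConfusionMatrix(np.diag([5, 4, 3, 2, 1, 6])))
        assert rep.overall_accuracy == 1.0
        for name in ("precision", "recall", "specificity", "f1"):
            assert rep.macro[name] == 1.0

    def test_f1_definitional_identity_and_bounds(self, rng):
        for _ in range(200):
            rep = classification_metrics(_random_cm(rng))
            for v in rep.per_class.values():
                p, r, f1 = v["precision"], v["recall"], v["f1"]
                if p is not None and r is not None and p + r > 0:
                    assert f1 == pytest.approx(2 * p * r / (p + r))
                    assert f1 <= max(p, r) + 1e-12
                for name, val in v.items():
                    if val is not None:
                        assert 0.0 <= val <= 1.0

    def test_agrees_with_sklearn_per_class(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        y_true = rng.integers(0, 6, size=300)
        y_pred = rng.integers(0, 6, size=300)
        rep = classification_metrics(confusion_matrix(y_true, y_pred))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(6), zero_division=np.nan
        )
        for c in range(6):
            for mine, ref in ((rep.per_class[c]["precision"], p[c]), (rep.per_class[c]["recall"], r[c])):
                if np.isnan(ref):
                    assert mine is None
                else:
                    assert mine == pytest.approx(ref)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionMatrix(np.zeros((6, 6), dtype=int)))


class TestRepeatRuns:
    def test_ten_accuracies_recorded(self):
        res = repeat_runs(lambda s: 0.5 + 0.01 * (s % 3), n_repeats=10, base_seed=0)
        assert len(res.accuracies) == 10
        assert res.mean == pytest.approx(np.mean(res.accuracies))

    def test_constant_run_zero_sd(self):
        res = repeat_runs(lambda s: 0.9, n_repeats=5)
        assert res.sd == 0.0
        assert res.format_mean_sd() == "90.00 ± 0.00%"

    def test_failure_reports_run_index(self):
        def boom(seed):
            if seed == 3:
                raise RuntimeError("x")
            return 0.5

        with pytest.raises(RuntimeError, match="run 3"):
            repeat_runs(boom, n_repeats=10, base_seed=0)


class TestTTest:
    def test_identical_samples_null(self):
        r = two_sample_ttest([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert r.t_statistic == pytest.approx(0.0) and r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_large_shift_significant(self):
        a = [1, 2, 3, 4, 5]
        b = [11, 12, 13, 14, 15]
        r = two_sample_ttest(a, b)
        assert abs(r.t_statistic) > 5 and r.p_value < 0.02 and r.significant

    def test_welch_closed_form_on_fixed_vectors(self):
        a = np.array([0.93, 0.95, 0.94, 0.96, 0.92])
        b = np.array([0.90, 0.89, 0.91, 0.88, 0.92])
        r = two_sample_ttest(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        from scipy.stats import t as t_dist

        p_hand = 2 * t_dist.sf(abs(t_hand), df)
        assert r.t_statistic == pytest.approx(t_hand, rel=1e-9)
        assert r.p_value == pytest.approx(p_hand, rel=1e-9)

    def test_symmetry_under_swap(self, rng):
        a, b = rng.normal(size=(2, 8))
        r1 = two_sample_ttest(a, b)
        r2 = two_sample_ttest(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_variance_equal_means_convention(self):
        r = two_sample_ttest([0.5, 0.5], [0.5, 0.5])
        assert r.t_statistic == 0.0 and r.p_value == 1.0


class TestTables:
    def test_mean_sd_and_ttest_table_shapes(self):
        runs = {
            ("fused", "mlp_att"): repeat_runs(lambda s: 0.9 + 0.001 * s, 10),
            ("fused", "svm_rbf"): repeat_runs(lambda s: 0.8 + 0.002 * s, 10),
        }
        table = mean_sd_table(runs)
        assert list(table.columns) == ["variant", "family", "mean_accuracy", "sd_accuracy", "mean_sd"]
        assert "±" in table["mean_sd"].iloc[0]
        tt = ttest_table(
            {"mlp_att": runs[("fused", "mlp_att")], "svm_rbf": runs[("fused", "svm_rbf")]},
            reference="mlp_att",
        )
        assert set(tt["family"]) == {"mlp_att", "svm_rbf"}
        assert tt[tt.family == "svm_rbf"]["significant"].iloc[0] in (True, False)
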