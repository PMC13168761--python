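"""Classification metrics, curves, DeLong, CIs, and relevance regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from svcikit.evaluate import (
    ConfusionMatrix,
    auc_trapezoid,
    bootstrap_f1_ci,
    calibration_curve,
    clopper_pearson,
    confusion_from_predictions,
    decision_curve,
    delong_test,
    metrics_from_confusion,
    probability_score_correlation,
    regression_relevance,
)


class TestConfusionMetrics:
    def test_internal_test_worked_example(self):
        """The unique confusion matrix implied by a 27/34 test split with
        recall 24/27 and specificity 31/34 gives accuracy 55/61 = 0.902."""
        m = metrics_from_confusion(ConfusionMatrix(tp=24, fn=3, tn=31, fp=3))
        assert m["accuracy"] == pytest.approx(55 / 61)
        assert m["recall"] == pytest.approx(24 / 27)
        assert m["specificity"] == pytest.approx(31 / 34)
        assert round(m["accuracy"], 3) == 0.902
        assert round(m["recall"], 3) == 0.889
        assert round(m["specificity"], 3) == 0.912

    def test_symmetric_matrix(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=25, fp=25, fn=25, tn=25))
        assert m["accuracy"] == m["recall"] == m["specificity"] == m["f1"] == 0.5

    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=10, fp=0, fn=0, tn=12))
        assert m["accuracy"] == m["recall"] == m["specificity"] == m["f1"] == 1.0

    def test_empty_class_flagged(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=0, fp=2, fn=0, tn=8))
        assert m["recall"] is None
        assert any("recall" in f for f in m["flags"])

    def test_weighted_f1_option(self):
        cm = ConfusionMatrix(tp=20, fp=10, fn=5, tn=15)
        binary = metrics_from_confusion(cm)["f1"]
        weighted = metrics_from_confusion(cm, f1_average="weighted")["f1"]
        assert binary == pytest.approx(2 * 20 / (2 * 20 + 10 + 5))
        assert binary != weighted

    def test_threshold_tie_predicts_negative(self):
        cm = confusion_from_predictions(np.array([1, 0]), np.array([0.5, 0.5]))
        assert cm.tp == 0 and cm.fn == 1 and cm.tn == 1


class TestCIs:
    def test_clopper_pearson_table_value(self):
        """55 of 61 successes gives the printed exact interval."""
        lo, hi = clopper_pearson(55, 61)
        assert lo == pytest.approx(0.798, abs=5e-4)
        assert hi == pytest.approx(0.963, abs=5e-4)

    def test_boundary_cases(self):
        lo, hi = clopper_pearson(0, 20)
        assert lo == 0.0
        lo2, hi2 = clopper_pearson(20, 20)
        assert hi2 == 1.0

    def test_bootstrap_f1_contains_point(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 80)
        p = np.clip(y * 0.6 + rng.normal(0.2, 0.2, 80), 0, 1)
        med, lo, hi = bootstrap_f1_ci(y, p, n_boot=500, seed=1)
        assert lo <= med <= hi


class TestAUC:
    def test_perfect_separation(self):
        auc, _, _ = auc_trapezoid(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        s = rng.random(2000)
        y = rng.integers(0, 2, 2000)
        auc, _, _ = auc_trapezoid(s, y)
        assert abs(auc - 0.5) < 0.03

    def test_equals_mann_whitney_on_random_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = 30
            s = rng.normal(size=n)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            auc, _, _ = auc_trapezoid(s, y)
            assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_trapezoid(np.array([0.1, 0.2]), np.array([1, 1]))


class TestCurves:
    def test_calibrated_probabilities_small_gap(self):
        rng = np.random.default_rng(3)
        p = rng.random(5000)
        y = (rng.random(5000) < p).astype(int)
        table = calibration_curve(p, y)
        gaps = (table["mean_predicted"] - table["observed_fraction"]).abs()
        assert gaps.max() < 0.05

    def test_degenerate_single_bin(self):
        p = np.full(40, 0.5)
        y = np.array([0, 1] * 20)
        table = calibration_curve(p, y)
        assert len(table) == 1
        assert table["observed_fraction"].iloc[0] == 0.5

    def test_decision_curve_hand_computed(self):
        """10-subject table checked by hand at t = 0.2."""
        p = np.array([0.9, 0.8, 0.7, 0.6, 0.55, 0.4, 0.3, 0.2, 0.15, 0.05])
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        table = decision_curve(p, y, thresholds=np.array([0.2]))
        # predictions at 0.2: 8 positives, TP=4, FP=4
        expected = 4 / 10 - 4 / 10 * (0.2 / 0.8)
        assert table["net_benefit"].iloc[0] == pytest.approx(expected)
        assert table["treat_none"].iloc[0] == 0.0

    def test_perfect_classifier_net_benefit_is_prevalence(self):
        p = np.array([0.99, 0.98, 0.01, 0.02])
        y = np.array([1, 1, 0, 0])
        table = decision_curve(p, y, thresholds=np.array([0.1, 0.5, 0.9]))
        assert np.allclose(table["net_benefit"], 0.5)


class TestDeLong:
    def test_identical_scores_zero(self):
        y = np.array([1, 0, 1, 0, 1, 0])
        s = np.array([0.9, 0.2, 0.8, 0.3, 0.7, 0.4])
        z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 60)
        y[:5] = 1
        y[5:10] = 0
        a = rng.normal(size=60) + y
        b = rng.normal(size=60) + 0.5 * y
        z_ab, _ = delong_test(a, b, y)
        z_ba, _ = delong_test(b, a, y)
        assert z_ab == pytest.approx(-z_ba)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 600
        for _ in range(reps):
            y = np.r_[np.ones(20, int), np.zeros(20, int)]
            latent = rng.normal(size=40) + y
            a = latent + rng.normal(0, 0.5, 40)
            b = latent + rng.normal(0, 0.5, 40)
            _, p = delong_test(a, b, y)
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 0.03

    def test_variance_close_to_bootstrap(self):
        """DeLong variance of the AUC difference within 15% of a bootstrap
        estimate on one synthetic dataset."""
        rng = np.random.default_rng(6)
        n = 120
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        latent = rng.normal(size=n) + 1.2 * y
        a = latent + rng.normal(0, 0.7, n)
        b = latent + rng.normal(0, 0.7, n)
        z, _ = delong_test(a, b, y)
        from svcikit.evaluate import auc_trapezoid as auc_fn

        d_obs = auc_fn(a, y)[0] - auc_fn(b, y)[0]
        var_delong = (d_obs / z) ** 2
        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if y[idx].min() == y[idx].max():
                continue
            diffs.append(auc_fn(a[idx], y[idx])[0] - auc_fn(b[idx], y[idx])[0])
        var_boot = np.var(diffs)
        assert abs(var_delong - var_boot) / var_boot < 0.15


class TestCorrelations:
    def test_affine_transform_perfect_correlation(self):
        rng = np.random.default_rng(7)
        mmse = rng.normal(25, 3, 50)
        probs = np.clip(0.9 - 0.02 * mmse + 0.0 * rng.random(50), 0, 1)
        df = probability_score_correlation(probs, pd.DataFrame({"MMSE": mmse}))
        assert abs(df["r"].iloc[0]) == pytest.approx(1.0)

    def test_sign_pattern_on_severity_linked_scores(self, small_cohort):
        """Probabilities rising with lesion burden correlate negatively with
        scales where higher is better and positively with timed tests."""
        _, records, _ = small_cohort
        sev = np.array([sum(r.severity.values()) for r in records])
        probs = 1 / (1 + np.exp(-(sev - sev.mean())))
        scores = pd.DataFrame([r.scores for r in records])
        df = probability_score_correlation(probs, scores).set_index("scale")
        for scale in ("MMSE", "MoCA", "Immediate Recall", "Delayed Recall"):
            assert df.loc[scale, "r"] < 0
        for scale in ("TMT-A", "TMT-B"):
            assert df.loc[scale, "r"] > 0

    def test_permuted_scores_weak_correlation(self):
        rng = np.random.default_rng(8)
        probs = rng.random(60)
        scores = pd.DataFrame({"MMSE": rng.permutation(rng.normal(25, 3, 60))})
        df = probability_score_correlation(probs, scores)
        assert abs(df["r"].iloc[0]) < 0.35

    def test_constant_inputs_rejected(self):
        with pytest.raises(ValueError):
            probability_score_correlation(
                np.full(10, 0.5), pd.DataFrame({"MMSE": np.arange(10.0)})
            )


class TestRegressionRelevance:
    def test_signal_region_predicts_scores(self):
        """Scores generated from region intensities are recoverable when the
        mask covers the region, and not from pure-noise scores."""
        rng = np.random.default_rng(9)
        n = 60
        shape = (16, 16, 16)
        strength = rng.normal(0, 1, n)
        x = rng.normal(0, 0.3, (n, 1) + shape).astype(np.float32)
        x[:, 0, 4:12, 4:12, 4:12] += strength[:, None, None, None]
        mask = np.zeros(shape, bool)
        mask[4:12, 4:12, 4:12] = True
        scores = pd.DataFrame(
            {
                "signal": strength + rng.normal(0, 0.3, n),
                "noise": rng.normal(size=n),
            }
        )
        out = regression_relevance(
            x, mask, scores, seed=0, epochs=20, lr=3e-3
        ).set_index("scale")
        n_test = int(out.loc["signal", "n_test"])
        r = out.loc["signal", "r"]
        t_stat = r * np.sqrt(max(n_test - 2, 1)) / np.sqrt(max(1 - r**2, 1e-12))
        assert stats.t.sf(t_stat, n_test - 2) < 0.05  # one-sided
        assert abs(out.loc["noise", "r"]) < 0.6

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            regression_relevance(
                np.zeros((12, 1, 16, 16, 16), np.float32),
                np.zeros((16, 16, 16), bool),
                pd.DataFrame({"s": np.arange(12.0)}),
            )
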