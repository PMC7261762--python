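import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dbsidnn as dd
from dbsidnn.errors import DomainError, ValidationError
from dbsidnn.evaluation import evaluate_predictions


def mann_whitney_auc(y, scores):
    """Brute-force pair-count oracle: P(score_pos > score_neg) + 0.5 ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        labels = np.repeat(list(dd.CLASSES), 3)
        cm = dd.confusion_matrix(labels, labels)
        assert np.array_equal(np.diag(cm.to_numpy()), [3] * 5)
        assert cm.to_numpy().sum() == 15

    def test_all_predicted_one_class_single_column(self):
        ref = np.repeat(list(dd.CLASSES), 2)
        pred = np.array(["NAWM"] * 10)
        cm = dd.confusion_matrix(ref, pred)
        assert cm["NAWM"].sum() == 10
        assert cm.drop(columns="NAWM").to_numpy().sum() == 0

    def test_hand_tally(self):
        ref = ["PBH", "PBH", "PGH", "AGH", "NBH", "NBH", "NAWM", "PBH", "PGH", "NAWM"]
        pred = ["PBH", "PGH", "PGH", "AGH", "NBH", "NAWM", "NAWM", "PBH", "PBH", "NAWM"]
        cm = dd.confusion_matrix(ref, pred)
        assert cm.loc["PBH", "PBH"] == 2
        assert cm.loc["PBH", "PGH"] == 1
        assert cm.loc["PGH", "PBH"] == 1
        assert cm.loc["NBH", "NAWM"] == 1
        assert cm.loc["NAWM", "NAWM"] == 2

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            dd.confusion_matrix(["PBH"], ["XYZ"])


class TestRocOneVsRest:
    def test_perfect_separation(self):
        ref = np.array(["PBH"] * 5 + ["NAWM"] * 5)
        scores = np.array([0.9] * 5 + [0.1] * 5)
        _, _, _, auc = dd.roc_one_vs_rest(ref, scores, "PBH")
        assert auc == 1.0

    def test_uninformative_scores_auc_half(self):
        rng = np.random.default_rng(0)
        n = 10_000
        ref = np.where(rng.random(n) < 0.3, "PBH", "NAWM")
        scores = rng.random(n)
        _, _, _, auc = dd.roc_one_vs_rest(ref, scores, "PBH")
        assert abs(auc - 0.5) < 0.02

    def test_six_sample_hand_case_matches_pair_oracle(self):
        ref = np.array(["PBH", "NAWM", "PBH", "NAWM", "PBH", "NAWM"])
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.2])
        y = (ref == "PBH").astype(int)
        _, _, _, auc = dd.roc_one_vs_rest(ref, scores, "PBH")
        assert auc == pytest.approx(mann_whitney_auc(y, scores))

    def test_single_class_reference_rejected(self):
        with pytest.raises(DomainError):
            dd.roc_one_vs_rest(np.array(["PBH", "PBH"]), np.array([0.1, 0.9]), "PBH")

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_auc_equals_mann_whitney_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            y[0] = 0
            y[1] = 1
        # coarse scores force ties through every code path
        scores = rng.integers(0, 6, size=n) / 5.0
        ref = np.where(y == 1, "PBH", "NAWM")
        _, _, _, auc = dd.roc_one_vs_rest(ref, scores, "PBH")
        assert auc == pytest.approx(mann_whitney_auc(y, scores), abs=1e-12)


class TestPrecisionRecall:
    def test_perfect_separation(self):
        ref = np.array(["PBH"] * 3 + ["NAWM"] * 7)
        scores = np.array([0.9] * 3 + [0.1] * 7)
        _, _, _, auc = dd.precision_recall_one_vs_rest(ref, scores, "PBH")
        assert auc == 1.0

    def test_uninformative_scores_auc_near_prevalence(self):
        rng = np.random.default_rng(3)
        n = 20_000
        prevalence = 0.2
        ref = np.where(rng.random(n) < prevalence, "PBH", "NAWM")
        scores = rng.random(n)
        _, _, _, auc = dd.precision_recall_one_vs_rest(ref, scores, "PBH")
        assert abs(auc - prevalence) < 0.02

    def test_six_sample_hand_case_matches_threshold_enumeration(self):
        ref = np.array(["PBH", "NAWM", "PBH", "NAWM", "PBH", "NAWM"])
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.6, 0.2])
        y = (ref == "PBH").astype(int)
        # step-interpolated AUC = sum over thresholds of (R_i - R_{i-1}) P_i
        order = np.argsort(-scores)
        ys = y[order]
        tp = np.cumsum(ys)
        precision = tp / np.arange(1, 7)
        recall = tp / y.sum()
        expected = 0.0
        prev_r = 0.0
        for p, r in zip(precision, recall):
            expected += (r - prev_r) * p
            prev_r = r
        _, _, _, auc = dd.precision_recall_one_vs_rest(ref, scores, "PBH")
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(DomainError):
            dd.precision_recall_one_vs_rest(np.array(["NAWM"] * 4), np.arange(4.0), "PBH")


class TestF1:
    def test_perfect_and_worst(self):
        ref = np.array(["PBH"] * 4 + ["NAWM"] * 4)
        assert dd.f1_score(ref, ref, "PBH") == 1.0
        flipped = np.array(["NAWM"] * 4 + ["PBH"] * 4)
        assert dd.f1_score(ref, flipped, "PBH") == 0.0

    def test_direct_formula(self):
        # TP = 8, FP = 2, FN = 4 -> F1 = 2*8 / (2*8 + 2 + 4) = 8/11
        ref = np.array(["PBH"] * 12 + ["NAWM"] * 10)
        pred = np.array(["PBH"] * 8 + ["NAWM"] * 4 + ["PBH"] * 2 + ["NAWM"] * 8)
        assert dd.f1_score(ref, pred, "PBH") == pytest.approx(8 / 11)

    def test_absent_class_rejected(self):
        with pytest.raises(ValidationError):
            dd.f1_score(np.array(["NAWM"] * 3), np.array(["NAWM"] * 3), "PBH")


class TestOptimalCutoff:
    def test_perfect_separation(self):
        ref = np.array(["PBH"] * 5 + ["NAWM"] * 5)
        scores = np.array([0.9] * 5 + [0.1] * 5)
        fpr, tpr, thr, _ = dd.roc_one_vs_rest(ref, scores, "PBH")
        _, sens, spec = dd.optimal_cutoff(fpr, tpr, thr)
        assert sens == 1.0 and spec == 1.0

    def test_uninformative_scores_j_near_zero(self):
        rng = np.random.default_rng(1)
        n = 5_000
        ref = np.where(rng.random(n) < 0.5, "PBH", "NAWM")
        scores = rng.random(n)
        fpr, tpr, thr, _ = dd.roc_one_vs_rest(ref, scores, "PBH")
        _, sens, spec = dd.optimal_cutoff(fpr, tpr, thr)
        assert sens + spec - 1 < 0.06

    def test_matches_exhaustive_threshold_scan(self):
        ref = np.array(["PBH", "NAWM", "PBH", "NAWM", "PBH", "NAWM"])
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.6, 0.2])
        y = (ref == "PBH").astype(int)
        best_j = -np.inf
        for t in np.unique(scores):
            pred = scores >= t
            sens = np.sum(pred & (y == 1)) / y.sum()
            spec = np.sum(~pred & (y == 0)) / (len(y) - y.sum())
            best_j = max(best_j, sens + spec - 1)
        fpr, tpr, thr, _ = dd.roc_one_vs_rest(ref, scores, "PBH")
        _, sens, spec = dd.optimal_cutoff(fpr, tpr, thr)
        assert sens + spec - 1 == pytest.approx(best_j)


class TestBootstrapCi:
    def test_constant_statistic_zero_width(self):
        lo, hi, _ = dd.bootstrap_ci(lambda s: 0.42, np.arange(50), n_iter=100, seed=0)
        assert lo == hi == 0.42

    def test_same_seed_identical(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=100)
        a = dd.bootstrap_ci(np.mean, data, n_iter=200, seed=7)
        b = dd.bootstrap_ci(np.mean, data, n_iter=200, seed=7)
        assert a == b

    def test_coverage_of_mean_ci(self):
        # ~95% of intervals on Normal(0,1) samples should cover 0
        rng = np.random.default_rng(5)
        covered = 0
        n_rep = 200
        for i in range(n_rep):
            data = rng.normal(size=200)
            lo, hi, _ = dd.bootstrap_ci(np.mean, data, n_iter=300, seed=i)
            covered += lo <= 0.0 <= hi
        assert 0.90 <= covered / n_rep <= 0.99

    def test_width_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(11)
        ns = [50, 100, 200, 400, 800, 1600]
        widths = []
        for n in ns:
            data = rng.integers(0, 2, size=n).astype(float)  # Bernoulli accuracy data
            lo, hi, _ = dd.bootstrap_ci(np.mean, data, n_iter=400, seed=n)
            widths.append(hi - lo)
        slope = np.polyfit(np.log(ns), np.log(widths), 1)[0]
        assert -0.6 <= slope <= -0.4

    def test_degenerate_resamples_redrawn_and_counted(self):
        # statistic undefined when a resample lacks both labels
        data = pd.DataFrame({"y": [0] * 18 + [1] * 2})

        def stat(sample):
            if sample["y"].sum() in (0, len(sample)):
                raise dd.evaluation.DegenerateResample()
            return sample["y"].mean()

        lo, hi, redrawn = dd.bootstrap_ci(stat, data, n_iter=300, seed=1)
        assert redrawn > 0
        assert 0 < lo <= hi < 1


class TestBinomialErrorCi:
    def test_headline_interval_endpoints(self):
        # 286 errors in 4326 trials: exact binomial 95% CI (5.9%, 7.3%)
        lo, hi = dd.binomial_error_ci(4326, 286)
        assert round(lo * 100, 1) == 5.9
        assert round(hi * 100, 1) in (7.3, 7.4)  # printed precision ambiguity

    def test_extremes(self):
        lo, hi = dd.binomial_error_ci(20, 0)
        assert lo == 0.0
        lo, hi = dd.binomial_error_ci(20, 20)
        assert hi == 1.0

    def test_against_beta_quantile_oracle(self):
        from scipy.stats import beta

        n, x = 10, 5
        lo, hi = dd.binomial_error_ci(n, x)
        assert lo == pytest.approx(beta.ppf(0.025, x, n - x + 1), abs=1e-12)
        assert hi == pytest.approx(beta.ppf(0.975, x + 1, n - x), abs=1e-12)
        assert (round(lo, 3), round(hi, 3)) == (0.187, 0.813)

    def test_zero_trials_rejected(self):
        with pytest.raises(DomainError):
            dd.binomial_error_ci(0, 0)


class TestEvaluationReport:
    @pytest.fixture(scope="class")
    def report(self):
        rng = np.random.default_rng(2)
        n = 400
        ref = np.array(list(dd.CLASSES))[rng.integers(0, 5, size=n)]
        logits = rng.normal(0, 1, size=(n, 5))
        logits[np.arange(n), [list(dd.CLASSES).index(c) for c in ref]] += 2.5
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        return evaluate_predictions(ref, probs, n_bootstrap=50, seed=0)

    def test_self_consistency(self, report):
        cm = report.confusion.to_numpy()
        assert cm.sum() == report.n_test
        assert report.error_rate == pytest.approx(1 - np.trace(cm) / cm.sum())

    def test_cis_contain_point_estimates(self, report):
        assert report.error_ci[0] <= report.error_rate <= report.error_ci[1]
        for stats in report.per_class.values():
            assert stats["roc_auc_ci"][0] <= stats["roc_auc"] <= stats["roc_auc_ci"][1]

    def test_serialization_round_trip(self, report):
        import json

        d = json.loads(report.to_json())
        assert d["n_test"] == report.n_test
        assert "Confusion matrix" in report.to_text()
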