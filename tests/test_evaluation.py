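import numpy as np
import pytest
from scipy import stats

from parotid_radiomics import (
    diagnostic_metrics,
    optimal_cutoff,
    roc_auc_ci,
    stratified_split,
)
from oracles import auc_pair_counting


class TestStratifiedSplit:
    def test_published_cohort_breakdown(self):
        labels = np.array(["WT"] * 66 + ["MT"] * 40)
        train, test = stratified_split(labels, seed=0)
        assert len(train) == 79 and len(test) == 27
        assert (labels[train] == "WT").sum() == 49
        assert (labels[train] == "MT").sum() == 30
        assert (labels[test] == "WT").sum() == 17
        assert (labels[test] == "MT").sum() == 10

    def test_ceil_rule_small_classes(self):
        labels = np.array(["WT"] * 4 + ["MT"] * 4)
        train, test = stratified_split(labels, seed=1)
        assert len(test) == 2 and len(train) == 6
        assert (labels[test] == "WT").sum() == 1

    def test_same_seed_identical(self):
        labels = np.array(["WT"] * 20 + ["MT"] * 12)
        a = stratified_split(labels, seed=9)
        b = stratified_split(labels, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_partition_property(self):
        labels = np.array(["WT"] * 13 + ["MT"] * 7)
        train, test = stratified_split(labels, seed=5)
        assert len(np.intersect1d(train, test)) == 0
        assert len(train) + len(test) == 20

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(np.array(["WT", "WT", "MT"]), seed=0)


class TestAUC:
    def test_perfect_separation(self):
        scores = [3, 4, 5, 0, 1, 2]
        labels = ["WT"] * 3 + ["MT"] * 3
        res = roc_auc_ci(scores, labels)
        assert res["auc"] == 1.0
        assert res["p"] < 0.05

    def test_uninformative(self):
        res = roc_auc_ci([1.0] * 8, ["WT"] * 4 + ["MT"] * 4)
        assert res["auc"] == 0.5

    def test_worked_pair_counting(self):
        # WT: 3,2; MT: 1,2 -> (1 + 1 + 1 + 0.5)/4
        res = roc_auc_ci([3, 2, 1, 2], ["WT", "WT", "MT", "MT"])
        assert res["auc"] == pytest.approx(0.875)

    def test_oracle_equivalence_up_to_n50(self, rng):
        for trial in range(30):
            n1 = int(rng.integers(2, 26))
            n2 = int(rng.integers(2, 26))
            # duplicate-prone integer scores exercise tie handling
            scores = rng.integers(0, 10, n1 + n2).astype(float)
            labels = np.array(["WT"] * n1 + ["MT"] * n2)
            expected = auc_pair_counting(scores[:n1], scores[n1:])
            got = roc_auc_ci(scores, labels)
            assert got["auc"] == pytest.approx(max(expected, 1 - expected), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc_ci([1, 2], ["WT", "WT"])

    def test_ci_covers_point_estimate(self, rng):
        scores = rng.normal(size=40)
        labels = np.array(["WT"] * 20 + ["MT"] * 20)
        res = roc_auc_ci(scores, labels)
        assert res["ci"][0] <= res["auc"] <= res["ci"][1]


class TestOptimalCutoff:
    def test_clean_gap_midpoint(self):
        # WT {1,2,3}, MT {-2,-1}: J = 1 anywhere in (-1, 1); midpoint 0 returned
        cut, direction = optimal_cutoff([1, 2, 3, -2, -1], ["WT"] * 3 + ["MT"] * 2)
        assert cut == pytest.approx(0.0)
        assert direction == "lt"

    def test_no_separation_near_median(self):
        scores = [1, 2, 3, 1, 2, 3]
        labels = ["WT"] * 3 + ["MT"] * 3
        cut, _ = optimal_cutoff(scores, labels)
        assert 1.0 <= cut <= 3.0

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = np.array(["WT"] * 15 + ["MT"] * 15)
        cut1, _ = optimal_cutoff(scores, labels)
        cut2, _ = optimal_cutoff(np.exp(scores), labels)
        # same voxels called MT either way
        assert np.array_equal(scores < cut1, np.exp(scores) < cut2)


class TestDiagnosticMetrics:
    def _report(self, se_frac, sp_frac, n_mt=31, n_wt=48):
        """Build scores realizing given Se/Sp exactly at cutoff 0."""
        tp = round(se_frac * n_mt)
        tn = round(sp_frac * n_wt)
        mt = [-1.0] * tp + [1.0] * (n_mt - tp)
        wt = [1.0] * tn + [-1.0] * (n_wt - tn)
        return diagnostic_metrics(wt + mt, ["WT"] * n_wt + ["MT"] * n_mt, cutoff=0.0)

    def test_published_training_row_lr_arithmetic(self):
        # Se 74.19%, Sp 81.25% -> +LR 3.96, -LR 0.32 at 2 d.p.
        rep = self._report(23 / 31, 39 / 48)
        assert rep.sensitivity == pytest.approx(74.19, abs=0.01)
        assert rep.specificity == pytest.approx(81.25, abs=0.01)
        assert round(rep.pos_lr, 2) == 3.96
        assert round(rep.neg_lr, 2) == 0.32

    def test_published_feature_row_lr_arithmetic(self):
        # Se 67.74%, Sp 81.25% -> +LR 3.61
        rep = self._report(21 / 31, 39 / 48)
        assert round(rep.pos_lr, 2) == 3.61

    def test_perfect_classifier_clopper_pearson(self):
        scores = [-1.0] * 10 + [1.0] * 10
        labels = ["MT"] * 10 + ["WT"] * 10
        rep = diagnostic_metrics(scores, labels, cutoff=0.0)
        assert rep.sensitivity == 100.0 and rep.specificity == 100.0
        # exact lower bound (alpha/2)^(1/n) = 0.025^0.1 ~ 69.15%
        assert rep.sensitivity_ci[0] == pytest.approx(100 * 0.025 ** (1 / 10), abs=0.05)
        assert np.isinf(rep.pos_lr)
        assert rep.pos_lr_ci[1] == np.inf

    def test_lr_self_consistency(self, rng):
        scores = rng.normal(size=60)
        labels = np.array(["WT"] * 35 + ["MT"] * 25)
        rep = diagnostic_metrics(scores, labels, cutoff=float(np.median(scores)))
        if np.isfinite(rep.pos_lr):
            assert rep.pos_lr * (100 - rep.specificity) == pytest.approx(
                rep.sensitivity, abs=1e-12
            )
        if np.isfinite(rep.neg_lr):
            assert rep.neg_lr * rep.specificity == pytest.approx(
                100 - rep.sensitivity, abs=1e-12
            )

    def test_delong_ci_coverage_simulation(self, rng):
        # quick calibration check: CI covers the true AUC in most draws
        covered = 0
        true_auc = stats.norm.cdf(1.0 / np.sqrt(2))  # shift 1, unit variances
        for _ in range(50):
            wt = rng.normal(1.0, 1.0, 40)
            mt = rng.normal(0.0, 1.0, 30)
            res = roc_auc_ci(np.r_[wt, mt], ["WT"] * 40 + ["MT"] * 30)
            if res["ci"][0] <= true_auc <= res["ci"][1]:
                covered += 1
        assert covered >= 40  # ~95% nominal, generous slack
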