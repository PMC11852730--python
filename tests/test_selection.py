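import numpy as np
import pandas as pd
import pytest

from parotid_radiomics import (
    ScoreModel,
    SelectionConfig,
    drop_redundant,
    fit_lasso_score,
    icc_stability_filter,
    radiomic_score,
    univariate_screen,
)
from parotid_radiomics.selection import benjamini_hochberg, icc_agreement, mann_whitney_p
from oracles import icc_anova_oracle


def table_from(features: dict, labels) -> pd.DataFrame:
    df = pd.DataFrame(features)
    df.insert(0, "label", labels)
    return df


class TestICC:
    def test_identical_tables_perfect_agreement(self, rng):
        x = rng.normal(size=(10, 5))
        t1 = pd.DataFrame(x, columns=[f"f{i}" for i in range(5)])
        t1.insert(0, "label", "WT")
        retained, icc = icc_stability_filter(t1, t1.copy())
        assert np.allclose(icc, 1.0)
        assert retained == [f"f{i}" for i in range(5)]

    def test_independent_noise_dropped(self, rng):
        t1 = pd.DataFrame({"f": rng.normal(size=30)})
        t2 = pd.DataFrame({"f": rng.normal(size=30)})
        retained, icc = icc_stability_filter(t1, t2)
        assert retained == []
        assert icc["f"] < 0.5

    def test_worked_anova_example(self):
        # ratings (1,1),(2,2),(3,3),(4,6): hand-computable mixed-model ICC
        x1 = np.array([1.0, 2.0, 3.0, 4.0])
        x2 = np.array([1.0, 2.0, 3.0, 6.0])
        got = icc_agreement(x1[:, None], x2[:, None])[0]
        assert got == pytest.approx(icc_anova_oracle(x1, x2), abs=1e-12)

    def test_matches_pingouin_two_way_absolute_single(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x1 = rng.normal(size=12)
        x2 = x1 + rng.normal(scale=0.4, size=12)
        df = pd.DataFrame(
            {
                "subject": list(range(12)) * 2,
                "rater": ["a"] * 12 + ["b"] * 12,
                "score": np.concatenate([x1, x2]),
            }
        )
        ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
        ref_icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        got = icc_agreement(x1[:, None], x2[:, None])[0]
        assert got == pytest.approx(ref_icc2, abs=1e-6)

    def test_zero_variance_warns_and_zero(self):
        t1 = pd.DataFrame({"f": [1.0, 1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            retained, icc = icc_stability_filter(t1, t1.copy())
        assert icc["f"] == 0.0
        assert retained == []

    def test_too_few_lesions_rejected(self):
        t1 = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 3"):
            icc_stability_filter(t1, t1.copy())


class TestUnivariateScreen:
    def test_exact_two_vs_two(self):
        # WT {1,2} vs MT {3,4}: all 6 rank splits -> two-sided exact p = 1/3
        p = mann_whitney_p(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_bh_worked_example(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_bh_monotone_and_dominates_raw(self, rng):
        raw = rng.uniform(size=50)
        adj = benjamini_hochberg(raw)
        assert np.all(adj >= raw - 1e-15)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_constant_feature_dropped(self, rng):
        tbl = table_from(
            {"flat": np.ones(20), "good": np.r_[rng.normal(0, 1, 10), rng.normal(5, 1, 10)]},
            ["WT"] * 10 + ["MT"] * 10,
        )
        retained, rep = univariate_screen(tbl)
        assert "flat" not in retained
        assert rep.loc["flat", "p_adjusted"] == 1.0
        assert "good" in retained

    def test_single_class_rejected(self):
        tbl = table_from({"f": [1.0, 2.0]}, ["WT", "WT"])
        with pytest.raises(ValueError, match="both classes"):
            univariate_screen(tbl)

    def test_degenerate_alpha_one_keeps_noise_features(self, rng):
        tbl = table_from(
            {f"f{i}": rng.normal(size=20) for i in range(5)},
            ["WT"] * 10 + ["MT"] * 10,
        )
        retained, _ = univariate_screen(tbl, SelectionConfig(alpha=1.0))
        assert retained == [f"f{i}" for i in range(5)]


class TestRedundancyPruning:
    def test_duplicate_column_keeps_smaller_p(self, rng):
        x = rng.normal(size=40)
        tbl = table_from({"a": x, "b": x.copy()}, ["WT"] * 20 + ["MT"] * 20)
        pv = pd.Series({"a": 0.04, "b": 0.001})
        retained, elim = drop_redundant(tbl, pv)
        assert retained == ["b"]
        assert elim[0]["dropped"] == "a"

    def test_anticorrelated_pair_pruned(self, rng):
        x = rng.normal(size=60)
        tbl = table_from(
            {"up": x, "down": -x + rng.normal(scale=0.05, size=60)},
            ["WT"] * 30 + ["MT"] * 30,
        )
        pv = pd.Series({"up": 0.001, "down": 0.04})
        retained, elim = drop_redundant(tbl, pv)
        assert retained == ["up"]
        assert elim[0]["rho"] < -0.9

    def test_independent_features_all_survive(self, rng):
        cols = {f"f{i}": rng.normal(size=100) for i in range(8)}
        tbl = table_from(cols, ["WT"] * 50 + ["MT"] * 50)
        pv = pd.Series({k: 0.01 for k in cols})
        retained, elim = drop_redundant(tbl, pv)
        assert retained == list(cols)
        assert elim == []

    def test_deterministic_tie_break(self, rng):
        x = rng.normal(size=30)
        tbl = table_from({"zeta": x, "alpha": x.copy()}, ["WT"] * 15 + ["MT"] * 15)
        pv = pd.Series({"zeta": 0.02, "alpha": 0.02})
        retained, _ = drop_redundant(tbl, pv)
        assert retained == ["alpha"]  # lexicographically later name eliminated


class TestLassoScore:
    def _planted_table(self, rng, n=80, n_noise=50):
        labels = ["WT"] * (n // 2) + ["MT"] * (n // 2)
        signal = np.r_[rng.normal(2, 0.3, n // 2), rng.normal(-2, 0.3, n // 2)]
        cols = {"signal": signal}
        cols.update({f"noise{i}": rng.normal(size=n) for i in range(n_noise)})
        return table_from(cols, labels)

    def test_planted_signal_recovered_noise_suppressed(self, rng):
        tbl = self._planted_table(rng)
        model, path = fit_lasso_score(tbl, SelectionConfig(seed=1))
        assert "signal" in model.coefficients
        n_noise_kept = sum(1 for f in model.coefficients if f.startswith("noise"))
        assert n_noise_kept <= 5  # >= 90% of the 50 noise features at zero

    def test_null_table_small_or_empty_model(self, rng):
        small = 0
        reps = 50
        for rep in range(reps):
            labels = ["WT"] * 20 + ["MT"] * 20
            cols = {f"f{i}": rng.normal(size=40) for i in range(30)}
            try:
                model, _ = fit_lasso_score(table_from(cols, labels), SelectionConfig(seed=rep))
                if len(model.coefficients) <= 3:
                    small += 1
            except ValueError:
                small += 1  # heavy penalty zeroed everything
        assert small >= 0.8 * reps  # CV deviance favours heavy shrinkage on noise

    def test_fixed_seed_reproducible(self, rng):
        tbl = self._planted_table(rng)
        m1, _ = fit_lasso_score(tbl, SelectionConfig(seed=3))
        m2, _ = fit_lasso_score(tbl, SelectionConfig(seed=3))
        assert m1.lambda_ == m2.lambda_
        assert m1.coefficients == m2.coefficients

    def test_wt_scores_higher(self, rng):
        tbl = self._planted_table(rng)
        model, _ = fit_lasso_score(tbl, SelectionConfig(seed=1))
        from parotid_radiomics.selection import score_table

        s = score_table(model, tbl)
        assert s[tbl["label"] == "WT"].mean() > s[tbl["label"] == "MT"].mean()

    def test_too_few_rows_per_class_rejected(self, rng):
        tbl = self._planted_table(rng, n=10)
        with pytest.raises(ValueError, match="per class"):
            fit_lasso_score(tbl, SelectionConfig(seed=0))


class TestRadiomicScore:
    def _table4_model(self):
        # published score parameters: intercept and 3 coefficients
        return ScoreModel(
            intercept=-0.895,
            coefficients={
                "T2|log-sigma-3-mm|glszm|GrayLevelVariance": -0.765,
                "ADC|wavelet-HLL|firstorder|RootMeanSquared": 0.24,
                "T2|wavelet-LLH|glrlm|HighGrayLevelRunEmphasis": 1.654,
            },
            standardization={
                "T2|log-sigma-3-mm|glszm|GrayLevelVariance": (0.0, 1.0),
                "ADC|wavelet-HLL|firstorder|RootMeanSquared": (0.0, 1.0),
                "T2|wavelet-LLH|glrlm|HighGrayLevelRunEmphasis": (0.0, 1.0),
            },
        )

    def test_zero_vector_gives_intercept(self):
        model = self._table4_model()
        v = {f: 0.0 for f in model.coefficients}
        assert radiomic_score(model, v) == pytest.approx(-0.895)

    def test_linearity(self):
        model = ScoreModel(0.0, {"f": 2.0}, {"f": (0.0, 1.0)})
        assert radiomic_score(model, {"f": 3.0}) == pytest.approx(6.0)

    def test_single_unit_feature(self):
        model = self._table4_model()
        v = {f: 0.0 for f in model.coefficients}
        v["T2|log-sigma-3-mm|glszm|GrayLevelVariance"] = 1.0
        assert radiomic_score(model, v) == pytest.approx(-0.895 - 0.765)

    def test_standardization_applied(self):
        model = ScoreModel(1.0, {"f": 0.5}, {"f": (10.0, 2.0)})
        assert radiomic_score(model, {"f": 14.0}) == pytest.approx(1.0 + 0.5 * 2.0)

    def test_missing_feature_named(self):
        model = self._table4_model()
        with pytest.raises(KeyError, match="GrayLevelVariance"):
            radiomic_score(model, {"ADC|wavelet-HLL|firstorder|RootMeanSquared": 0.0})
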