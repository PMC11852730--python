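"""Simulation studies validating the pipeline end to end.

Two pre-registered experiments:

* **Planted-effect recovery** — the full study condition (106 lesions,
  66 WT / 40 MT, 32x32x16 ROIs, default effect profile): the selection
  cascade should flag the three planted feature families as class-
  discriminative and the fitted Radiomic Score should separate the
  classes strongly in training. Family recovery is scored at the
  univariate-screen stage (a family counts as recovered when at least
  one of its signature features, on any sequence/filter, is
  BH-significant); the later Spearman/LASSO stages deliberately collapse
  correlated features to one representative per cluster, so membership
  of the final sparse model is not the recovery criterion.

* **Null calibration** — repeated zero-effect cohorts: the fraction of
  BH-significant features should stay at or below the nominal level, and
  the test-set AUC of whatever score the cascade produces should be
  compatible with 0.5. Null repetitions use a reduced cohort (20+20
  lesions, 16x16x8 ROIs) and filter-free extraction so that 20
  repetitions stay cheap; the calibration properties checked do not
  depend on cohort scale or on the filter bank.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .cohort import CohortSpec, EffectProfile, generate_cohort
from .evaluation import roc_auc_ci, stratified_split
from .features import ExtractionConfig, extract_table
from .selection import SelectionConfig, fit_lasso_score, score_table, univariate_screen
from .selection import drop_redundant, icc_stability_filter

__all__ = ["PLANTED_FAMILIES", "planted_effect_study", "null_calibration_study"]

#: Signature features of the three planted class contrasts
#: (gray-level mean shift, correlation length, variance ratio).
PLANTED_FAMILIES = {
    "glrlm_high_gray_level": ("glrlm", "HighGrayLevelRunEmphasis"),
    "glszm_gray_level_variance": ("glszm", "GrayLevelVariance"),
    "firstorder_rms": ("firstorder", "RootMeanSquared"),
}


def _family_recovered(significant: list[str], family: str, feature: str) -> bool:
    return any(
        name.split("|")[2] == family and name.split("|")[3] == feature
        for name in significant
    )


def planted_effect_study(seed: int) -> dict:
    """Full-scale planted-effect run; returns AUCs and family recovery."""
    spec = CohortSpec(seed=seed)
    lesions = generate_cohort(spec)
    cfg = ExtractionConfig()
    features = extract_table(lesions, cfg)

    reseg = [l for l in lesions if l.mask_reseg is not None]
    seg1 = features.loc[[l.lesion_id for l in reseg]]
    seg2 = extract_table(reseg, cfg, use_reseg_mask=True)

    sel_cfg = SelectionConfig(seed=seed)
    train_idx, test_idx = stratified_split(features["label"].to_numpy(), seed=seed)
    train = features.iloc[train_idx]
    test = features.iloc[test_idx]

    stable, icc = icc_stability_filter(seg1, seg2, sel_cfg)
    screened, pv = univariate_screen(train[["label"] + stable], sel_cfg)
    pruned, _ = drop_redundant(train[["label"] + screened], pv["p_adjusted"], sel_cfg)
    model, _ = fit_lasso_score(train[["label"] + pruned], sel_cfg)

    recovered = {
        key: _family_recovered(screened, fam, feat)
        for key, (fam, feat) in PLANTED_FAMILIES.items()
    }
    train_roc = roc_auc_ci(score_table(model, train), train["label"])
    test_roc = roc_auc_ci(score_table(model, test), test["label"])
    return {
        "n_lesions": len(lesions),
        "features_per_sequence": sum(c.startswith("T2|") for c in features.columns),
        "n_stable": len(stable),
        "n_screened": len(screened),
        "n_pruned": len(pruned),
        "n_selected": len(model.coefficients),
        "families_recovered": recovered,
        "n_families_recovered": int(sum(recovered.values())),
        "training_auc": train_roc["auc"],
        "testing_auc": test_roc["auc"],
    }


def _null_rep(seed: int) -> tuple[float, float]:
    """One zero-effect repetition; returns (test AUC, BH-significant fraction)."""
    spec = CohortSpec(
        n_wt=20, n_mt=20, roi_shape=(16, 16, 8),
        effect_profile=EffectProfile.null(), n_reseg=4, seed=seed,
    )
    lesions = generate_cohort(spec)
    cfg = ExtractionConfig(images="original")
    features = extract_table(lesions, cfg)
    sel_cfg = SelectionConfig(seed=seed, cv_folds=5, n_lambdas=25)

    train_idx, test_idx = stratified_split(features["label"].to_numpy(), seed=seed)
    train = features.iloc[train_idx]
    test = features.iloc[test_idx]

    screened, pv = univariate_screen(train, sel_cfg)
    bh_fraction = float(np.mean(pv["p_adjusted"] < sel_cfg.alpha))
    if not screened:
        return 0.5, bh_fraction  # no score can be built: uninformative by construction
    pruned, _ = drop_redundant(train[["label"] + screened], pv["p_adjusted"], sel_cfg)
    try:
        model, _ = fit_lasso_score(train[["label"] + pruned], sel_cfg)
    except ValueError:
        return 0.5, bh_fraction  # all coefficients shrunk to zero
    roc = roc_auc_ci(score_table(model, test), test["label"])
    # orientation-free: keep the WT-high AUC so chance stays at 0.5
    auc = roc["auc"] if roc["wt_high"] else 1.0 - roc["auc"]
    return float(auc), bh_fraction


def null_calibration_study(seed: int, reps: int = 20) -> dict:
    """Zero-effect calibration over ``reps`` cohort repetitions."""
    seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    aucs, fracs = zip(*(_null_rep(int(s)) for s in seeds))
    aucs = np.asarray(aucs)
    se = aucs.std(ddof=1) / np.sqrt(reps)
    half = stats.t.ppf(0.975, reps - 1) * se
    mean = float(aucs.mean())
    return {
        "reps": reps,
        "mean_test_auc": mean,
        "auc_ci": (mean - float(half), mean + float(half)),
        "ci_covers_chance": bool(mean - half <= 0.5 <= mean + half),
        "bh_false_positive_fraction": float(np.mean(fracs)),
    }
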