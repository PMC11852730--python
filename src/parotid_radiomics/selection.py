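"""Four-stage feature-reduction cascade and the Radiomic Score.

Stage 1 — stability: intraclass correlation between features extracted
from the primary and a repeated segmentation; only features with
ICC > 0.85 survive. The ICC variant is ICC(A,1): two-way mixed effects,
absolute agreement, single measures — the standard choice for
intra-observer feature stability.

Stage 2 — relevance: two-sided Mann-Whitney U per feature with
Benjamini-Hochberg adjustment across all tested features jointly (both
sequences pooled); adjusted p < 0.05 survives.

Stage 3 — redundancy: pairs with Spearman |rho| > 0.9 are pruned by
eliminating the member with the larger univariate p-value (processed in
decreasing |rho| order; ties broken lexicographically for determinism).

Stage 4 — sparsity: L1-penalized logistic regression (WT encoded 1) over
a lambda path, lambda chosen to minimize the mean 10-fold cross-validated
binomial deviance; the surviving nonzero-coefficient features and their
training standardization parameters form the ScoreModel, and

    Radiomic Score = I + sum_y C_y * V_y

with V_y the z-standardized feature value. Each stage's retained set is a
subset of the previous stage's (cascade monotonicity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionConfig",
    "ScoreModel",
    "icc_stability_filter",
    "univariate_screen",
    "benjamini_hochberg",
    "drop_redundant",
    "fit_lasso_score",
    "radiomic_score",
    "run_selection_cascade",
]


@dataclass
class SelectionConfig:
    icc_threshold: float = 0.85
    alpha: float = 0.05
    spearman_threshold: float = 0.9
    cv_folds: int = 10
    lambda_rule: str = "min"  # or "1se"
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("icc_threshold", "spearman_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 < self.alpha <= 1:  # alpha = 1 is the degenerate keep-everything screen
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


@dataclass
class ScoreModel:
    """Intercept, LASSO coefficients and training standardization of the score."""

    intercept: float
    coefficients: dict[str, float]
    standardization: dict[str, tuple[float, float]]  # feature -> (mean, sd)
    lambda_: float = float("nan")

    def __post_init__(self) -> None:
        for name in self.coefficients:
            if name not in self.standardization:
                raise ValueError(f"no standardization parameters for feature {name!r}")
            if self.standardization[name][1] <= 0:
                raise ValueError(f"non-positive training sd for feature {name!r}")

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "lambda": self.lambda_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            standardization={k: (float(v[0]), float(v[1])) for k, v in d["standardization"].items()},
            lambda_=float(d.get("lambda", float("nan"))),
        )


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != "label"]


def icc_agreement(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Vectorized ICC(A,1) over columns of two (n_subjects, n_features) arrays."""
    n = x1.shape[0]
    k = 2
    data = np.stack([x1, x2], axis=1)  # (n, k, f)
    grand = data.mean(axis=(0, 1))
    row_mean = data.mean(axis=1)  # (n, f)
    col_mean = data.mean(axis=0)  # (k, f)
    ssr = k * ((row_mean - grand) ** 2).sum(axis=0)
    ssc = n * ((col_mean - grand) ** 2).sum(axis=0)
    resid = data - row_mean[:, None, :] - col_mean[None, :, :] + grand
    sse = (resid**2).sum(axis=(0, 1))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    zero_var = denom <= np.finfo(float).eps * np.maximum(1.0, np.abs(msr))
    if np.any(zero_var):
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s): ICC reported as 0",
            stacklevel=2,
        )
    return np.where(zero_var, 0.0, icc)


def icc_stability_filter(
    features_seg1: pd.DataFrame,
    features_seg2: pd.DataFrame,
    cfg: SelectionConfig | None = None,
) -> tuple[list[str], pd.Series]:
    """Retain features whose ICC across the two segmentations exceeds the gate.

    Both tables must cover the same lesions (rows) and features (columns);
    returns (retained feature names, ICC per feature).
    """
    cfg = cfg or SelectionConfig()
    feats = _feature_columns(features_seg1)
    if _feature_columns(features_seg2) != feats:
        raise ValueError("feature columns differ between the two segmentation tables")
    if not features_seg1.index.equals(features_seg2.index):
        features_seg2 = features_seg2.loc[features_seg1.index]
    if len(features_seg1) < 3:
        raise ValueError("ICC needs at least 3 lesions")
    icc = icc_agreement(
        features_seg1[feats].to_numpy(np.float64),
        features_seg2[feats].to_numpy(np.float64),
    )
    icc_s = pd.Series(icc, index=feats, name="ICC")
    retained = [f for f in feats if icc_s[f] > cfg.icc_threshold]
    return retained, icc_s


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment; monotone, adjusted p >= raw p, capped at 1."""
    p = np.asarray(pvalues, dtype=np.float64)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both groups have <= 8 observations and no ties
    straddle the groups; otherwise the normal approximation with tie
    correction.
    """
    if len(x) <= 8 and len(y) <= 8:
        try:
            return float(stats.mannwhitneyu(x, y, method="exact").pvalue)
        except ValueError:
            pass
    res = stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def univariate_screen(
    table: pd.DataFrame, cfg: SelectionConfig | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Mann-Whitney + Benjamini-Hochberg screen.

    Returns (retained feature names, frame with raw and adjusted p per
    feature). Adjustment is joint across every tested feature.
    """
    cfg = cfg or SelectionConfig()
    classes = table["label"].unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    feats = _feature_columns(table)
    wt = table[table["label"] == "WT"]
    mt = table[table["label"] == "MT"]
    raw = np.array(
        [
            mann_whitney_p(wt[f].to_numpy(np.float64), mt[f].to_numpy(np.float64))
            if (wt[f].nunique() > 1 or mt[f].nunique() > 1 or wt[f].iloc[0] != mt[f].iloc[0])
            else 1.0
            for f in feats
        ]
    )
    adj = benjamini_hochberg(raw)
    report = pd.DataFrame({"p_raw": raw, "p_adjusted": adj}, index=feats)
    retained = [f for f, a in zip(feats, adj) if a < cfg.alpha]
    return retained, report


def drop_redundant(
    table: pd.DataFrame,
    pvalues: pd.Series,
    cfg: SelectionConfig | None = None,
) -> tuple[list[str], list[dict]]:
    """Spearman redundancy pruning.

    All pairwise Spearman correlations are computed among the table's
    feature columns; pairs with |rho| above the threshold are processed in
    decreasing |rho| order and, where both members are still alive, the
    member with the larger univariate p-value is eliminated (ties:
    lexicographically later name goes). Returns (retained names,
    elimination records).
    """
    cfg = cfg or SelectionConfig()
    feats = _feature_columns(table)
    if len(feats) < 2:
        return list(feats), []
    x = table[feats].to_numpy(np.float64)
    rho = stats.spearmanr(x).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    alive = set(feats)
    pairs = [
        (abs(rho[i, j]), feats[i], feats[j], rho[i, j])
        for i in range(len(feats))
        for j in range(i + 1, len(feats))
        if abs(rho[i, j]) > cfg.spearman_threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    eliminations: list[dict] = []
    for _, fa, fb, r in pairs:
        if fa in alive and fb in alive:
            pa, pb = pvalues[fa], pvalues[fb]
            if pa > pb:
                drop = fa
            elif pb > pa:
                drop = fb
            else:
                drop = max(fa, fb)
            alive.remove(drop)
            eliminations.append({"pair": (fa, fb), "rho": float(r), "dropped": drop})
    return [f for f in feats if f in alive], eliminations


def _lasso_logistic(C: float, seed: int) -> LogisticRegression:
    return LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-6,
        random_state=seed,
    )


def _deviance_path(
    x: np.ndarray, y: np.ndarray, lambdas: np.ndarray, cfg: SelectionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SE of CV binomial deviance at each lambda."""
    n = len(y)
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(x, y))
    dev = np.zeros((len(lambdas), len(folds)))
    for j, (tr, va) in enumerate(folds):
        for i, lam in enumerate(lambdas):
            clf = _lasso_logistic(1.0 / (n * lam), cfg.seed)
            clf.fit(x[tr], y[tr])
            prob = clf.predict_proba(x[va])[:, 1]
            dev[i, j] = 2.0 * log_loss(y[va], prob, labels=[0, 1])
    return dev.mean(axis=1), dev.std(axis=1, ddof=1) / np.sqrt(len(folds))


def fit_lasso_score(
    train: pd.DataFrame, cfg: SelectionConfig | None = None
) -> tuple[ScoreModel, pd.DataFrame]:
    """LASSO-CV over the screened features; returns (ScoreModel, lambda path).

    Features are z-standardized with training statistics (stored in the
    model, applied unchanged to any later data — no leakage). WT is the
    positive class, so scores are higher for Warthin's tumors.
    """
    cfg = cfg or SelectionConfig()
    feats = _feature_columns(train)
    if not feats:
        raise ValueError("no candidate features reached the LASSO stage")
    y = (train["label"] == "WT").to_numpy(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cfg.cv_folds:
        raise ValueError(
            f"need >= {cfg.cv_folds} rows per class for {cfg.cv_folds}-fold CV, got {counts}"
        )
    raw = train[feats].to_numpy(np.float64)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    keep = sd > 0
    feats = [f for f, k in zip(feats, keep) if k]
    raw, mean, sd = raw[:, keep], mean[keep], sd[keep]
    x = (raw - mean) / sd

    n = len(y)
    lam_max = np.abs(x.T @ (y - y.mean())).max() / n
    lambdas = np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambdas)
    mean_dev, se_dev = _deviance_path(x, y, lambdas, cfg)
    i_min = int(np.argmin(mean_dev))
    if cfg.lambda_rule == "1se":
        within = np.flatnonzero(mean_dev <= mean_dev[i_min] + se_dev[i_min])
        i_sel = int(within[0])  # largest lambda within 1 SE (path is decreasing)
    else:
        i_sel = i_min
    lam = float(lambdas[i_sel])

    clf = _lasso_logistic(1.0 / (n * lam), cfg.seed)
    clf.fit(x, y)
    coefs = clf.coef_.ravel()
    nonzero = np.flatnonzero(coefs != 0)
    if nonzero.size == 0:
        raise ValueError(
            "LASSO selected no features at the chosen lambda; inspect the "
            "lambda path report (the cohort may carry no class signal)"
        )
    model = ScoreModel(
        intercept=float(clf.intercept_[0]),
        coefficients={feats[i]: float(coefs[i]) for i in nonzero},
        standardization={feats[i]: (float(mean[i]), float(sd[i])) for i in nonzero},
        lambda_=lam,
    )
    path = pd.DataFrame(
        {"lambda": lambdas, "mean_deviance": mean_dev, "se_deviance": se_dev}
    )
    return model, path


def radiomic_score(model: ScoreModel, features) -> float:
    """Radiomic Score = I + sum_y C_y * V_y over the model's features.

    ``features`` is any mapping from feature name to raw value; values are
    standardized with the model's stored training mean/sd.
    """
    score = model.intercept
    for name, coef in model.coefficients.items():
        try:
            v = features[name]
        except KeyError as exc:
            raise KeyError(f"feature {name!r} missing from the input vector") from exc
        mu, sd = model.standardization[name]
        score += coef * (float(v) - mu) / sd
    return float(score)


def score_table(model: ScoreModel, table: pd.DataFrame) -> pd.Series:
    """Radiomic Score for every row of a feature table."""
    return pd.Series(
        [radiomic_score(model, row) for _, row in table.iterrows()],
        index=table.index,
        name="radiomic_score",
    )


def run_selection_cascade(
    train: pd.DataFrame,
    features_seg1: pd.DataFrame | None = None,
    features_seg2: pd.DataFrame | None = None,
    cfg: SelectionConfig | None = None,
) -> dict:
    """Run the full cascade; returns a report dict with per-stage results.

    The ICC gate is applied when both re-segmentation tables are given;
    otherwise the cascade starts at the univariate screen (all features
    treated as stable).
    """
    cfg = cfg or SelectionConfig()
    feats = _feature_columns(train)
    report: dict = {"n_input": len(feats)}

    if features_seg1 is not None and features_seg2 is not None:
        stable, icc = icc_stability_filter(features_seg1, features_seg2, cfg)
        report["icc"] = icc
        stable = [f for f in feats if f in set(stable)]
    else:
        stable = feats
    report["stage_icc"] = stable

    sub = train[["label"] + stable]
    screened, pv = univariate_screen(sub, cfg)
    report["pvalues"] = pv
    report["stage_screen"] = screened

    pruned, elim = drop_redundant(
        train[["label"] + screened], pv["p_adjusted"], cfg
    )
    report["eliminations"] = elim
    report["stage_spearman"] = pruned

    model, path = fit_lasso_score(train[["label"] + pruned], cfg)
    report["lambda_path"] = path
    report["model"] = model
    report["stage_lasso"] = sorted(model.coefficients)
    return report
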