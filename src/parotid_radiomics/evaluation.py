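"""Train/test splitting and ROC-based diagnostic readout.

Conventions: the Radiomic Score is higher for Warthin's tumors, so the
malignant class (MT) — the clinically detected condition — is the
positive class and is called at scores *below* the cut-off. The cut-off
maximizes Youden's J over observed score midpoints. AUC is the
Mann-Whitney estimator (ties count 1/2) with DeLong variance for the CI
and the p-value against AUC = 0.5; sensitivity/specificity get exact
Clopper-Pearson CIs and likelihood ratios get log-method CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "DiagnosticReport",
    "stratified_split",
    "roc_auc_ci",
    "optimal_cutoff",
    "diagnostic_metrics",
]


@dataclass
class DiagnosticReport:
    auc: float
    auc_ci: tuple[float, float]
    auc_p: float
    cutoff: float
    direction: str  # "lt": MT called when score < cutoff
    sensitivity: float  # percent
    sensitivity_ci: tuple[float, float]
    specificity: float  # percent
    specificity_ci: tuple[float, float]
    pos_lr: float
    pos_lr_ci: tuple[float, float]
    neg_lr: float
    neg_lr_ci: tuple[float, float]
    n_mt: int
    n_wt: int

    def to_dict(self) -> dict:
        return asdict(self)


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    wt = scores[labels == "WT"]
    mt = scores[labels == "MT"]
    if len(wt) == 0 or len(mt) == 0:
        raise ValueError("both classes must be present")
    return wt, mt


def stratified_split(labels, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified one-third-style split.

    Per class the test count is ceil(n/4), drawn uniformly without
    replacement; the remainder trains. Returns (train_idx, test_idx).
    With the 66 WT + 40 MT cohort this reproduces 79 training (49 WT,
    30 MT) and 27 testing (17 WT, 10 MT) lesions.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    test: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_test = int(np.ceil(idx.size / 4))
        test.extend(rng.choice(idx, size=n_test, replace=False).tolist())
    test_idx = np.sort(np.array(test, dtype=int))
    train_idx = np.setdiff1d(np.arange(labels.size), test_idx)
    return train_idx, test_idx


def _delong_variance(wt: np.ndarray, mt: np.ndarray) -> tuple[float, float]:
    """(AUC for WT-high, DeLong variance)."""
    m, n = len(wt), len(mt)
    all_scores = np.concatenate([wt, mt])
    rank_all = stats.rankdata(all_scores)
    rank_wt = stats.rankdata(wt)
    rank_mt = stats.rankdata(mt)
    # structural components
    v10 = (rank_all[:m] - rank_wt) / n
    v01 = 1.0 - (rank_all[m:] - rank_mt) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc_ci(scores, labels, level: float = 0.95) -> dict:
    """AUC with DeLong CI and two-sided p-value against AUC = 0.5.

    AUC is computed under the WT-high convention and flipped to >= 0.5 if
    needed (the flip is recorded in ``wt_high``).
    """
    wt, mt = _as_arrays(scores, labels)
    auc, var = _delong_variance(wt, mt)
    wt_high = auc >= 0.5
    if not wt_high:
        auc = 1.0 - auc
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    if se > 0:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return {"auc": float(auc), "ci": (lo, hi), "p": p, "se": se, "wt_high": wt_high}


def optimal_cutoff(scores, labels) -> tuple[float, str]:
    """Cut-off maximizing Youden's J = Se + Sp - 1.

    MT is called at scores below the threshold (WT-high convention).
    Candidates are midpoints of consecutive distinct scores; among
    equal-J candidates the one nearest the overall score median wins.
    """
    wt, mt = _as_arrays(scores, labels)
    all_scores = np.concatenate([wt, mt])
    uniq = np.unique(all_scores)
    if uniq.size == 1:
        return float(uniq[0]), "lt"
    mids = (uniq[:-1] + uniq[1:]) / 2
    best_j = -np.inf
    best: list[float] = []
    for t in mids:
        se = np.mean(mt < t)
        sp = np.mean(wt >= t)
        j = se + sp - 1.0
        if j > best_j + 1e-12:
            best_j, best = j, [float(t)]
        elif abs(j - best_j) <= 1e-12:
            best.append(float(t))
    median = float(np.median(all_scores))
    cut = min(best, key=lambda t: (abs(t - median), t))
    return cut, "lt"


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = 1.0 - level
    lo = float(stats.beta.ppf(a / 2, k, n - k + 1)) if k > 0 else 0.0
    hi = float(stats.beta.ppf(1 - a / 2, k + 1, n - k)) if k < n else 1.0
    return lo, hi


def _lr_ci(lr: float, num_k: int, num_n: int, den_k: int, den_n: int) -> tuple[float, float]:
    """Log-method CI for a ratio of two proportions (k/n each)."""
    if not np.isfinite(lr) or lr == 0:
        return (0.0 if lr == 0 else float("inf"),) * 2
    # Haldane correction for any zero cell entering the variance
    nk, nn, dk, dn = (v + 0.5 if min(num_k, num_n - num_k, den_k, den_n - den_k) == 0 else v
                      for v in (num_k, num_n, den_k, den_n))
    se = np.sqrt(1 / nk - 1 / nn + 1 / dk - 1 / dn)
    z = stats.norm.ppf(0.975)
    return float(lr * np.exp(-z * se)), float(lr * np.exp(z * se))


def diagnostic_metrics(scores, labels, cutoff: float, direction: str = "lt") -> DiagnosticReport:
    """Full diagnostic report at a fixed cut-off (MT positive)."""
    wt, mt = _as_arrays(scores, labels)
    if direction != "lt":
        raise ValueError("only the 'lt' (MT below cut-off) direction is supported")
    tp = int(np.sum(mt < cutoff))
    fn = len(mt) - tp
    tn = int(np.sum(wt >= cutoff))
    fp = len(wt) - tn
    se = tp / (tp + fn)
    sp = tn / (tn + fp)

    pos_lr = se / (1 - sp) if sp < 1 else float("inf")
    neg_lr = (1 - se) / sp if sp > 0 else float("inf")
    pos_ci = _lr_ci(pos_lr, tp, tp + fn, fp, fp + tn)
    neg_ci = _lr_ci(neg_lr, fn, tp + fn, tn, fp + tn)
    if not np.isfinite(pos_lr):  # one-sided CI
        pos_ci = (_lr_ci(se / (0.5 / (fp + tn)), tp, tp + fn, 1, fp + tn)[0], float("inf"))
    if not np.isfinite(neg_lr):
        neg_ci = (_lr_ci((1 - se) / (0.5 / (fp + tn)), fn, tp + fn, 1, fp + tn)[0], float("inf"))

    roc = roc_auc_ci(scores, labels)
    return DiagnosticReport(
        auc=roc["auc"],
        auc_ci=roc["ci"],
        auc_p=roc["p"],
        cutoff=float(cutoff),
        direction=direction,
        sensitivity=100.0 * se,
        sensitivity_ci=tuple(100.0 * v for v in _clopper_pearson(tp, tp + fn)),
        specificity=100.0 * sp,
        specificity_ci=tuple(100.0 * v for v in _clopper_pearson(tn, tn + fp)),
        pos_lr=pos_lr,
        pos_lr_ci=pos_ci,
        neg_lr=neg_lr,
        neg_lr_ci=neg_ci,
        n_mt=len(mt),
        n_wt=len(wt),
    )
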