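"""Model evaluation: ROC/AUC with DeLong comparison tests, qualitative
grading scales, intra-observer agreement statistics, collinearity
diagnostics, and mutual information."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "AgreementResult",
    "CollinearityReport",
    "roc_auc",
    "grade_auc",
    "grade_agreement",
    "compare_auc",
    "icc",
    "cohen_kappa",
    "collinearity_diagnostics",
    "mutual_information",
]

#: AUC grading bands (lower bound inclusive).
AUC_BANDS = [
    (0.9, "excellent"),
    (0.8, "good"),
    (0.7, "fair"),
    (0.6, "poor"),
    (0.0, "fail"),
]

#: Agreement (ICC / kappa) grading bands (lower bound inclusive).
AGREEMENT_BANDS = [
    (0.8, "excellent"),
    (0.6, "good"),
    (0.4, "moderate"),
    (0.2, "poor"),
    (-float("inf"), "very poor"),
]


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    auc_variance: float
    grade: str


@dataclass(frozen=True)
class AgreementResult:
    statistic_type: str  # "ICC" or "kappa"
    value: float
    grade: str


@dataclass
class CollinearityReport:
    condition_indices: np.ndarray
    variance_decomposition: np.ndarray  # rows: condition indices, cols: columns of X
    vif: np.ndarray  # per non-intercept predictor
    flags: list[str]
    column_names: list[str]


def _check_binary(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components per positive / negative case."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical ROC curve and trapezoidal AUC.

    Ties contribute half, so the AUC equals the normalized Mann-Whitney
    statistic; the variance is DeLong's estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    _check_binary(labels)

    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos

    # collapse tied score values into single curve points
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.r_[distinct, len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[cut]
    fps = (cut + 1) - tps
    sens = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[cut]]

    auc, v10, v01 = _delong_components(scores, labels)
    trap = float(np.trapezoid(sens, fpr))
    assert abs(trap - auc) < 1e-10, "trapezoid and Mann-Whitney AUC diverged"
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        one_minus_specificity=fpr,
        auc=auc,
        auc_variance=_delong_variance(v10, v01),
        grade=grade_auc(auc),
    )


def grade_auc(auc: float) -> str:
    """Qualitative grade of an AUC: excellent / good / fair / poor / fail."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {auc}")
    for lower, grade in AUC_BANDS:
        if auc >= lower:
            return grade
    return "fail"


def grade_agreement(value: float) -> str:
    """Qualitative grade of an agreement statistic (ICC or kappa)."""
    if value > 1.0:
        raise ValueError(f"agreement statistic cannot exceed 1, got {value}")
    for lower, grade in AGREEMENT_BANDS:
        if value >= lower:
            return grade
    return "very poor"


def compare_auc(
    scores_a: Sequence[float],
    labels_a: Sequence[int],
    scores_b: Sequence[float],
    labels_b: Sequence[int],
    paired: bool = False,
) -> tuple[float, float, float]:
    """Compare two AUCs with a DeLong z-test.

    Paired: both score vectors on the same cases (labels must match); the
    joint DeLong covariance is used. Unpaired (e.g. training vs validation
    cohorts): independent variances are summed. Returns (auc_a, auc_b, p).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    _check_binary(labels_a)
    _check_binary(labels_b)

    auc_a, v10_a, v01_a = _delong_components(scores_a, labels_a)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels_b)
    var_a = _delong_variance(v10_a, v01_a)
    var_b = _delong_variance(v10_b, v01_b)

    if paired:
        if scores_a.shape != scores_b.shape or not np.array_equal(labels_a, labels_b):
            raise ValueError("paired comparison requires aligned rows and labels")
        m, n = len(v10_a), len(v01_a)
        cov10 = np.cov(v10_a, v10_b, ddof=1)[0, 1] if m > 1 else 0.0
        cov01 = np.cov(v01_a, v01_b, ddof=1)[0, 1] if n > 1 else 0.0
        var_diff = var_a + var_b - 2.0 * (cov10 / m + cov01 / n)
    else:
        var_diff = var_a + var_b

    if var_diff <= 0:
        p = 1.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


def icc(ratings: np.ndarray) -> AgreementResult:
    """Two-way mixed, absolute-agreement, single-measure intra-class
    correlation for an n-subjects x 2-measurements array."""
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] != 2:
        raise ValueError("ratings must be an (n, 2) array")
    n, k = ratings.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")

    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((ratings - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise ZeroDivisionError("no between-subject variance; ICC undefined")
    value = float((msr - mse) / denom)
    return AgreementResult("ICC", value, grade_agreement(value))


def cohen_kappa(r1: Sequence, r2: Sequence) -> AgreementResult:
    """Unweighted Cohen's kappa for two categorical rating vectors."""
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("rating vectors must be 1-D and equal length")
    cats = np.unique(np.concatenate([r1, r2]))
    n = len(r1)
    p_o = float(np.mean(r1 == r2))
    p1 = np.array([np.mean(r1 == c) for c in cats])
    p2 = np.array([np.mean(r2 == c) for c in cats])
    p_e = float(p1 @ p2)
    if p_e >= 1.0:
        raise ZeroDivisionError(
            "both raters constant and identical; kappa undefined"
        )
    value = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult("kappa", float(value), grade_agreement(value))


def collinearity_diagnostics(
    X: np.ndarray, column_names: Optional[Sequence[str]] = None
) -> CollinearityReport:
    """Condition indices, variance-decomposition proportions, and VIFs.

    Columns (intercept included by the caller) are scaled to unit length
    before the SVD. Condition-index bands: < 30 weak, 30-100 moderate to
    strong, > 100 severe.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than columns")
    names = list(column_names) if column_names else [f"col{j}" for j in range(p)]

    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero column in design matrix")
    Xs = X / norms

    _, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    s = np.where(s < 1e-300, 1e-300, s)
    cond = s.max() / s

    # variance decomposition: phi[i, j] = V[j, i]^2 / s[i]^2
    phi = (Vt**2) / (s**2)[:, None]
    vdp = phi / phi.sum(axis=0, keepdims=True)

    vif = np.empty(p)
    for j in range(p):
        xj = Xs[:, j]
        others = np.delete(Xs, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((xj - xj.mean()) ** 2).sum())
        if ss_tot == 0 or ss_res / max(ss_tot, 1e-300) < 1e-12:
            vif[j] = np.inf
        else:
            r2 = 1.0 - ss_res / ss_tot
            vif[j] = 1.0 / (1.0 - r2) if r2 < 1.0 else np.inf

    flags = []
    for ci in cond:
        if ci > 100:
            flags.append("severe")
        elif ci >= 30:
            flags.append("moderate to strong")
        else:
            flags.append("weak")
    return CollinearityReport(
        condition_indices=cond,
        variance_decomposition=vdp,
        vif=vif,
        flags=flags,
        column_names=names,
    )


def mutual_information(
    feature: Sequence[float], outcome: Sequence[int], n_bins: int = 5
) -> float:
    """Plug-in mutual information (bits) between a feature and a binary
    outcome; continuous features are discretized to quintiles first."""
    feature = np.asarray(feature, dtype=float)
    outcome = np.asarray(outcome)
    if feature.size == 0:
        raise ValueError("empty input")
    if feature.shape != outcome.shape:
        raise ValueError("feature and outcome must align")

    distinct = np.unique(feature)
    if distinct.size <= 1:
        return 0.0
    if distinct.size > n_bins:
        edges = np.quantile(feature, np.linspace(0, 1, n_bins + 1)[1:-1])
        binned = np.searchsorted(np.unique(edges), feature, side="right")
    else:
        binned = np.searchsorted(distinct, feature)

    mi = 0.0
    for b in np.unique(binned):
        for c in np.unique(outcome):
            p_xy = np.mean((binned == b) & (outcome == c))
            if p_xy == 0:
                continue
            p_x = np.mean(binned == b)
            p_y = np.mean(outcome == c)
            mi += p_xy * np.log2(p_xy / (p_x * p_y))
    return float(max(mi, 0.0))
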