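"""Statistical analyses for the bootstrap experiments.

Routing between parametric and rank-based tests follows one rule throughout:
normality is assessed with a Kolmogorov-Smirnov test against a normal with
estimated moments (Lilliefors correction); parametric tests (ANOVA, t-test,
point-biserial correlation) are used only when every group passes, otherwise
rank-based analogues (Kruskal-Wallis, rank-sum / signed-rank, rank-biserial)
are used. Post-hoc pairwise p-values are Bonferroni-multiplied by the number
of pairs. Alpha is 0.05 everywhere.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ALPHA",
    "ComparisonReport",
    "FeatureReportRow",
    "is_normal",
    "compare_groups",
    "compare_two",
    "biserial",
    "aggregate_importance",
    "single_feature_roc",
    "upper_left_operating_point",
]

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class ComparisonReport:
    test_name: str
    statistic: float
    p_value: float
    posthoc_p: np.ndarray  # Bonferroni-adjusted, symmetric, nan diagonal
    normality: list[bool]
    group_names: list[str] | None = None


@dataclass
class FeatureReportRow:
    feature: str
    correlation_type: str
    r: float
    p: float
    auc: float
    sensitivity: float
    specificity: float
    flipped: bool


def is_normal(values, alpha: float = ALPHA) -> bool:
    """Lilliefors-corrected KS normality test; True iff p >= alpha."""
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError(f"normality test needs n >= 5, got {values.size}")
    if np.ptp(values) == 0:
        log.info("is_normal: constant sample treated as non-normal")
        return False
    _, p = lilliefors(values, dist="norm")
    return bool(p >= alpha)


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, m * p)


def compare_groups(auc_sets, group_names=None, alpha: float = ALPHA) -> ComparisonReport:
    """Omnibus + Bonferroni post-hoc comparison of per-iteration AUC sets.

    ANOVA with pairwise t-tests when every group is normal; Kruskal-Wallis
    with pairwise rank-sum tests otherwise.
    """
    groups = [np.asarray(g, dtype=float) for g in auc_sets]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    normal = [is_normal(g, alpha) for g in groups]
    all_normal = all(normal)
    if all_normal:
        stat, p = sps.f_oneway(*groups)
        name = "anova"
    else:
        stat, p = sps.kruskal(*groups)
        name = "kruskal-wallis"
    k = len(groups)
    m = k * (k - 1) // 2
    post = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            if all_normal:
                _, pij = sps.ttest_ind(groups[i], groups[j])
            else:
                _, pij = sps.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
            post[i, j] = post[j, i] = _bonferroni(float(pij), m)
    return ComparisonReport(name, float(stat), float(p), post, normal, group_names)


def compare_two(a, b, paired: bool = False, alpha: float = ALPHA) -> float:
    """Two-sample p-value: t-test when both samples are normal, rank test otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal lengths")
    if paired and np.allclose(a, b):
        return 1.0  # zero differences: no evidence of any effect
    normal = is_normal(a, alpha) and is_normal(b, alpha)
    if normal:
        _, p = sps.ttest_rel(a, b) if paired else sps.ttest_ind(a, b)
    elif paired:
        _, p = sps.wilcoxon(a, b)
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(p)


def biserial(values, labels, alpha: float = ALPHA) -> tuple[float, float, str]:
    """Correlation between a continuous variable and a binary outcome.

    Point-biserial (Pearson with 0/1 labels) when the values pass the
    normality test; otherwise rank-biserial, r = 2*U/(n1*n0) - 1 from the
    Mann-Whitney U statistic, with its p-value.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("biserial correlation requires both classes present")
    if np.ptp(values) == 0:
        log.info("biserial: constant values, correlation defined as 0")
        return 0.0, 1.0, "point-biserial"
    if is_normal(values, alpha):
        r, p = sps.pointbiserialr(labels, values)
        return float(r), float(p), "point-biserial"
    pos = values[labels == 1]
    neg = values[labels == 0]
    u, p = sps.mannwhitneyu(pos, neg, alternative="two-sided")
    r = 2.0 * float(u) / (len(pos) * len(neg)) - 1.0
    return float(r), float(p), "rank-biserial"


def aggregate_importance(
    importances, removed_masks=None, threshold: float = 0.80
) -> tuple[np.ndarray, np.ndarray]:
    """Double-normalized mean feature importance across bootstrap iterations.

    Per iteration the raw scores are min-max normalized to [0, 1] and features
    removed by a correlation filter are set to 0; the per-iteration scores are
    averaged and the average is min-max normalized again. Returns
    ``(final_scores, top_mask)`` where ``top_mask`` marks scores > threshold.
    The maximum-scoring feature always scores exactly 1.
    """
    imp = np.asarray(importances, dtype=float)
    if imp.ndim == 1:
        imp = imp[None, :]
    if imp.shape[0] < 1:
        raise ValueError("need at least one iteration")
    norm = np.zeros_like(imp)
    for t in range(imp.shape[0]):
        row = imp[t]
        if removed_masks is not None:
            row = np.where(np.asarray(removed_masks[t], dtype=bool), row, 0.0)
        rng_ = row.max() - row.min()
        norm[t] = (row - row.min()) / rng_ if rng_ > 0 else 0.0
        if removed_masks is not None:
            norm[t] = np.where(np.asarray(removed_masks[t], dtype=bool), norm[t], 0.0)
    avg = norm.mean(axis=0)
    rng_ = avg.max() - avg.min()
    if rng_ == 0:
        raise ValueError("all aggregated importances are equal; cannot rank features")
    final = (avg - avg.min()) / rng_
    return final, final > threshold


def upper_left_operating_point(fpr, tpr, thresholds) -> tuple[float, float, float]:
    """Threshold minimizing Euclidean distance to (FPR=0, TPR=1); ties favor
    higher specificity (lower FPR). Returns (threshold, sensitivity, specificity)."""
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    d = np.hypot(fpr, 1.0 - tpr)
    best = np.flatnonzero(np.isclose(d, d.min()))
    k = best[np.argmin(fpr[best])]
    return float(thresholds[k]), float(tpr[k]), float(1.0 - fpr[k])


def single_feature_roc(values, labels, name: str = "feature", alpha: float = ALPHA) -> FeatureReportRow:
    """ROC of one feature used directly as a classifier confidence.

    Values are min-max normalized to [0, 1]; if the feature is anti-correlated
    with the outcome (biserial r < 0) the labels are flipped and the row is
    marked. Sensitivity/specificity are read at the upper-left-corner point.
    """
    from sklearn.metrics import roc_auc_score, roc_curve

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.ptp(values) == 0:
        raise ValueError("single_feature_roc requires non-constant values")
    conf = (values - values.min()) / np.ptp(values)
    r, p, ctype = biserial(values, labels, alpha)
    flipped = r < 0
    y = 1 - labels if flipped else labels
    auc = float(roc_auc_score(y, conf))
    fpr, tpr, thr = roc_curve(y, conf)
    _, sens, spec = upper_left_operating_point(fpr, tpr, thr)
    return FeatureReportRow(name, ctype, r, p, auc, sens, spec, bool(flipped))
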