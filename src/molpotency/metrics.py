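"""Evaluation metrics and statistical comparisons.

Pearson correlation and MSE for the continuous potency task; ROC AUC and
PR AUC for binary external evaluation; bootstrap standard deviations for
uncertainty; a one-sided DeLong test for paired ROC AUC comparisons; and a
two-sided two-sample t-test for cross-seed ablation comparisons.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


class UndefinedMetricError(ValueError):
    pass


def _as_arrays(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    return a, b


def pearson(pred, y) -> float:
    """Product-moment correlation in [-1, 1]."""
    pred, y = _as_arrays(pred, y)
    if pred.size < 2:
        raise UndefinedMetricError("need at least 2 observations")
    if np.std(pred) == 0 or np.std(y) == 0:
        raise UndefinedMetricError("zero variance input")
    return float(stats.pearsonr(pred, y).statistic)


def mse(pred, y) -> float:
    pred, y = _as_arrays(pred, y)
    if pred.size == 0:
        raise UndefinedMetricError("empty input")
    return float(np.mean((pred - y) ** 2))


def _check_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if not set(classes).issubset({0, 1}):
        raise ValueError("labels must be binary 0/1")
    return labels


def roc_auc(scores, labels) -> float:
    """P(random positive outscores random negative), ties counting 1/2."""
    labels = _check_binary(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve, step-wise interpolation."""
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("PR AUC needs at least one positive")
    return float(average_precision_score(labels, scores))


def bootstrap_sd(metric, pred, y, B: int = 1000, seed: int = 0) -> float:
    """SD of ``metric`` over B paired resamples of (pred, y) with replacement.

    Resamples on which the metric is undefined (e.g. single-class labels for
    AUC) are redrawn; gives up after 100*B failed draws.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    pred, y = _as_arrays(pred, y)
    rng = np.random.default_rng(seed)
    n = pred.size
    values = []
    attempts = 0
    while len(values) < B:
        attempts += 1
        if attempts > 100 * B:
            raise UndefinedMetricError("metric undefined on nearly all resamples")
        idx = rng.integers(0, n, size=n)
        try:
            values.append(metric(pred[idx], y[idx]))
        except (UndefinedMetricError, ValueError):
            continue
    return float(np.std(values))


# -- DeLong test -------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and its structural components V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return auc, v10, v01


def delong_one_sided(scores_a, scores_b, labels) -> float:
    """One-sided DeLong p-value for H1: AUC(a) > AUC(b) on paired scores.

    Uses the structural-components variance estimator for correlated AUCs.
    Identical score vectors give p = 0.5 (zero observed difference under a
    symmetric null); any other zero-variance difference raises.
    """
    scores_a, scores_b = _as_arrays(scores_a, scores_b)
    labels = _check_binary(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("DeLong test needs both classes present")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(d01, ddof=1) / n if n > 1 else 0.0
    )
    if var <= 0:
        # degenerate variance: identical scores give the symmetric-null 0.5;
        # a nonzero AUC difference with zero component variance is the
        # infinite-z limit (e.g. perfect vs anti-perfect separation)
        if auc_a == auc_b:
            return 0.5
        return 0.0 if auc_a > auc_b else 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(stats.norm.sf(z))


def seed_ttest(metrics_a, metrics_b) -> float:
    """Two-sided two-sample t-test p comparing per-seed metric values."""
    a = np.asarray(metrics_a, dtype=np.float64)
    b = np.asarray(metrics_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 1.0
        raise UndefinedMetricError("zero pooled variance with unequal means")
    return float(stats.ttest_ind(a, b).pvalue)


def metric_report(
    pred, y, binary: bool, B: int = 1000, seed: int = 0
) -> dict:
    """Point values + bootstrap SDs for the task-appropriate metric set."""
    if binary:
        ops = {"roc_auc": roc_auc, "pr_auc": pr_auc}
    else:
        ops = {"pearson": pearson, "mse": mse}
    report = {}
    for name, op in ops.items():
        report[name] = {
            "value": op(pred, y),
            "bootstrap_sd": bootstrap_sd(op, pred, y, B=B, seed=seed),
            "B": B,
        }
    return report
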