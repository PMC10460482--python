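"""Benchmark statistics: FDP, true-positive count, AUC and partial AUC.

Scores follow the q-value convention throughout: smaller means stronger
evidence of differential expression.  ROC quantities use the Mann-Whitney
tie convention (ties earn half credit) via trapezoidal interpolation; the
partial AUC over false-positive rates up to ``fpr_max`` is standardized by
dividing the area by ``fpr_max`` so a perfect ranking scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import InvalidParameterError, UndefinedMetricError


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise InvalidParameterError(f"length mismatch: {a.shape} vs {b.shape}")
    return a, b


def false_discovery_proportion(reject, h) -> float:
    """V/R among rejected genes; 0 when nothing is rejected."""
    reject, h = _check_pair(reject, h)
    r = int(np.count_nonzero(reject))
    if r == 0:
        return 0.0
    v = int(np.count_nonzero(np.asarray(reject, bool) & (np.asarray(h) == 0)))
    return v / r


def true_positive_count(reject, h) -> int:
    """Number of rejected genes that are truly differentially expressed."""
    reject, h = _check_pair(reject, h)
    return int(np.count_nonzero(np.asarray(reject, bool) & (np.asarray(h) == 1)))


def _check_classes(h) -> np.ndarray:
    h = np.asarray(h, int)
    if h.min() == h.max():
        raise UndefinedMetricError("ROC metrics need both truth classes present")
    return h


def roc_auc(scores, h) -> float:
    """Probability a random DE gene scores below a random EE gene."""
    scores, h = _check_pair(scores, h)
    h = _check_classes(h)
    return float(roc_auc_score(h, -np.asarray(scores, float)))


def partial_auc(scores, h, fpr_max: float = 0.1) -> float:
    """Standardized area under the ROC curve over FPR in [0, fpr_max]."""
    if not 0 < fpr_max <= 1:
        raise InvalidParameterError(f"fpr_max={fpr_max} must be in (0, 1]")
    scores, h = _check_pair(scores, h)
    h = _check_classes(h)
    fpr, tpr, _ = roc_curve(h, -np.asarray(scores, float))
    if fpr_max < 1.0:
        # truncate the curve at fpr_max, interpolating on the entering segment
        keep = fpr <= fpr_max
        last = int(np.count_nonzero(keep)) - 1
        fpr_t, tpr_t = fpr[keep], tpr[keep]
        if fpr_t[-1] < fpr_max:
            nxt = last + 1
            frac = (fpr_max - fpr[last]) / (fpr[nxt] - fpr[last])
            fpr_t = np.append(fpr_t, fpr_max)
            tpr_t = np.append(tpr_t, tpr[last] + frac * (tpr[nxt] - tpr[last]))
        fpr, tpr = fpr_t, tpr_t
    return float(np.trapezoid(tpr, fpr) / fpr_max)


@dataclass(frozen=True)
class MetricSummary:
    """Replicate means and Monte-Carlo standard errors of the four metrics."""

    fdp_mean: float
    tp_mean: float
    auc_mean: float
    pauc_mean: float
    fdp_se: float
    tp_se: float
    auc_se: float
    pauc_se: float
    n_reps: int


def summarize_replicates(replicates: pd.DataFrame) -> MetricSummary:
    """Aggregate per-replicate rows (columns fdp, tp, auc, pauc).

    Means are arithmetic means; standard errors are sd/sqrt(n_reps).
    Replicates where a ROC metric was undefined (single truth class) are
    excluded from that metric's mean.
    """
    n = len(replicates)
    if n == 0:
        raise InvalidParameterError("no replicates to summarize")

    def _mean_se(col: str) -> tuple[float, float]:
        vals = replicates[col].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        return float(vals.mean()), se

    fdp, fdp_se = _mean_se("fdp")
    tp, tp_se = _mean_se("tp")
    auc, auc_se = _mean_se("auc")
    pauc, pauc_se = _mean_se("pauc")
    return MetricSummary(fdp, tp, auc, pauc, fdp_se, tp_se, auc_se, pauc_se, n)
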