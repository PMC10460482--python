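"""p-tilde statistics, the pFDR estimator and q-values.

The rejection statistic for gene j is the product
``ptilde_j = P_j * pi0|alpha(X_j)``: a gene is declared differentially
expressed when its p-tilde falls at or below a threshold t.  Written on the
p-value scale the same rule rejects when ``P_j <= u_t(X_j)`` with
``u_t(x) = min(1, t / pi0|alpha(x))``, so genes in covariate regions with a
low conditional null probability face a laxer p-value cutoff.

For a threshold t with R(t) = #{ptilde <= t} rejections the pFDR estimate is

    pfdr_hat(t) = t * C / R(t),   C = sum_j pi0(X_j) / pi0|alpha(X_j),

an upper bound for the exact estimator sum_j u_t(X_j) * pi0(X_j) / R(t)
(equality when pi0|alpha(X_j) >= t for all j).  Gene j's q-value is the
minimum of pfdr_hat(t) over thresholds t >= ptilde_j; because pfdr_hat only
drops where R jumps and increases in t between jumps, the minimum is attained
on the observed p-tilde order statistics and is computed exactly.

With pi0|alpha identically 1 and a single global pi0 the machinery collapses
to the standard (covariate-free) q-value procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .nullprob import (
    COVARIATE_COL,
    DEFAULT_N_BINS,
    GENE_COL,
    PVALUE_COL,
    NullProbFit,
    check_test_table,
    estimate_pi0,
)


@dataclass(frozen=True)
class InferenceResult:
    """Per-gene inference output at one target pFDR level."""

    ptilde: np.ndarray
    qvalue: np.ndarray
    reject: np.ndarray
    t_star: float      # largest rejected p-tilde (0 when nothing is rejected)
    c_sum: float       # C = sum pi0 / pi0|alpha
    level: float

    @property
    def n_rejected(self) -> int:
        return int(np.count_nonzero(self.reject))


def compute_ptilde(pvalues: np.ndarray, pi0_alpha: np.ndarray) -> np.ndarray:
    """Elementwise product P_j * pi0|alpha(X_j)."""
    p = np.asarray(pvalues, float)
    w = np.asarray(pi0_alpha, float)
    if p.shape != w.shape:
        raise InvalidParameterError(
            f"length mismatch: {p.shape} p-values vs {w.shape} pi0_alpha"
        )
    return p * w


def rejection_upper_bound(t: float, pi0_alpha):
    """Upper bound u_t of the p-value rejection region [0, u_t(x)].

    ``u_t = 1`` when ``pi0_alpha <= t``, else ``t / pi0_alpha``; satisfies
    ``p <= u_t  <=>  p * pi0_alpha <= t`` for p in [0, 1].
    """
    if t < 0:
        raise InvalidParameterError(f"t={t} must be nonnegative")
    w = np.asarray(pi0_alpha, float)
    with np.errstate(divide="ignore"):
        out = np.where(w <= t, 1.0, t / w)
    return float(out) if np.isscalar(pi0_alpha) else out


def estimate_pfdr(
    t: float,
    ptilde: np.ndarray,
    pi0: np.ndarray,
    pi0_alpha: np.ndarray,
    variant: str = "upper_bound",
) -> float:
    """Estimated pFDR of the rule ptilde <= t.

    ``variant="upper_bound"`` (default) returns ``t * C / R(t)``;
    ``variant="exact"`` returns ``sum(u_t(X_j) * pi0_j) / R(t)``.  Both
    return 0 when no gene is rejected.
    """
    if t < 0:
        raise InvalidParameterError(f"t={t} must be nonnegative")
    if variant not in ("upper_bound", "exact"):
        raise InvalidParameterError(f"unknown variant {variant!r}")
    pt = np.asarray(ptilde, float)
    r = int(np.count_nonzero(pt <= t))
    if r == 0:
        return 0.0
    if variant == "upper_bound":
        c = float(np.sum(np.asarray(pi0, float) / np.asarray(pi0_alpha, float)))
        return t * c / r
    u = rejection_upper_bound(t, np.asarray(pi0_alpha, float))
    return float(np.sum(u * np.asarray(pi0, float))) / r


def compute_qvalues(ptilde: np.ndarray, c_sum: float) -> np.ndarray:
    """q-values: running minimum of t * c_sum / R(t) over t >= each ptilde.

    Evaluated exactly on the p-tilde order statistics (the minimizers of the
    step-function estimator), capped at 1, returned in input order.  Tied
    p-tilde values share the rank of the last tied element and hence a
    common q-value.
    """
    if c_sum < 0:
        raise InvalidParameterError(f"c_sum={c_sum} must be nonnegative")
    pt = np.asarray(ptilde, float)
    m = pt.size
    order = np.argsort(pt, kind="stable")
    ranks = np.arange(1, m + 1)
    cand = pt[order] * c_sum / ranks
    q_sorted = np.minimum(np.minimum.accumulate(cand[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def run_inference(table: pd.DataFrame, fit: NullProbFit, level: float) -> InferenceResult:
    """Full inference at a target pFDR level from a null-probability fit."""
    if not 0 < level <= 1:
        raise InvalidParameterError(f"level={level} must be in (0, 1]")
    tab = check_test_table(table)
    if len(tab) != fit.pi0.size:
        raise InvalidParameterError(
            f"fit covers {fit.pi0.size} genes but table has {len(tab)}"
        )
    p = tab[PVALUE_COL].to_numpy(float)
    ptilde = compute_ptilde(p, fit.pi0_alpha)
    c_sum = float(np.sum(fit.pi0 / fit.pi0_alpha))
    qvalue = compute_qvalues(ptilde, c_sum)
    reject = qvalue <= level
    t_star = float(ptilde[reject].max()) if reject.any() else 0.0
    return InferenceResult(
        ptilde=ptilde,
        qvalue=qvalue,
        reject=reject,
        t_star=t_star,
        c_sum=c_sum,
        level=float(level),
    )


def standard_qvalue(
    pvalues: np.ndarray,
    pi0: float | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> np.ndarray:
    """Standard covariate-free q-values.

    A single global null proportion (estimated by the histogram rule unless
    supplied) weights every gene equally, i.e. ``compute_qvalues(p, m*pi0)``.
    """
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0, _ = estimate_pi0(p, n_bins=n_bins)
    return compute_qvalues(p, p.size * float(pi0))


def result_table(table: pd.DataFrame, fit: NullProbFit, result: InferenceResult) -> pd.DataFrame:
    """Canonical eight-column output table (reject encoded as 0/1)."""
    tab = check_test_table(table)
    out = pd.DataFrame(
        {
            GENE_COL: tab[GENE_COL],
            PVALUE_COL: tab[PVALUE_COL],
            COVARIATE_COL: tab[COVARIATE_COL],
            "pi0": fit.pi0,
            "pi0_alpha": fit.pi0_alpha,
            "ptilde": result.ptilde,
            "qvalue": result.qvalue,
            "reject": result.reject.astype(int),
        }
    )
    return out
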