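"""Neighborhood estimation of covariate-conditional null probabilities.

Each gene j carries a p-value P_j and a real-valued covariate X_j (for
example log10 gene length).  Two conditional probabilities of the gene being
null (equally expressed) are estimated from the p-values of the ``nnh`` genes
whose covariate values are nearest to X_j in Euclidean distance:

* ``pi0(x) = P(gene null | X = x)`` — a Storey-type tail estimator applied to
  the neighborhood p-values, with the tail cutoff ``Pcut`` chosen by an
  iterative histogram rule so that the p-value distribution above ``Pcut``
  looks uniform;
* ``pi0|a(x) = P(gene null | P <= alpha, X = x)``, obtained from the identity
  ``pi0|a(x) = alpha * pi0(x) / P(P <= alpha | X = x)`` with
  ``P(P <= alpha | X = x)`` estimated as the neighborhood proportion of
  p-values at or below ``alpha``, and the ratio capped at 1.

The per-gene fit sorts genes by covariate once and slides a contiguous
window, so fitting all m genes costs O(m log m) rather than O(m * nnh).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidParameterError

#: Default number of equal-width histogram bins used to locate Pcut.
DEFAULT_N_BINS = 20

#: Floor applied to pi0|alpha only when the neighborhood pi0 estimate is
#: exactly zero; keeps the p-tilde statistic and the q-value constant
#: C = sum pi0/pi0|alpha well defined (the ratio is then exactly 0).
_PI0_ALPHA_FLOOR = 1e-12

GENE_COL = "gene_id"
PVALUE_COL = "pvalue"
COVARIATE_COL = "covariate"


def check_test_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a test table (columns gene_id, pvalue, covariate).

    Returns the validated frame (a defensive copy with a clean integer
    index).  Raises :class:`DataError` with a row-level message on the first
    violation found.
    """
    for col in (GENE_COL, PVALUE_COL, COVARIATE_COL):
        if col not in table.columns:
            raise DataError(f"missing required column {col!r}")
    if len(table) < 1:
        raise DataError("test table must contain at least one row")
    out = table[[GENE_COL, PVALUE_COL, COVARIATE_COL]].reset_index(drop=True)

    p = pd.to_numeric(out[PVALUE_COL], errors="coerce").to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(p) | (p < 0.0) | (p > 1.0))
    if bad.size:
        j = int(bad[0])
        raise DataError(
            f"row {j} (gene {out[GENE_COL].iloc[j]!r}): p-value "
            f"{out[PVALUE_COL].iloc[j]!r} is not a number in [0, 1]"
        )
    x = pd.to_numeric(out[COVARIATE_COL], errors="coerce").to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        j = int(bad[0])
        raise DataError(
            f"row {j} (gene {out[GENE_COL].iloc[j]!r}): covariate "
            f"{out[COVARIATE_COL].iloc[j]!r} is not finite"
        )
    if out[GENE_COL].duplicated().any():
        dup = out[GENE_COL][out[GENE_COL].duplicated()].iloc[0]
        raise DataError(f"duplicate gene_id {dup!r}")
    out[PVALUE_COL] = p
    out[COVARIATE_COL] = x
    return out


@dataclass(frozen=True)
class NullProbFit:
    """Per-gene conditional null-probability estimates.

    ``pi0``, ``prob_le_alpha``, ``pi0_alpha`` and ``pcut`` are aligned with
    the row order of the table the fit was computed from.  ``x_sorted`` and
    ``p_sorted`` retain the training covariates (ascending) and their
    p-values so the fit can be evaluated at new covariate values.
    """

    alpha: float
    nnh: int
    n_bins: int
    pi0: np.ndarray
    prob_le_alpha: np.ndarray
    pi0_alpha: np.ndarray
    pcut: np.ndarray
    x_sorted: np.ndarray
    p_sorted: np.ndarray

    @property
    def m(self) -> int:
        return self.x_sorted.size


# ---------------------------------------------------------------------------
# window machinery (shared by fitting, prediction and cross-validation)

def _window_starts(x_sorted: np.ndarray, values: np.ndarray, nnh: int) -> np.ndarray:
    """Start index of the size-``nnh`` window of covariates nearest each value.

    For each query value v the window [L, L+nnh) over the ascending training
    covariates minimizes the larger endpoint distance; exact distance ties
    prefer the leftward (smaller-covariate) window, so the window is a
    function of v alone and equal covariates get equal windows.
    """
    m = x_sorted.size
    if nnh >= m:
        return np.zeros(values.shape, dtype=np.intp)
    lo = np.zeros(values.shape, dtype=np.intp)
    hi = np.full(values.shape, m - nnh, dtype=np.intp)
    while True:
        active = lo < hi
        if not active.any():
            break
        mid = np.minimum((lo + hi) // 2, m - nnh - 1)  # converged lanes ignore it
        move = (values - x_sorted[mid]) > (x_sorted[mid + nnh] - values)
        lo = np.where(active & move, mid + 1, lo)
        hi = np.where(active & ~move, mid, hi)
    return lo


def _bin_cumcounts(p_sorted: np.ndarray, n_bins: int) -> np.ndarray:
    """Cumulative per-bin counts: row i holds bin counts of p_sorted[:i]."""
    bins = np.minimum((p_sorted * n_bins).astype(np.intp), n_bins - 1)
    cum = np.zeros((p_sorted.size + 1, n_bins), dtype=np.int64)
    cum[np.arange(1, p_sorted.size + 1), bins] = 1
    np.cumsum(cum, axis=0, out=cum)
    return cum


def _pi0_from_hist(hist: np.ndarray, nnh: int, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Apply the iterative histogram rule to each row of bin counts.

    Pcut is the left edge of the first bin whose count does not exceed the
    mean count of that bin and all bins to its right; the null proportion is
    the tail mass at or above Pcut rescaled by 1/(1 - Pcut), capped at 1.
    """
    suffix = hist[:, ::-1].cumsum(axis=1)[:, ::-1]
    remaining = n_bins - np.arange(n_bins)
    ok = hist <= suffix / remaining
    b = np.argmax(ok, axis=1)  # last bin always satisfies the rule
    pcut = b / n_bins
    tail = suffix[np.arange(hist.shape[0]), b]
    pi0 = np.minimum(1.0, (tail / nnh) / (1.0 - pcut))
    return pi0, pcut


def _combine_pi0_alpha(pi0: np.ndarray, prob_le_alpha: np.ndarray, alpha: float) -> np.ndarray:
    """pi0|alpha = min(1, alpha*pi0 / P(P<=alpha)); conservative fallbacks."""
    pi0 = np.asarray(pi0, float)
    ple = np.asarray(prob_le_alpha, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = alpha * pi0 / ple
    out = np.where(ple > 0, np.minimum(1.0, raw), 1.0)
    return np.maximum(out, _PI0_ALPHA_FLOOR)


def _evaluate(
    x_sorted: np.ndarray,
    p_sorted: np.ndarray,
    values: np.ndarray,
    alpha: float,
    nnh: int,
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Neighborhood estimates (pi0, prob_le_alpha, pi0_alpha, pcut) at values."""
    lo = _window_starts(x_sorted, values, nnh)
    cum = _bin_cumcounts(p_sorted, n_bins)
    hist = cum[lo + nnh] - cum[lo]
    pi0, pcut = _pi0_from_hist(hist, nnh, n_bins)
    cum_le = np.concatenate(([0], np.cumsum(p_sorted <= alpha)))
    ple = (cum_le[lo + nnh] - cum_le[lo]) / nnh
    pi0_alpha = _combine_pi0_alpha(pi0, ple, alpha)
    return pi0, ple, pi0_alpha, pcut


# ---------------------------------------------------------------------------
# public operations

def find_neighborhood(covariates: np.ndarray, j: int, nnh: int) -> np.ndarray:
    """Indices of the ``nnh`` genes with covariates closest to gene ``j``.

    Gene j itself is eligible (distance zero).  Exact distance ties are
    broken toward the smaller input index.  Returned indices are sorted
    ascending.
    """
    x = np.asarray(covariates, float)
    m = x.size
    if not 1 <= nnh <= m:
        raise InvalidParameterError(f"nnh={nnh} must be in [1, m={m}]")
    if not 0 <= j < m:
        raise InvalidParameterError(f"gene index {j} out of range for m={m}")
    dist = np.abs(x - x[j])
    order = np.lexsort((np.arange(m), dist))
    return np.sort(order[:nnh])


def estimate_pi0(pvalues: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> tuple[float, float]:
    """Histogram-based null-proportion estimate for one set of p-values.

    Returns ``(pi0_hat, pcut)`` where ``pcut`` is the equal-width bin edge
    above which the empirical p-value distribution is treated as uniform and
    ``pi0_hat = #{P >= pcut} / (N * (1 - pcut))`` capped at 1.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise InvalidParameterError("cannot estimate pi0 from an empty p-value vector")
    if n_bins < 2:
        raise InvalidParameterError(f"n_bins={n_bins} must be >= 2")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    bins = np.minimum((p * n_bins).astype(np.intp), n_bins - 1)
    hist = np.bincount(bins, minlength=n_bins)[None, :]
    pi0, pcut = _pi0_from_hist(hist, p.size, n_bins)
    return float(pi0[0]), float(pcut[0])


def estimate_prob_le_alpha(pvalues: np.ndarray, alpha: float) -> float:
    """Proportion of p-values at or below ``alpha``."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise InvalidParameterError("empty p-value vector")
    if not 0 < alpha <= 1:
        raise InvalidParameterError(f"alpha={alpha} must be in (0, 1]")
    return float(np.mean(p <= alpha))


def estimate_pi0_alpha(pi0_hat: float, prob_le_alpha: float, alpha: float) -> float:
    """Conditional null probability given P <= alpha, capped at 1.

    ``min(1, alpha * pi0_hat / prob_le_alpha)``; a zero denominator returns
    the maximally conservative value 1.
    """
    if not 0 <= pi0_hat <= 1:
        raise InvalidParameterError(f"pi0_hat={pi0_hat} must be in [0, 1]")
    if not 0 < alpha <= 1:
        raise InvalidParameterError(f"alpha={alpha} must be in (0, 1]")
    return float(_combine_pi0_alpha(np.array([pi0_hat]), np.array([prob_le_alpha]), alpha)[0])


def fit_null_probabilities(
    table: pd.DataFrame,
    alpha: float,
    nnh: int,
    n_bins: int = DEFAULT_N_BINS,
) -> NullProbFit:
    """Estimate pi0(X_j) and pi0|alpha(X_j) for every gene in ``table``.

    Genes are sorted by covariate once and each gene's neighborhood is the
    contiguous window of size ``nnh`` nearest its covariate value, so genes
    with identical covariates receive identical estimates and the whole fit
    runs in O(m log m).
    """
    tab = check_test_table(table)
    m = len(tab)
    if not 0 < alpha <= 1:
        raise InvalidParameterError(f"alpha={alpha} must be in (0, 1]")
    if not 2 <= nnh <= m:
        raise InvalidParameterError(f"nnh={nnh} must be in [2, m={m}]")
    if n_bins < 2:
        raise InvalidParameterError(f"n_bins={n_bins} must be >= 2")
    x = tab[COVARIATE_COL].to_numpy(float)
    p = tab[PVALUE_COL].to_numpy(float)
    order = np.argsort(x, kind="stable")
    x_sorted = x[order]
    p_sorted = p[order]
    pi0, ple, pi0_alpha, pcut = _evaluate(x_sorted, p_sorted, x, alpha, nnh, n_bins)
    return NullProbFit(
        alpha=float(alpha),
        nnh=int(nnh),
        n_bins=int(n_bins),
        pi0=pi0,
        prob_le_alpha=ple,
        pi0_alpha=pi0_alpha,
        pcut=pcut,
        x_sorted=x_sorted,
        p_sorted=p_sorted,
    )


def predict_pi0_alpha(fit: NullProbFit, new_covariates: np.ndarray) -> np.ndarray:
    """Evaluate a fitted pi0|alpha estimate at new covariate values.

    Each new value is matched to its ``nnh`` nearest training covariates and
    the estimate is recomputed from the training p-values, so a new value
    equal to a training covariate reproduces the training estimate exactly.
    """
    if fit.x_sorted.size == 0:
        raise InvalidParameterError("fit has no training data")
    values = np.atleast_1d(np.asarray(new_covariates, float))
    if not np.all(np.isfinite(values)):
        raise InvalidParameterError("new covariates must be finite")
    _, _, pi0_alpha, _ = _evaluate(
        fit.x_sorted, fit.p_sorted, values, fit.alpha, fit.nnh, fit.n_bins
    )
    return pi0_alpha


def augment_table(table: pd.DataFrame, fit: NullProbFit) -> pd.DataFrame:
    """Input table plus pi0, prob_le_alpha, pi0_alpha and pcut columns."""
    tab = check_test_table(table)
    tab["pi0"] = fit.pi0
    tab["prob_le_alpha"] = fit.prob_le_alpha
    tab["pi0_alpha"] = fit.pi0_alpha
    tab["pcut"] = fit.pcut
    return tab
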