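"""Two-group normal expression simulator and benchmark runner.

The generative model for m genes and n samples per treatment group:

    X_j ~ N(mu_x, sigma_x^2)                      gene covariate
    sigma_j^2 ~ var_scale / ChiSquare(var_df)     gene variance (inverse chi-square)
    H_j | X_j ~ Bernoulli(1 - pi0(X_j))           1 = differentially expressed
    delta_1j | H_j = H_j * N(mu_delta, sigma_delta^2)   treatment effect
    Y_skj ~ N(delta_kj, sigma_j^2),  delta_0j = 0

Defaults follow the benchmark conditions this package is validated under:
m = 10000 genes, n = 10 samples per group, covariate N(4, 0.5^2) (log10 gene
length scale), gene variances from an unscaled inverse chi-square with 5
degrees of freedom, effect spread sigma_delta = 0.02.  Three null-probability
scenarios are provided: a constant pi0A(x) = 0.8, and two increasing sigmoids
pi0B(x) = 0.6 + 0.3/(1+exp(-10(x-4))) and pi0C(x) = 0.7 + 0.3/(1+exp(-10(x-4)))
(the latter reaching a null probability of one for large covariates).

Per-gene p-values come from the pooled-variance two-sample t-test (both
groups share sigma_j^2, so the equal-variance test is exact; Welch is
available as a flag).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import special, stats

from . import metrics as _metrics
from . import pfdr as _pfdr
from .alpha_select import CvConfig, select_alpha
from .exceptions import InvalidParameterError
from .nullprob import COVARIATE_COL, GENE_COL, PVALUE_COL, fit_null_probabilities

_SEED_MAX = 2**31


def pi0_scenario(name: str, x):
    """Null-probability scenario functions A (constant), B and C (sigmoid)."""
    x = np.asarray(x, float)
    if name == "A":
        out = np.full(x.shape, 0.8)
    elif name == "B":
        out = 0.6 + 0.3 * special.expit(10.0 * (x - 4.0))
    elif name == "C":
        out = np.minimum(1.0, 0.7 + 0.3 * special.expit(10.0 * (x - 4.0)))
    else:
        raise InvalidParameterError(f"unknown pi0 scenario {name!r}; expected A, B or C")
    return out if out.shape else float(out)


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters of the two-group normal model."""

    m: int = 10000
    n: int = 10
    mu_delta: float = 0.24
    sigma_delta: float = 0.02
    mu_x: float = 4.0
    sigma_x: float = 0.5
    var_df: float = 5.0
    var_scale: float = 1.0
    pi0_fn: str | Callable[[np.ndarray], np.ndarray] = "B"
    covariate_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.m < 2 or self.n < 2:
            raise InvalidParameterError("m and n must both be >= 2")
        if self.sigma_delta < 0 or self.sigma_x <= 0 or self.var_df <= 0 or self.var_scale <= 0:
            raise InvalidParameterError("invalid scale or degrees-of-freedom parameter")

    def pi0(self, x):
        if callable(self.pi0_fn):
            return np.asarray(self.pi0_fn(np.asarray(x, float)), float)
        return np.asarray(pi0_scenario(self.pi0_fn, x), float)


@dataclass(frozen=True)
class SimTruth:
    """Latent state of one simulated dataset, for scoring procedures."""

    h: np.ndarray        # 1 = differentially expressed
    x: np.ndarray        # covariate
    delta1: np.ndarray   # treatment-group effect (0 where h == 0)
    sigma2: np.ndarray   # gene variance


def simulate_dataset(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, SimTruth]:
    """Draw one dataset; returns (expression[group, sample, gene], truth)."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    m, n = scenario.m, scenario.n
    if scenario.covariate_sampler is not None:
        x = np.asarray(scenario.covariate_sampler(rng, m), float)
    else:
        x = rng.normal(scenario.mu_x, scenario.sigma_x, size=m)
    sigma2 = scenario.var_scale / rng.chisquare(scenario.var_df, size=m)
    h = (rng.random(m) < 1.0 - scenario.pi0(x)).astype(np.int8)
    delta1 = np.where(h == 1, rng.normal(scenario.mu_delta, scenario.sigma_delta, size=m), 0.0)
    sigma = np.sqrt(sigma2)
    expr = np.empty((2, n, m))
    expr[0] = rng.normal(0.0, sigma, size=(n, m))
    expr[1] = rng.normal(delta1, sigma, size=(n, m))
    return expr, SimTruth(h=h, x=x, delta1=delta1, sigma2=sigma2)


def two_sample_t_pvalues(expression: np.ndarray, equal_var: bool = True) -> np.ndarray:
    """Two-sided two-sample t-test p-value per gene (pooled variance).

    Genes whose pooled variance is exactly zero get p = 1 (no evidence under
    a degenerate within-group spread).
    """
    a, b = np.asarray(expression[0], float), np.asarray(expression[1], float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InvalidParameterError("each group needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate genes patched below
        res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        p = np.asarray(res.pvalue, float)
    degenerate = (a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)) == 0.0
    p[degenerate | ~np.isfinite(p)] = 1.0
    return p


def truth_table(truth: SimTruth) -> pd.DataFrame:
    return pd.DataFrame(
        {"h": truth.h.astype(int), "covariate": truth.x,
         "delta1": truth.delta1, "sigma2": truth.sigma2}
    )


def make_test_table(pvalues: np.ndarray, covariates: np.ndarray) -> pd.DataFrame:
    """Assemble the canonical test table (gene_id, pvalue, covariate)."""
    m = len(pvalues)
    width = len(str(m))
    return pd.DataFrame(
        {
            GENE_COL: [f"g{str(i).zfill(width)}" for i in range(m)],
            PVALUE_COL: np.asarray(pvalues, float),
            COVARIATE_COL: np.asarray(covariates, float),
        }
    )


# ---------------------------------------------------------------------------
# benchmark procedures

_PROC_RE = re.compile(r"^(std|prop)\.q(?:\((?P<args>[^)]*)\))?$")


def parse_procedure(name: str) -> dict:
    """Parse a procedure label such as ``prop.q(est, alpha=cv)``.

    Families: ``std.q`` (covariate-free q-values) and ``prop.q`` (the
    covariate-conditional procedure).  Tokens: ``est`` (default) or ``true``
    for estimated vs oracle null probabilities, and ``alpha=<float|cv>``
    (default 0.05) for prop.q.
    """
    m = _PROC_RE.match(name.replace(" ", ""))
    if m is None:
        raise InvalidParameterError(f"unknown procedure {name!r}")
    family = m.group(1)
    truth = False
    alpha: float | str = 0.05
    for tok in filter(None, (m.group("args") or "").split(",")):
        if tok in ("est", "true"):
            truth = tok == "true"
        elif tok.startswith(("alpha=", "α=")):
            val = tok.split("=", 1)[1]
            if val == "cv":
                alpha = "cv"
            else:
                alpha = float(val)
                if not 0 < alpha <= 1:
                    raise InvalidParameterError(f"alpha={alpha} must be in (0, 1]")
        else:
            raise InvalidParameterError(f"unknown token {tok!r} in procedure {name!r}")
    if family == "prop" and truth and alpha != 1:
        raise InvalidParameterError("prop.q(true, ...) is only defined with alpha=1")
    if family == "std":
        canonical = f"std.q({'true' if truth else 'est'})"
    else:
        canonical = f"prop.q({'true' if truth else 'est'}, alpha={alpha})"
    return {"family": family, "true": truth, "alpha": alpha, "name": canonical}


def _apply_procedure(
    proc: dict,
    table: pd.DataFrame,
    truth: SimTruth,
    scenario: SimScenario,
    level: float,
    nnh: int,
    cv_config: CvConfig | None,
    seed: int,
) -> np.ndarray:
    """q-values of one procedure on one simulated dataset."""
    p = table[PVALUE_COL].to_numpy(float)
    m = p.size
    if proc["family"] == "std":
        if proc["true"]:
            pi0_const = float(np.mean(scenario.pi0(truth.x)))
            return _pfdr.standard_qvalue(p, pi0=pi0_const)
        return _pfdr.standard_qvalue(p)
    if proc["true"]:
        # oracle null probabilities at alpha=1: pi0|1(x) = pi0(x), C = m
        pi0 = scenario.pi0(truth.x)
        ptilde = _pfdr.compute_ptilde(p, np.maximum(pi0, 1e-12))
        return _pfdr.compute_qvalues(ptilde, float(m))
    alpha = proc["alpha"]
    if alpha == "cv":
        cfg = cv_config if cv_config is not None else CvConfig(nnh=nnh, level=level)
        cfg = replace(cfg, nnh=min(cfg.nnh, m), seed=seed)
        alpha = select_alpha(table, cfg).alpha_star
    fit = fit_null_probabilities(table, alpha=float(alpha), nnh=min(nnh, m))
    return _pfdr.run_inference(table, fit, level).qvalue


def run_scenario(
    scenario: SimScenario,
    procedures: list[str],
    n_reps: int,
    level: float = 0.05,
    seed: int | None = None,
    nnh: int = 2000,
    cv_config: CvConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, _metrics.MetricSummary]]:
    """Replicate the simulation and score each procedure.

    Per replicate: simulate, compute t-test p-values, run each procedure at
    the target level, record FDP, true-positive count, AUC and partial AUC.
    Returns the per-replicate rows and a per-procedure summary (means and
    Monte-Carlo standard errors).  Replicates use child seeds derived from
    ``seed`` so each is individually reproducible.
    """
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    specs = [parse_procedure(name) for name in procedures]
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    rows = []
    for rep in range(n_reps):
        child = int(rng.integers(0, _SEED_MAX))
        expr, truth = simulate_dataset(replace(scenario, seed=child))
        p = two_sample_t_pvalues(expr)
        table = make_test_table(p, truth.x)
        h = truth.h.astype(int)
        both_classes = 0 < h.sum() < h.size
        for proc in specs:
            q = _apply_procedure(proc, table, truth, scenario, level, nnh, cv_config, child)
            reject = q <= level
            rows.append(
                {
                    "procedure": proc["name"],
                    "rep": rep,
                    "fdp": _metrics.false_discovery_proportion(reject, h),
                    "tp": _metrics.true_positive_count(reject, h),
                    "auc": _metrics.roc_auc(q, h) if both_classes else np.nan,
                    "pauc": _metrics.partial_auc(q, h) if both_classes else np.nan,
                }
            )
    replicates = pd.DataFrame(rows)
    summaries = {
        name: _metrics.summarize_replicates(group)
        for name, group in replicates.groupby("procedure", sort=False)
    }
    return replicates, summaries
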