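# Methods

## Model and inference procedure

`condq` works in the two-group multiple-testing setting: m genes, each with
a two-sided p-value P_j and a real covariate X_j, where the prior
probability of gene j being null (equally expressed) is a function of the
covariate.  Two conditional null probabilities drive the procedure:

* `pi0(x) = P(null | X = x)`;
* `pi0|a(x) = P(null | P <= alpha, X = x) = alpha * pi0(x) / P(P <= alpha | X = x)`,
  which follows from the assumption that null p-values are Uniform(0, 1).

The rejection rule declares gene j DE when its p-tilde value
`P~_j = P_j * pi0|a(X_j)` falls at or below a threshold t.  Equivalently,
on the p-value scale, `P_j <= u_t(X_j)` with `u_t(x) = min(1, t / pi0|a(x))`.
Among rules that are everywhere at least as strict as the flat rule
`P <= alpha`, this family is the unique one that makes the conditional
type-1 error posterior probability `P(type-1 error | P <= alpha, X)` equal
across all genes; the test suite verifies this property by Monte Carlo with
an analytically known `pi0|a`.

For a threshold t, with `R(t)` the number of p-tilde values at or below t,
the pFDR estimate is `t * C / R(t)` where `C = sum_j pi0(X_j) / pi0|a(X_j)`.
This is the simple upper bound of the exact conditional-expectation
estimator `sum_j u_t(X_j) * pi0(X_j) / R(t)`; the two coincide whenever no
`pi0|a(X_j)` falls below t, and both are exposed (`estimate_pfdr`, variants
`upper_bound` and `exact`).  The q-value of gene j is the minimum of the
estimated pFDR over thresholds `t >= P~_j`.  Because the estimator only
decreases where R jumps and increases in t between jumps, the minimum is
attained on the observed p-tilde order statistics; `compute_qvalues`
evaluates it there exactly (a brute-force dense-grid minimization agrees to
1e-12 in the tests).  Estimates are capped at 1, and `pFDR^(t)` is defined
as 0 below the smallest p-tilde (matching the convention FDP = 0 when
nothing is rejected).

## Neighborhood estimation

Both conditional probabilities are estimated from the `Nnh` genes whose
covariate values are nearest the target gene's in Euclidean distance
(default `Nnh = 2000`; the gene itself is a member of its own
neighborhood).  Within a neighborhood:

* `pi0` uses a histogram uniform-tail rule: p-values are binned into
  `n_bins = 20` equal-width bins; scanning left to right, `Pcut` is the left
  edge of the first bin whose count does not exceed the mean count of that
  bin and all bins to its right; then
  `pi0 = #{P >= Pcut} / (Nnh * (1 - Pcut))`, capped at 1.  `n_bins` is
  configurable; 20 bins keeps per-bin counts around 100 at the default
  neighborhood size, large enough that the scan is not noise-driven.
* `P(P <= alpha | x)` is the neighborhood proportion of p-values at or
  below alpha, and `pi0|a = min(1, alpha * pi0 / P(P <= alpha | x))`.

Degenerate cases are resolved conservatively: a neighborhood with no
p-value at or below alpha gets `pi0|a = 1`; a neighborhood whose `pi0`
estimate is exactly 0 would give `pi0|a = 0`, which is floored at 1e-12 so
the p-tilde statistic and the constant C stay well defined (the gene then
contributes 0 to C and is effectively always rejected, consistent with a
neighborhood that appears to be pure signal).

Fitting all m genes sorts once by covariate and slides a contiguous window,
computing per-window histograms from cumulative bin counts: O(m log m +
m·n_bins) rather than O(m·Nnh).  The window for a query value v is the
size-`Nnh` contiguous run of sorted covariates minimizing the larger
endpoint distance, with exact-distance ties resolved toward the smaller
covariate; since the window depends only on v, genes with identical
covariates always receive identical estimates, and out-of-sample prediction
(`predict_pi0_alpha`, used by cross-validation) reuses the same machinery —
a query equal to a training covariate reproduces the training estimate
exactly.  The standalone `find_neighborhood` helper breaks exact-distance
ties toward the smaller input index instead; the two rules can differ only
when two candidates are exactly equidistant, which has probability zero for
continuous covariates.

## Choosing alpha

`alpha` indexes the conditioning event `P <= alpha`.  `alpha = 1` makes
`pi0|a = pi0`; smaller alpha sharpens the contrast between signal-rich and
signal-poor covariate regions but makes the neighborhood proportion
noisier.  `select_alpha` runs repeated k-fold cross-validation (defaults: a
grid of 100 equally spaced values on [0.001, 0.2], 10 folds, 1 repeat for
simulation work and 100 recommended for a single real dataset): per fold,
the rejection threshold t* attaining the target level is learned on the
training genes, the fitted `pi0|a` is evaluated at held-out covariates, and
held-out genes with `p * pi0|a <= t*` are counted.  The grid value with the
highest mean count wins; ties break to the smallest (most conservative)
alpha.  Fold assignment is drawn on row positions after sorting by gene
identifier and applying a seeded shuffle, so the selection does not depend
on input row order.  Inside a fold `Nnh` is clamped to the training size
with a logged warning.  When cross-validation is not used the default is
`alpha = 0.05`.  The fold loop shares all alpha-independent work (sorting,
windows, pi0 histograms) across the grid; a test pins its equality to the
plain per-alpha evaluation path.

## Synthetic data

`simulation.SimScenario` generates the two-group normal model used for
validation:

| parameter | default | meaning |
|---|---|---|
| m | 10000 | genes |
| n | 10 | samples per treatment group |
| mu_x, sigma_x | 4.0, 0.5 | covariate normal law (log10 gene-length scale) |
| var_df, var_scale | 5, 1 | gene variance `sigma_j^2 = var_scale / ChiSquare(var_df)` |
| mu_delta, sigma_delta | 0.24, 0.02 | treatment-effect normal law for DE genes |
| pi0_fn | "B" | null-probability scenario |

Scenarios: A is constant 0.8; B is `0.6 + 0.3*sigmoid(10(x-4))`; C is
`0.7 + 0.3*sigmoid(10(x-4))` (capped at 1, and reaching a fully null
covariate region).  The inverse chi-square is the unscaled reciprocal
`1/ChiSquare(df)` (mean 1/3 at df = 5); a scale is available via
`var_scale`.  P-values use the pooled-variance two-sample t-test — exact
here because both groups share `sigma_j^2` — with Welch available via
`equal_var=False`; genes with zero pooled variance get p = 1.  User-supplied
`pi0_fn` callables and covariate samplers allow non-standard scenarios, but
no validation surface is defined for them.

What the generator does not emulate about real RNA-seq: counts are not
negative-binomial, genes are independent (no correlation between
expression vectors), the alternative p-value law does not vary with the
covariate, and library-size/normalization artifacts are absent.  Passing
benchmarks here therefore demonstrate the statistical mechanics of the
procedure, not robustness to correlated or count-valued data.

`run_scenario` replicates simulate → t-test → procedure → metrics for any
of `std.q(est|true)`, `prop.q(est, alpha=<value|cv>)` and
`prop.q(true, alpha=1)` (oracle null probabilities), deriving per-replicate
child seeds (< 2^31) from one root seed so each replicate is independently
reproducible.  Metrics per replicate: FDP (0 when nothing is rejected),
true-positive count, Mann-Whitney AUC of the q-value ranking, and partial
AUC over false-positive rates up to 0.1 standardized by dividing the area
by 0.1 (deliberately not the McClish transform).  Ties in scores receive
half credit via trapezoidal interpolation.

## Validation scales and numerical choices

The statistical acceptance tests run at reduced but honest scales chosen as
study conditions: FDP control uses 300 replicates at m = 2000, Nnh = 400;
null-probability recovery uses 20 replicates at m = 10000, Nnh = 2000; the
cross-validation benefit check uses 100 replicates at m = 2000 with the
full 100-point grid.  Monte-Carlo bands are three standard errors.
Q-value ties share the rank of the last tied element; `t_star` is reported
as the largest rejected p-tilde (0 when none), which coincides with the
q-value view of the rejection set.  The inference level is accepted on
(0, 1], level 1 meaning "reject everything".

## Known limitations

* Uniform-tail pi0 estimation is conservatively biased upward, and the bias
  grows with the fraction of weak-effect alternatives: when per-gene power
  is low (e.g. effect mean 0.24 with n = 10 and inverse-chi-square(5)
  variances), a substantial share of alternative p-values lands above any
  cutoff, and the per-gene estimates can exceed the true null probability
  by 0.1-0.2 where the true value is low.  This keeps pFDR control intact
  (the estimator over-counts nulls) but costs power, and it is a property
  of the estimator class, not of the histogram rule: fixed-lambda Storey
  estimates on the same data show the same floor.
* The covariate is univariate; the distance-based neighborhood generalizes
  in principle but standardization questions for multivariate covariates
  are unresolved, so only one covariate is accepted.
* Correlated p-values are outside the validated envelope (as with other
  procedures of this family, control degrades under strong correlation).
* Smoothing-spline pi0(lambda) estimation and local-FDR/FDR-regression
  style alternatives are out of scope.
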