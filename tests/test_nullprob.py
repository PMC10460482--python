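"""Neighborhood null-probability estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condq import (
    DataError,
    InvalidParameterError,
    check_test_table,
    estimate_pi0,
    estimate_pi0_alpha,
    estimate_prob_le_alpha,
    find_neighborhood,
    fit_null_probabilities,
    pi0_scenario,
    predict_pi0_alpha,
)
from conftest import make_table, simulated_table


class TestFindNeighborhood:
    def test_interior_point_with_distance_tie_prefers_smaller_index(self):
        # value 2: itself plus one of the equidistant 1 and 3; index rule picks 1
        assert find_neighborhood([1, 2, 3, 10], j=1, nnh=2).tolist() == [0, 1]

    def test_boundary_neighborhood_is_one_sided(self):
        assert find_neighborhood([1, 2, 3, 10], j=3, nnh=2).tolist() == [2, 3]

    def test_full_set_when_nnh_equals_m(self):
        assert find_neighborhood([5, 1, 3], j=0, nnh=3).tolist() == [0, 1, 2]

    def test_self_is_always_included(self, rng):
        x = rng.normal(size=50)
        for j in (0, 17, 49):
            assert j in find_neighborhood(x, j=j, nnh=5)

    def test_nnh_larger_than_m_rejected(self):
        with pytest.raises(InvalidParameterError):
            find_neighborhood([1, 2, 3], j=0, nnh=4)


class TestEstimatePi0:
    def test_uniform_grid_gives_one_with_zero_cutoff(self):
        p = (np.arange(1000) + 0.5) / 1000
        pi0, pcut = estimate_pi0(p)
        assert pi0 == 1.0
        assert pcut == 0.0

    def test_pure_signal_gives_zero(self):
        pi0, pcut = estimate_pi0(np.full(500, 1e-6))
        assert pi0 == 0.0
        assert pcut == pytest.approx(0.05)

    def test_half_signal_half_uniform_recovers_half(self):
        # hand-traced: spike bin is skipped, tail 475/1000 rescaled by 1/0.95
        p = np.concatenate([np.full(500, 1e-6), (np.arange(500) + 0.5) / 500])
        pi0, pcut = estimate_pi0(p)
        assert pi0 == pytest.approx(0.5)
        assert pcut == pytest.approx(0.05)

    def test_appending_strong_signal_never_increases_estimate(self):
        base = list((np.arange(200) + 0.5) / 200)
        prev = estimate_pi0(np.array(base))[0]
        for _ in range(30):
            base.append(1e-8)
            cur = estimate_pi0(np.array(base))[0]
            assert cur <= prev + 1e-12
            prev = cur

    def test_empty_and_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate_pi0(np.array([]))
        with pytest.raises(InvalidParameterError):
            estimate_pi0(np.array([0.5]), n_bins=1)
        with pytest.raises(InvalidParameterError):
            estimate_pi0(np.array([1.5]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200), st.integers(2, 40))
    def test_output_ranges_and_pcut_is_a_bin_edge(self, pvals, n_bins):
        pi0, pcut = estimate_pi0(np.array(pvals), n_bins=n_bins)
        assert 0.0 <= pi0 <= 1.0
        assert 0.0 <= pcut < 1.0
        assert (pcut * n_bins) == pytest.approx(round(pcut * n_bins))


class TestEstimateProbLeAlpha:
    def test_counts_proportion(self):
        assert estimate_prob_le_alpha([0.01, 0.2, 0.9], 0.05) == pytest.approx(1 / 3)

    def test_alpha_one_is_always_one(self):
        assert estimate_prob_le_alpha([0.3, 0.99, 1.0], 1.0) == 1.0

    def test_no_small_pvalues_gives_zero(self):
        assert estimate_prob_le_alpha([0.5, 0.9], 0.05) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate_prob_le_alpha([], 0.05)


class TestEstimatePi0Alpha:
    def test_ratio(self):
        assert estimate_pi0_alpha(0.8, 0.2, 0.05) == pytest.approx(0.2)

    def test_vacuous_conditioning_returns_pi0(self):
        assert estimate_pi0_alpha(0.7, 1.0, 1.0) == pytest.approx(0.7)

    def test_cap_binds_at_one(self):
        assert estimate_pi0_alpha(1.0, 0.05, 0.05) == 1.0

    def test_zero_denominator_is_maximally_conservative(self):
        assert estimate_pi0_alpha(0.8, 0.0, 0.05) == 1.0


class TestFit:
    def test_global_neighborhood_shares_one_estimate(self, rng):
        p = rng.random(100)
        table = make_table(p, rng.normal(size=100))
        fit = fit_null_probabilities(table, alpha=0.05, nnh=100)
        assert np.ptp(fit.pi0) == 0.0
        assert np.ptp(fit.pi0_alpha) == 0.0
        pi0_g, _ = estimate_pi0(p)
        assert fit.pi0[0] == pytest.approx(pi0_g)

    def test_matches_per_gene_neighborhood_construction(self, rng):
        # naive oracle: explicit neighborhood search + scalar estimators
        m, nnh, alpha = 200, 50, 0.1
        p, x = rng.random(m), rng.normal(size=m)
        fit = fit_null_probabilities(make_table(p, x), alpha=alpha, nnh=nnh)
        for j in range(0, m, 7):
            idx = find_neighborhood(x, j, nnh)
            pi0_j, _ = estimate_pi0(p[idx])
            ple_j = estimate_prob_le_alpha(p[idx], alpha)
            assert fit.pi0[j] == pytest.approx(pi0_j, abs=1e-12)
            assert fit.prob_le_alpha[j] == pytest.approx(ple_j, abs=1e-12)
            assert fit.pi0_alpha[j] == pytest.approx(
                estimate_pi0_alpha(pi0_j, ple_j, alpha), abs=1e-12
            )

    def test_row_permutation_permutes_outputs(self, rng):
        m = 300
        table = make_table(rng.random(m), rng.normal(size=m))
        perm = rng.permutation(m)
        fit = fit_null_probabilities(table, alpha=0.05, nnh=60)
        fit_p = fit_null_probabilities(table.iloc[perm].reset_index(drop=True),
                                       alpha=0.05, nnh=60)
        np.testing.assert_allclose(fit_p.pi0, fit.pi0[perm])
        np.testing.assert_allclose(fit_p.pi0_alpha, fit.pi0_alpha[perm])

    def test_identical_covariates_get_identical_estimates(self, rng):
        x = np.repeat([1.0, 2.0, 3.0], 30)
        table = make_table(rng.random(90), x)
        fit = fit_null_probabilities(table, alpha=0.1, nnh=40)
        for v in (1.0, 2.0, 3.0):
            assert np.ptp(fit.pi0[x == v]) == 0.0
            assert np.ptp(fit.pi0_alpha[x == v]) == 0.0

    def test_estimate_ranges_and_cap_identity(self):
        table, _ = simulated_table(seed=3, m=1000)
        fit = fit_null_probabilities(table, alpha=0.05, nnh=200)
        assert np.all((fit.pi0 >= 0) & (fit.pi0 <= 1))
        assert np.all((fit.pi0_alpha > 0) & (fit.pi0_alpha <= 1))
        pos = (fit.prob_le_alpha > 0) & (fit.pi0 > 0)
        np.testing.assert_allclose(
            fit.pi0_alpha[pos],
            np.minimum(1.0, 0.05 * fit.pi0[pos] / fit.prob_le_alpha[pos]),
        )

    def test_alpha_one_reduces_to_pi0(self):
        table, _ = simulated_table(seed=4, m=800)
        fit = fit_null_probabilities(table, alpha=1.0, nnh=200)
        np.testing.assert_allclose(fit.pi0_alpha, np.minimum(1.0, np.maximum(fit.pi0, 1e-12)))

    def test_pure_null_estimates_are_conservative(self, rng):
        # uniform p-values: both estimates should sit near 1
        m = 5000
        table = make_table(rng.random(m), rng.normal(size=m))
        fit = fit_null_probabilities(table, alpha=0.05, nnh=1000)
        assert fit.pi0.mean() >= 0.9
        assert fit.pi0_alpha.mean() >= 0.9
        assert np.ptp(fit.pi0) < 0.25  # roughly constant when covariate uninformative

    def test_sigmoid_scenario_estimates_track_shape_conservatively(self):
        # increasing pi0B(x): estimates increase with x and stay above truth
        reps = []
        for seed in range(5):
            table, truth = simulated_table(seed=200 + seed, m=5000)
            fit = fit_null_probabilities(table, alpha=0.05, nnh=1000)
            reps.append((truth.x, fit.pi0))
        x = np.concatenate([r[0] for r in reps])
        est = np.concatenate([r[1] for r in reps])
        lo, mid, hi = np.quantile(x, [0.1, 0.5, 0.9])
        means = [est[np.abs(x - q) < 0.05].mean() for q in (lo, mid, hi)]
        assert means[0] < means[1] < means[2]
        for q, m_est in zip((lo, mid, hi), means):
            assert m_est >= pi0_scenario("B", q) - 0.02  # upward (conservative) bias

    def test_parameter_errors(self, rng):
        table = make_table(rng.random(10), rng.normal(size=10))
        with pytest.raises(InvalidParameterError):
            fit_null_probabilities(table, alpha=0.05, nnh=11)
        with pytest.raises(InvalidParameterError):
            fit_null_probabilities(table, alpha=0.0, nnh=5)
        with pytest.raises(InvalidParameterError):
            fit_null_probabilities(table, alpha=0.05, nnh=5, n_bins=1)


class TestPredict:
    def test_training_covariates_reproduce_training_estimates(self, rng):
        table = make_table(rng.random(400), rng.normal(size=400))
        fit = fit_null_probabilities(table, alpha=0.05, nnh=80)
        pred = predict_pi0_alpha(fit, table["covariate"].to_numpy())
        np.testing.assert_allclose(pred, fit.pi0_alpha)

    def test_far_covariate_uses_extreme_one_sided_window(self, rng):
        table = make_table(rng.random(100), np.sort(rng.normal(size=100)))
        fit = fit_null_probabilities(table, alpha=0.1, nnh=20)
        far = predict_pi0_alpha(fit, np.array([1e6]))[0]
        # estimate from the 20 genes with the largest covariates
        top = table.nlargest(20, "covariate")["pvalue"].to_numpy()
        pi0_top, _ = estimate_pi0(top)
        expected = estimate_pi0_alpha(pi0_top, estimate_prob_le_alpha(top, 0.1), 0.1)
        assert far == pytest.approx(expected)

    def test_constant_pvalue_pattern_gives_constant_predictions(self, rng):
        table = make_table(np.full(50, 0.5), rng.normal(size=50))
        fit = fit_null_probabilities(table, alpha=0.1, nnh=10)
        pred = predict_pi0_alpha(fit, np.linspace(-5, 5, 30))
        assert np.ptp(pred) == 0.0


class TestTableValidation:
    def test_rejects_out_of_range_pvalue_with_row_message(self):
        table = pd.DataFrame({"gene_id": ["a", "b"], "pvalue": [0.1, 1.5],
                              "covariate": [0.0, 1.0]})
        with pytest.raises(DataError, match="row 1"):
            check_test_table(table)

    def test_rejects_duplicate_gene_ids(self):
        table = pd.DataFrame({"gene_id": ["a", "a"], "pvalue": [0.1, 0.2],
                              "covariate": [0.0, 1.0]})
        with pytest.raises(DataError, match="duplicate"):
            check_test_table(table)

    def test_rejects_non_finite_covariate(self):
        table = pd.DataFrame({"gene_id": ["a", "b"], "pvalue": [0.1, 0.2],
                              "covariate": [0.0, np.inf]})
        with pytest.raises(DataError, match="covariate"):
            check_test_table(table)

    def test_rejects_missing_column_and_empty_table(self):
        with pytest.raises(DataError, match="missing"):
            check_test_table(pd.DataFrame({"gene_id": [], "pvalue": []}))
        with pytest.raises(DataError):
            check_test_table(pd.DataFrame({"gene_id": [], "pvalue": [],
                                           "covariate": []}))
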