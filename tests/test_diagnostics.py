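"""Rasch diagnostics: fit statistics, residual correlations, SEs, PSR,
baselines and the overlap probability."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

import ipoqll as q
from ipoqll.containers import GPCMParams, ResponseMatrix


class TestExpectedScoreAndVariance:
    def test_bernoulli_half(self):
        e, w = q.expected_score_and_variance(1.3, [1.3], 1.0)
        assert e == pytest.approx(0.5, abs=1e-12)
        assert w == pytest.approx(0.25, abs=1e-12)

    def test_uniform_three_categories(self):
        e, w = q.expected_score_and_variance(0.0, [0.0, 0.0], 2.0)
        assert e == pytest.approx(1.0, abs=1e-12)
        assert w == pytest.approx(2 / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        theta, alpha = rng.normal(), np.exp(rng.normal(0, 0.4))
        beta = np.sort(rng.normal(0, 1, 3))
        p = q.category_probabilities(theta, beta, alpha)
        e_ref = sum(x * p[x] for x in range(4))
        w_ref = sum((x - e_ref) ** 2 * p[x] for x in range(4))
        e, w = q.expected_score_and_variance(theta, beta, alpha)
        assert e == pytest.approx(e_ref, abs=1e-12)
        assert w == pytest.approx(w_ref, abs=1e-12)


class TestFitStatistics:
    def test_exact_fit_gives_zero(self):
        """Responses equal to the model expectation have zero mean squares."""
        # theta = 0, symmetric 3-category item: E = 1 exactly
        rm = ResponseMatrix(np.ones((10, 2), dtype=int), [3, 3])
        params = GPCMParams(np.zeros(10), [np.array([-0.5, 0.5])] * 2,
                            np.ones(2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns are flagged
            diag = q.fit_statistics(rm, [0, 1], params)
        assert np.allclose(diag.outfit, 0.0, atol=1e-12)
        assert np.allclose(diag.infit, 0.0, atol=1e-12)

    def test_constant_item_warns(self):
        rm = ResponseMatrix(np.ones((10, 2), dtype=int), [3, 3])
        params = GPCMParams(np.zeros(10), [np.array([-0.5, 0.5])] * 2,
                            np.ones(2))
        with pytest.warns(UserWarning, match="zero observed"):
            q.fit_statistics(rm, [0, 1], params)

    def test_null_distribution_near_one(self):
        """Under the generating model, outfit and infit concentrate near 1."""
        theta = q.ability_grid(301)
        beta = [q.default_thresholds(5) for _ in range(6)]
        alpha = np.ones(6)
        rm = q.sample_gpcm(theta, beta, alpha, seed=41)
        params = GPCMParams(theta, beta, alpha)
        diag = q.fit_statistics(rm, range(6), params)
        assert np.all(np.abs(diag.outfit - 1) < 0.15)
        assert np.all(np.abs(diag.infit - 1) < 0.15)

    def test_alpha_infit_rank_relation(self, inhomogeneous_survey,
                                       inhomogeneous_full_fit):
        """Low-discrimination items show high infit: strong negative rank link."""
        diag = q.fit_statistics(inhomogeneous_survey.responses, range(18),
                                inhomogeneous_full_fit.params)
        rho, _ = spearmanr(diag.alpha_hat, diag.infit)
        assert rho < -0.8

    def test_missing_cells_ignored(self, small_survey):
        rm, params = small_survey
        values = rm.values.copy()
        values[:5, 0] = -1
        rm2 = ResponseMatrix(values, rm.n_categories)
        diag = q.fit_statistics(rm2, range(4), params)
        assert np.all(np.isfinite(diag.outfit))


class TestResidualCorrelations:
    def test_duplicate_item_flagged(self, penalties):
        theta = q.ability_grid(200, -2, 2)
        rm = q.sample_gpcm(theta, [np.array([0.0])] * 2, np.ones(2), seed=3)
        dup = ResponseMatrix(np.hstack([rm.values, rm.values[:, [0]]]),
                             [2, 2, 2])
        params = GPCMParams(theta, [np.array([0.0])] * 3, np.ones(3))
        corr, mean_abs, max_abs, _ = q.residual_correlations(dup, range(3), params)
        assert corr[0, 2] == pytest.approx(1.0, abs=1e-9)
        assert max_abs > 0.3  # screening flag fires

    def test_matrix_shape_and_symmetry(self, small_survey):
        rm, params = small_survey
        corr, *_ = q.residual_correlations(rm, range(4), params)
        assert corr.shape == (4, 4)
        assert np.allclose(corr, corr.T, equal_nan=True)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_items_weakly_correlated(self):
        theta = q.ability_grid(301)
        beta = [q.default_thresholds(5) for _ in range(6)]
        rm = q.sample_gpcm(theta, beta, np.ones(6), seed=13)
        params = GPCMParams(theta, beta, np.ones(6))
        _, mean_abs, max_abs, _ = q.residual_correlations(rm, range(6), params)
        assert mean_abs < 4 / np.sqrt(301)

    def test_needs_two_items(self, small_survey):
        rm, params = small_survey
        with pytest.raises(ValueError):
            q.residual_correlations(rm, [0], params)


class TestAbilityStandardErrors:
    def test_bernoulli_information(self):
        rm = ResponseMatrix(np.array([[0], [1]]), [2])
        params = GPCMParams(np.zeros(2), [np.array([0.0])], np.ones(1))
        pers = q.ability_standard_errors(rm, [0], params)
        assert np.allclose(pers.se, 2.0, atol=1e-12)  # I = 0.25

    def test_information_additivity(self, small_survey):
        rm, params = small_survey
        single = q.ability_standard_errors(rm, range(4), params)
        doubled = ResponseMatrix(np.hstack([rm.values, rm.values]),
                                 np.concatenate([rm.n_categories] * 2))
        dparams = GPCMParams(params.theta, params.beta * 2,
                             np.concatenate([params.alpha] * 2))
        both = q.ability_standard_errors(doubled, range(8), dparams)
        assert np.allclose(both.se, single.se / np.sqrt(2), atol=1e-12)

    def test_matches_numeric_curvature(self, small_survey):
        """I_n equals minus the second derivative of the log likelihood."""
        rm, params = small_survey
        pers = q.ability_standard_errors(rm, range(4), params)
        eps = 1e-4
        for n in (0, 30, 59):
            lls = []
            for d in (-eps, 0.0, eps):
                th = params.theta.copy()
                th[n] += d
                p2 = GPCMParams(th, params.beta, params.alpha)
                lls.append(q.itemset_loglik(rm, range(4), p2))
            curv = (lls[0] - 2 * lls[1] + lls[2]) / eps ** 2
            info = 1.0 / pers.se[n] ** 2
            # for the GPCM the observed curvature in theta is exactly the
            # expected information sum alpha^2 W
            assert info == pytest.approx(-curv, rel=1e-3, abs=1e-4)


class TestPersonSeparationReliability:
    def test_zero_se_gives_one(self):
        theta = np.array([-1.0, 0.0, 2.0])
        assert q.person_separation_reliability(theta, np.zeros(3)) == 1.0

    def test_arithmetic(self):
        theta = np.array([-1.0, 1.0])  # ddof=1 variance = 2 -> scale to 1
        theta = theta / np.sqrt(2)
        se = np.full(2, 0.5)
        assert q.person_separation_reliability(theta, se) == pytest.approx(0.75)

    def test_clipped_at_zero_with_warning(self):
        theta = np.array([0.0, 0.1])
        with pytest.warns(UserWarning, match="clipped"):
            psr = q.person_separation_reliability(theta, np.ones(2))
        assert psr == 0.0

    def test_translation_invariance(self, rng):
        theta = rng.normal(0, 1, 50)
        se = rng.uniform(0.2, 0.5, 50)
        a = q.person_separation_reliability(theta, se)
        b = q.person_separation_reliability(theta + 3.7, se)
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            q.person_separation_reliability(np.zeros(3), np.ones(3))


class TestRandomInstrumentBaseline:
    def test_seeded_reproducibility_and_shape(self, small_survey, penalties):
        rm, _ = small_survey
        a = q.random_instrument_baseline(rm, size=2, n_draws=3,
                                         penalties=penalties, seed=5)
        b = q.random_instrument_baseline(rm, size=2, n_draws=3,
                                         penalties=penalties, seed=5)
        assert len(a) == 3
        assert a.equals(b)
        assert set(a.columns) == {"mean_outfit", "mean_infit",
                                  "mean_abs_residual_corr", "psr", "ipoq_ll"}

    def test_best_itemset_reaches_top_percentile(self, small_survey, penalties):
        rm, _ = small_survey
        best, _ = q.exhaustive_search(rm, penalties, size=2)
        stats = q.random_instrument_baseline(rm, size=2, n_draws=6,
                                             penalties=penalties, seed=2,
                                             reference=best)
        assert stats.attrs["reference_percentile"]["ipoq_ll"] == 100.0

    def test_size_bounds(self, small_survey, penalties):
        rm, _ = small_survey
        with pytest.raises(ValueError):
            q.random_instrument_baseline(rm, size=4, n_draws=1,
                                         penalties=penalties)


class TestOverlapTailProbability:
    def test_zero_overlap_is_certain(self):
        assert q.overlap_tail_probability(10, 4, 5, 0) == 1.0

    def test_small_pool_enumeration(self):
        # pool {1..4}, A = {1,2}; of the 6 possible B's exactly one equals A
        assert q.overlap_tail_probability(4, 2, 2, 2) == pytest.approx(1 / 6)

    @pytest.mark.parametrize("pool,a,b,k", [(8, 3, 4, 2), (10, 5, 5, 3),
                                            (6, 2, 3, 1)])
    def test_matches_direct_enumeration(self, pool, a, b, k):
        subset_a = set(range(a))
        hits = total = 0
        for combo in itertools.combinations(range(pool), b):
            total += 1
            hits += len(subset_a & set(combo)) >= k
        assert q.overlap_tail_probability(pool, a, b, k) == \
            pytest.approx(hits / total, abs=1e-12)

    def test_instrument_overlap_is_rare(self):
        assert q.overlap_tail_probability(36, 17, 17, 14) < 1e-4

    def test_infeasible_arguments(self):
        with pytest.raises(ValueError):
            q.overlap_tail_probability(10, 5, 5, 6)
        with pytest.raises(ValueError):
            q.overlap_tail_probability(4, 5, 2, 1)
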