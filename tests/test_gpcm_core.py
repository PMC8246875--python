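"""Probability model, itemset likelihood, penalized objective, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import ipoqll as q
from ipoqll.containers import GPCMParams, ResponseMatrix


def _random_instance(seed, n=5, p=3, m=2):
    rng = np.random.default_rng(seed)
    vals = rng.integers(0, m + 1, (n, p))
    vals[0, 1] = -1  # one missing cell
    rm = ResponseMatrix(vals, [m + 1] * p)
    params = GPCMParams(rng.normal(0, 1, n),
                        [np.sort(rng.normal(0, 1, m)) for _ in range(p)],
                        np.exp(rng.normal(0, 0.3, p)))
    return rm, params


class TestCategoryProbabilities:
    @pytest.mark.parametrize("theta,beta,alpha,expected", [
        (0.0, [0.0], 1.0, [0.5, 0.5]),
        (0.0, [0.0, 0.0], 7.3, [1 / 3, 1 / 3, 1 / 3]),
    ])
    def test_symmetric_cases(self, theta, beta, alpha, expected):
        p = q.category_probabilities(theta, beta, alpha)
        assert np.allclose(p, expected, atol=1e-12)

    def test_logistic_value(self):
        # P(X=1 | theta=1, beta=0, alpha=1) = 1 / (1 + e^-1)
        p = q.category_probabilities(1.0, [0.0], 1.0)
        assert p[1] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-9)
        assert p[1] == pytest.approx(0.731059, abs=1e-6)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(theta=st.floats(-6, 6), alpha=st.floats(0.01, 10),
           beta=st.lists(st.floats(-4, 4), min_size=1, max_size=4))
    def test_normalization_and_positivity(self, theta, alpha, beta):
        p = q.category_probabilities(theta, beta, alpha)
        assert p.shape == (len(beta) + 1,)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p > 0)

    def test_dichotomous_rasch_closed_form(self):
        thetas = np.linspace(-5, 5, 21)
        for beta in (-1.0, 0.0, 2.5):
            for th in thetas:
                p = q.category_probabilities(th, [beta], 1.0)
                assert abs(p[1] - expit(th - beta)) < 1e-12

    def test_top_category_monotone_in_theta(self):
        thetas = np.linspace(-4, 4, 41)
        probs = [q.category_probabilities(t, [-0.5, 0.5], 1.7)[-1] for t in thetas]
        assert np.all(np.diff(probs) > 0)

    def test_overflow_stability(self):
        p = q.category_probabilities(30.0, [-20.0, 20.0], 50.0)
        assert np.all(np.isfinite(p)) and abs(p.sum() - 1) < 1e-12

    @pytest.mark.parametrize("theta,beta,alpha", [
        (np.inf, [0.0], 1.0), (0.0, [np.nan], 1.0), (0.0, [0.0], -1.0),
        (0.0, [0.0], 0.0),
    ])
    def test_invalid_parameters_rejected(self, theta, beta, alpha):
        with pytest.raises(ValueError):
            q.category_probabilities(theta, beta, alpha)


class TestItemsetLoglik:
    def test_single_cell_closed_form(self):
        rm = ResponseMatrix(np.array([[1]]), [2])
        params = GPCMParams([0.0], [np.array([0.0])], [1.0])
        assert q.itemset_loglik(rm, [0], params) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_empty_itemset_is_zero(self):
        rm, params = _random_instance(0)
        assert q.itemset_loglik(rm, [], params) == 0.0

    def test_matches_cellwise_oracle(self):
        rm, params = _random_instance(42, n=3, p=2)
        total = 0.0
        for i in range(2):
            for n in range(3):
                x = rm.values[n, i]
                if x < 0:
                    continue
                pvec = q.category_probabilities(params.theta[n], params.beta[i],
                                                params.alpha[i])
                total += np.log(pvec[x])
        assert q.itemset_loglik(rm, [0, 1], params) == pytest.approx(total, abs=1e-9)

    def test_out_of_range_itemset(self):
        rm, params = _random_instance(0)
        with pytest.raises(IndexError):
            q.itemset_loglik(rm, [0, 5], params)


class TestPenalizedObjective:
    def test_penalties_vanish_at_neutral_parameters(self):
        rm, params = _random_instance(1)
        neutral = GPCMParams(np.zeros(rm.n_subjects), params.beta,
                             np.ones(rm.n_items))
        items = list(range(rm.n_items))
        assert q.penalized_objective(rm, items, neutral, 0.05, 50.0) == \
            pytest.approx(q.itemset_loglik(rm, items, neutral), abs=1e-12)

    def test_theta_penalty_arithmetic(self):
        rm = ResponseMatrix(np.array([[1], [0]]), [2])
        params = GPCMParams([1.0, -1.0], [np.array([0.0])], [1.0])
        l_s = q.itemset_loglik(rm, [0], params)
        f_s = q.penalized_objective(rm, [0], params, 0.05, 1.0)
        assert f_s == pytest.approx(l_s - 0.1, abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_independent_penalty_recomputation(self, seed):
        rm, params = _random_instance(seed)
        items = [0, 2]
        lt, la = 0.11, 2.7
        expected = (q.itemset_loglik(rm, items, params)
                    - lt * np.sum(params.theta ** 2)
                    - la * np.sum(np.log(params.alpha[items]) ** 2))
        assert q.penalized_objective(rm, items, params, lt, la) == \
            pytest.approx(expected, abs=1e-10)

    def test_penalize_theta_flag(self):
        rm, params = _random_instance(6)
        items = [0, 1, 2]
        without = q.penalized_objective(rm, items, params, 0.5, 1.0,
                                        penalize_theta=False)
        with_pen = q.penalized_objective(rm, items, params, 0.5, 1.0)
        assert without - with_pen == pytest.approx(0.5 * np.sum(params.theta ** 2))


class TestObjectiveGradient:
    @pytest.mark.parametrize("seed", [3, 9, 21])
    def test_finite_difference_agreement(self, seed):
        rm, params = _random_instance(seed)
        items = list(range(rm.n_items))
        lt, la = 0.05, 2.0
        g = q.objective_gradient(rm, items, params, lt, la)
        eps = 1e-6

        def obj(p):
            return q.penalized_objective(rm, items, p, lt, la)

        for n in range(rm.n_subjects):
            t1, t2 = params.theta.copy(), params.theta.copy()
            t1[n] += eps
            t2[n] -= eps
            fd = (obj(GPCMParams(t1, params.beta, params.alpha))
                  - obj(GPCMParams(t2, params.beta, params.alpha))) / (2 * eps)
            assert abs(fd - g["theta"][n]) < 1e-5
        for i in range(rm.n_items):
            for j in range(len(params.beta[i])):
                b1 = [b.copy() for b in params.beta]
                b2 = [b.copy() for b in params.beta]
                b1[i][j] += eps
                b2[i][j] -= eps
                fd = (obj(GPCMParams(params.theta, b1, params.alpha))
                      - obj(GPCMParams(params.theta, b2, params.alpha))) / (2 * eps)
                assert abs(fd - g["beta"][i][j]) < 1e-5
            e1 = np.log(params.alpha).copy()
            e2 = e1.copy()
            e1[i] += eps
            e2[i] -= eps
            fd = (obj(GPCMParams(params.theta, params.beta, np.exp(e1)))
                  - obj(GPCMParams(params.theta, params.beta, np.exp(e2)))) / (2 * eps)
            assert abs(fd - g["log_alpha"][i]) < 1e-5

    def test_free_blocks_selectable(self):
        rm, params = _random_instance(2)
        g = q.objective_gradient(rm, [0, 1], params, 0.05, 1.0,
                                 free_blocks=("beta",))
        assert set(g) == {"beta"}

    def test_gradient_near_zero_at_optimum(self):
        theta = q.ability_grid(40, -2, 2)
        rm = q.sample_gpcm(theta, [np.array([0.0])] * 3, np.ones(3), seed=5)
        est = q.GPCM(lambda_theta=0.05, lambda_alpha=5.0, gtol=1e-7, ftol=1e-15,
                     max_iter=2000)
        est.fit(rm)
        g = q.objective_gradient(rm, range(3), est.params_(), 0.05, 5.0)
        flat = np.concatenate([g["theta"], np.concatenate(g["beta"]), g["log_alpha"]])
        assert np.max(np.abs(flat)) < 1e-5

    def test_theta_gradient_equivariant_under_subject_swap(self):
        rm, params = _random_instance(13)
        perm = np.array([2, 0, 4, 1, 3])
        rm2 = ResponseMatrix(rm.values[perm], rm.n_categories)
        params2 = GPCMParams(params.theta[perm], params.beta, params.alpha)
        g1 = q.objective_gradient(rm, [0, 1, 2], params, 0.05, 1.0)["theta"]
        g2 = q.objective_gradient(rm2, [0, 1, 2], params2, 0.05, 1.0)["theta"]
        assert np.allclose(g1[perm], g2, atol=1e-12)
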