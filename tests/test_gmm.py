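import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import mixshape as ms
from _oracles import direct_mle_loglik


def params(mu, sigma, tau):
    return ms.GMMParams(mu=np.asarray(mu, float), sigma=sigma, tau=np.asarray(tau, float))


class TestGMMParams:
    def test_rejects_descending_means(self):
        with pytest.raises(ValueError, match="ascending"):
            params([1.0, -1.0], 1.0, [0.5, 0.5])

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            params([0.0], 0.0, [1.0])

    def test_rejects_unnormalized_tau(self):
        with pytest.raises(ValueError, match="sum to 1"):
            params([-1.0, 1.0], 1.0, [0.6, 0.5])


class TestMixtureDensity:
    def test_standard_normal_mode(self):
        p = params([0.0], 1.0, [1.0])
        assert ms.mixture_density(0.0, p) == pytest.approx(1 / math.sqrt(2 * math.pi), abs=1e-12)

    def test_symmetric_two_component(self):
        p = params([-1.0, 1.0], 1.0, [0.5, 0.5])
        # 0.5 phi(1) + 0.5 phi(-1) = phi(1): the single-normal value at z=1
        single = ms.mixture_density(1.0, params([0.0], 1.0, [1.0]))
        assert ms.mixture_density(0.0, p) == pytest.approx(single, abs=1e-14)

    def test_fa_like_value_against_direct_oracle(self, fa_params):
        # frozen from an independent scipy.stats.norm evaluation
        assert ms.mixture_density(0.0, fa_params) == pytest.approx(
            0.4054361795453113, abs=1e-12
        )
        direct = 0.7488 * norm.pdf(0.0, -0.26, 0.87) + 0.2512 * norm.pdf(0.0, 0.78, 0.87)
        assert ms.mixture_density(0.0, fa_params) == pytest.approx(direct, abs=1e-14)

    def test_integrates_to_one(self, fa_params):
        val, _ = quad(lambda z: ms.mixture_density(z, fa_params), -12, 12)
        assert val == pytest.approx(1.0, abs=1e-8)


class TestESTep:
    def test_single_component_memberships_are_one(self, small_matrix):
        resp = ms.e_step(small_matrix, params([0.0], 1.0, [1.0]))
        np.testing.assert_array_equal(resp, np.ones(small_matrix.values.shape + (1,)))

    def test_symmetric_point(self):
        p = params([-1.0, 1.0], 1.0, [0.5, 0.5])
        resp = ms.e_step(np.array([[0.0, 0.0], [0.0, 0.0]]), p)
        np.testing.assert_allclose(resp, 0.5, atol=1e-15)

    def test_far_point_assigned_to_near_component(self):
        p = params([-1.0, 1.0], 1.0, [0.5, 0.5])
        resp = ms.e_step(np.full((2, 2), 10.0), p)
        # direct density ratio: phi(9)/(phi(9)+phi(11)) = 1/(1+exp(-20))
        expected = 1.0 / (1.0 + math.exp((9**2 - 11**2) / 2))
        assert resp[0, 0, 1] == pytest.approx(expected, abs=1e-12)
        assert resp[0, 0, 1] > 1 - 1e-8

    def test_extreme_values_stay_finite(self):
        p = params([-1.0, 1.0], 0.5, [0.9, 0.1])
        resp = ms.e_step(np.array([[-500.0, 500.0]] * 2), p)
        assert np.all(np.isfinite(resp))
        np.testing.assert_allclose(resp.sum(axis=2), 1.0, atol=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        z=st.floats(-50, 50),
        mu1=st.floats(-5, 0),
        gap=st.floats(0.1, 5),
        sigma=st.floats(0.05, 5),
        t1=st.floats(0.01, 0.99),
    )
    def test_memberships_sum_to_one(self, z, mu1, gap, sigma, t1):
        p = params([mu1, mu1 + gap], sigma, [t1, 1 - t1])
        resp = ms.membership(z, p)
        assert resp.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(resp >= 0)


class TestMStep:
    def test_hard_membership_closed_form(self):
        z = np.array([[-2.0, -1.0], [1.0, 2.0]])
        resp = np.zeros((2, 2, 2))
        resp[0, :, 0] = 1.0  # {-2,-1} -> component 1
        resp[1, :, 1] = 1.0  # {1, 2} -> component 2
        p = ms.m_step(z, resp)
        np.testing.assert_allclose(p.mu, [-1.5, 1.5])
        np.testing.assert_allclose(p.tau, [0.5, 0.5])
        assert p.sigma**2 == pytest.approx(0.25)  # pooled within-group MLE

    def test_total_collapse_raises(self):
        z = np.array([[1.0, 2.0], [3.0, 4.0]])
        resp = np.zeros((2, 2, 2))
        resp[:, :, 0] = 1.0
        with pytest.raises(ms.ComponentCollapseError, match="component 2"):
            ms.m_step(z, resp)

    def test_soft_memberships_match_loop_oracle(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(2, 3))
        w = rng.random((2, 3, 2))
        w /= w.sum(axis=2, keepdims=True)
        p = ms.m_step(z, w)
        # naive recomputation
        mu, nk = np.zeros(2), np.zeros(2)
        for k in range(2):
            for i in range(2):
                for j in range(3):
                    mu[k] += z[i, j] * w[i, j, k]
                    nk[k] += w[i, j, k]
        mu /= nk
        s2 = 0.0
        for k in range(2):
            for i in range(2):
                for j in range(3):
                    s2 += (z[i, j] - mu[k]) ** 2 * w[i, j, k]
        s2 /= 6.0
        order = np.argsort(mu)
        np.testing.assert_allclose(p.mu, mu[order], atol=1e-12)
        np.testing.assert_allclose(p.tau, (nk / 6.0)[order], atol=1e-12)
        assert p.sigma == pytest.approx(math.sqrt(s2), abs=1e-12)

    def test_components_reordered_ascending(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(3, 4))
        w = rng.random((3, 4, 3))
        w /= w.sum(axis=2, keepdims=True)
        p = ms.m_step(z, w)
        assert np.all(np.diff(p.mu) > 0)


class TestFitEM:
    def test_m1_closed_form(self, small_matrix):
        fit = ms.fit_em(small_matrix, 1)
        z = small_matrix.values.ravel()
        assert fit.params.mu[0] == pytest.approx(z.mean(), abs=1e-10)
        assert fit.params.sigma**2 == pytest.approx(z.var(), abs=1e-10)  # MLE (nN)
        assert fit.params.tau[0] == 1.0
        assert fit.converged

    def test_trace_nondecreasing(self, small_cohort):
        fit = ms.fit_em(small_cohort.standardized_truth, 2, max_iter=200)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8)

    def test_requires_standardized_matrix(self, small_cohort):
        with pytest.raises(ValueError, match="standardized"):
            ms.fit_em(small_cohort.raw, 2)

    def test_duplicated_data_same_params_doubled_loglik(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=60)
        z[30:] += 2.5
        fit1 = ms.fit_em(z, 2, tol=1e-12, max_iter=20000)
        fit2 = ms.fit_em(np.concatenate([z, z]), 2, tol=1e-12, max_iter=20000)
        np.testing.assert_allclose(fit2.params.mu, fit1.params.mu, atol=1e-5)
        assert fit2.params.sigma == pytest.approx(fit1.params.sigma, abs=1e-5)
        assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-7)

    def test_permutation_invariance(self, small_cohort):
        Z = small_cohort.standardized_truth
        fit1 = ms.fit_em(Z, 2)
        rng = np.random.default_rng(9)
        vals = Z.values[rng.permutation(Z.n_subjects)][:, rng.permutation(Z.n_voxels)]
        Zp = ms.SubjectVoxelMatrix(
            values=vals, subject_ids=Z.subject_ids, standardized=True
        )
        fit2 = ms.fit_em(Zp, 2)
        np.testing.assert_allclose(fit2.params.mu, fit1.params.mu, atol=1e-9)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-6)

    def test_matches_direct_optimizer_on_small_instance(self):
        rng = np.random.default_rng(12)
        z = np.where(rng.random(50) < 0.6, rng.normal(-1, 0.8, 50), rng.normal(1.2, 0.8, 50))
        fit = ms.fit_em(z, 2, tol=1e-12, max_iter=5000)
        oracle = direct_mle_loglik(z, n_starts=10, seed=0)
        assert fit.loglik >= oracle - 1e-4

    def test_m_exceeding_distinct_values_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            ms.fit_em(np.array([1.0, 1.0, 2.0, 2.0]), 3)

    def test_tau_self_consistent_with_posterior(self, small_cohort):
        """Reported global tau is the grand mean of memberships at the fit."""
        Z = small_cohort.standardized_truth
        fit = ms.fit_em(Z, 2)
        resp = ms.e_step(Z, fit.params)
        tau_from_post = resp.mean(axis=1).mean(axis=0)
        np.testing.assert_array_equal(tau_from_post, fit.params.tau)


class TestAIC:
    def test_arithmetic(self):
        p1 = params([0.0], 1.0, [1.0])
        f = ms.FitResult(p1, -100.0, [-100.0], 1, True, aic=0.0, n_params=2)
        assert ms.aic(f) == 204.0
        p2 = params([-1.0, 1.0], 1.0, [0.5, 0.5])
        f2 = ms.FitResult(p2, -100.0, [-100.0], 1, True, aic=0.0, n_params=4)
        assert ms.aic(f2) == 208.0

    def test_nested_fit_preference_needs_loglik_gain_over_two(self):
        rng = np.random.default_rng(21)
        z = rng.normal(size=400)
        f1 = ms.fit_em(z, 1)
        f2 = ms.fit_em(z, 2)
        assert (f2.aic < f1.aic) == (f2.loglik - f1.loglik > 2.0)


class TestSelectM:
    def test_single_candidate(self, small_matrix):
        fit, table = ms.select_m(small_matrix, [2], restarts=2, seed=0)
        assert fit.params.m == 2
        assert len(table) == 1
        assert bool(table["selected"].iloc[0])

    def test_table_columns_and_selection_flag(self, small_cohort):
        fit, table = ms.select_m(
            small_cohort.standardized_truth, [1, 2], restarts=1, seed=0
        )
        assert list(table.columns) == ["m", "loglik", "d", "aic", "selected"]
        sel = table.loc[table["selected"], "m"].iloc[0]
        assert sel == fit.params.m
        assert table["aic"].min() == pytest.approx(fit.aic)

    def test_separated_mixture_prefers_m2(self):
        rng = np.random.default_rng(30)
        z = np.concatenate([rng.normal(-3, 1, 1500), rng.normal(3, 1, 1500)])
        fit, _ = ms.select_m(z, [1, 2, 3], restarts=2, seed=0)
        assert fit.params.m == 2

    def test_empty_candidates_error(self, small_matrix):
        with pytest.raises(ValueError, match="non-empty"):
            ms.select_m(small_matrix, [])
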