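"""Likelihood, priors, Gibbs conditionals, relabeling and diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import critmix as cm
from critmix.model import PosteriorSamples, _z_log_weights


def matrix_from_array(x, category="C"):
    x = np.asarray(x, dtype=float)
    idx = pd.DataFrame({
        "entry_id": [f"e{k}" for k in range(x.shape[0])],
        "participant": [f"e{k}" for k in range(x.shape[0])],
        "session": 1, "provenance": "new",
    })
    return cm.MergedMatrix(category_id=category, items=[f"i{k}" for k in range(x.shape[1])],
                           x=x, entry_index=idx)


class TestResponseProbability:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 2.0, 10.0, 100.0])
    def test_half_at_point_of_subjective_equality(self, alpha):
        """p = .50 exactly when the item scale equals the threshold."""
        for v in (-3.0, 0.0, 1.7):
            assert cm.response_probability(v, v, alpha) == 0.5

    def test_matches_logistic_closed_form(self):
        assert cm.response_probability(1.0, 0.0, 1.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0)), abs=1e-15)

    @given(beta=st.floats(-3, 3), theta=st.floats(-3, 3),
           alpha=st.floats(0.01, 5))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_range(self, beta, theta, alpha):
        """p(d) + p(-d) = 1 and p stays inside (0, 1)."""
        p = cm.response_probability(beta, theta, alpha)
        q = cm.response_probability(theta, beta, alpha)
        assert 0.0 < p < 1.0
        assert p + q == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_scale_and_threshold(self):
        b = np.linspace(-3, 3, 50)
        p = cm.response_probability(b, 0.0, 1.5)
        assert (np.diff(p) > 0).all()
        p2 = cm.response_probability(0.0, b, 1.5)
        assert (np.diff(p2) < 0).all()

    def test_asymptotes(self):
        assert cm.response_probability(50.0, 0.0, 2.0) == pytest.approx(1.0)
        assert cm.response_probability(-50.0, 0.0, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            cm.response_probability(0.0, 0.0, 0.0)


class TestCompleteLoglik:
    def test_empty_matrix_gives_zero(self):
        params = cm.ModelParameters(pi=[0.5, 0.5], z=[], beta=np.zeros((2, 0)),
                                    theta=[], mu=[0, 0], alpha=[1, 1])
        m = matrix_from_array(np.empty((0, 0)))
        assert cm.complete_loglik(params, m) == 0.0

    def test_equality_point_forces_log_half(self):
        params = cm.ModelParameters(pi=[0.5, 0.5], z=[0], beta=[[0.3], [9.0]],
                                    theta=[0.3], mu=[0, 0], alpha=[2, 2])
        m = matrix_from_array([[1.0]])
        assert cm.complete_loglik(params, m) == pytest.approx(np.log(0.5))

    def test_missing_cells_contribute_nothing(self, fixed_params):
        m_all = matrix_from_array([[1.0, np.nan], [np.nan, 0.0]])
        m_obs = matrix_from_array([[1.0, np.nan], [np.nan, np.nan]])
        diff = cm.complete_loglik(fixed_params, m_all) - cm.complete_loglik(
            fixed_params, m_obs)
        # removing the observed (2,2) cell changes the sum by exactly its term
        p = cm.response_probability(fixed_params.beta[1, 1],
                                    fixed_params.theta[1],
                                    fixed_params.alpha[1])
        assert diff == pytest.approx(np.log(1 - p))

    def test_dimension_mismatch_rejected(self, fixed_params):
        with pytest.raises(ValueError):
            cm.complete_loglik(fixed_params, matrix_from_array(np.zeros((3, 2))))

    def test_probabilities_of_all_outcomes_sum_to_one(self, fixed_params):
        """Brute-force normalization over all 2^4 response matrices."""
        total = 0.0
        for bits in itertools.product([0.0, 1.0], repeat=4):
            x = np.array(bits).reshape(2, 2)
            total += np.exp(cm.complete_loglik(fixed_params, matrix_from_array(x)))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestLogPrior:
    def test_matches_term_by_term_oracle(self, fixed_params):
        p = fixed_params
        expected = (
            stats.dirichlet.logpdf(p.pi, [1.0, 1.0])          # log((G-1)!) = 0 here
            + stats.norm.logpdf(p.beta).sum()
            + stats.norm.logpdf(p.mu).sum()
            + stats.halfnorm.logpdf(p.alpha).sum()
            + stats.norm.logpdf(p.theta[0], loc=p.mu[0])
            + stats.norm.logpdf(p.theta[1], loc=p.mu[1])
            + np.log(p.pi[0]) + np.log(p.pi[1])
        )
        assert cm.log_prior(p) == pytest.approx(expected, abs=1e-12)

    def test_uniform_dirichlet_term_is_zero_for_two_groups(self):
        # density of Dirichlet(1,1) is (G-1)! = 1 everywhere on the simplex
        assert stats.dirichlet.logpdf([0.3, 0.7], [1, 1]) == pytest.approx(0.0)

    def test_negative_alpha_outside_support(self):
        with pytest.raises(ValueError):
            cm.ModelParameters(pi=[0.5, 0.5], z=[0], beta=[[0.0], [0.0]],
                               theta=[0.0], mu=[0, 0], alpha=[-0.1, 1.0])

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            cm.ModelParameters(pi=[0.5, 0.6], z=[0], beta=[[0.0], [0.0]],
                               theta=[0.0], mu=[0, 0], alpha=[1, 1])


class TestLabelPermutationInvariance:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_joint_density_invariant_under_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        G, P, I = 3, 4, 3
        pi = rng.dirichlet(np.ones(G))
        params = cm.ModelParameters(
            pi=pi, z=rng.integers(0, G, P), beta=rng.normal(size=(G, I)),
            theta=rng.normal(size=P), mu=rng.normal(size=G),
            alpha=np.abs(rng.normal(size=G)) + 0.1)
        x = rng.integers(0, 2, size=(P, I)).astype(float)
        x[rng.random((P, I)) < 0.2] = np.nan
        m = matrix_from_array(x)
        perm = rng.permutation(G)
        permuted = params.permute_groups(perm)
        before = cm.complete_loglik(params, m) + cm.log_prior(params)
        after = cm.complete_loglik(permuted, m) + cm.log_prior(permuted)
        assert after == pytest.approx(before, rel=1e-12)


class TestGibbsConditionalForZ:
    def test_agrees_with_brute_force_enumeration(self, fixed_params):
        """The categorical z-conditional matches exhaustive joint evaluation."""
        m = matrix_from_array([[1.0, 0.0], [0.0, np.nan]])
        logw = _z_log_weights(m.x, fixed_params.beta, fixed_params.theta,
                              fixed_params.mu, fixed_params.alpha,
                              np.log(fixed_params.pi))
        for p_idx in range(2):
            joint = []
            for g in (0, 1):
                z = fixed_params.z.copy()
                z[p_idx] = g
                trial = cm.ModelParameters(
                    pi=fixed_params.pi, z=z, beta=fixed_params.beta,
                    theta=fixed_params.theta, mu=fixed_params.mu,
                    alpha=fixed_params.alpha)
                joint.append(cm.complete_loglik(trial, m) + cm.log_prior(trial))
            joint = np.array(joint)
            expected = np.exp(joint - joint.max())
            expected /= expected.sum()
            got = np.exp(logw[p_idx] - logw[p_idx].max())
            got /= got.sum()
            np.testing.assert_allclose(got, expected, atol=1e-10)


class TestFitMcmc:
    def test_same_seed_reproduces_draws_exactly(self, small_study):
        cfg, study = small_study
        m = cm.merge_sessions(study.truth.table, None, cfg.category_id)
        a = cm.fit_mcmc(m, n_chains=2, n_iter=120, n_burnin=60, seed=3)
        b = cm.fit_mcmc(m, n_chains=2, n_iter=120, n_burnin=60, seed=3)
        for name in ("pi", "z", "beta", "theta", "mu", "alpha"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_no_data_posterior_matches_prior_moments(self):
        """With every cell missing the sampler must reproduce the prior."""
        m = matrix_from_array(np.full((6, 6), np.nan))
        s = cm.fit_mcmc(m, n_chains=2, n_iter=1500, n_burnin=500, seed=11)
        assert abs(s.beta.mean()) < 0.2
        assert abs(s.mu.mean()) < 0.25
        assert s.alpha.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.2)

    def test_degenerate_inputs_rejected(self, small_study):
        cfg, study = small_study
        m = cm.merge_sessions(study.truth.table, None, cfg.category_id)
        with pytest.raises(ValueError):
            cm.fit_mcmc(m, G=1)
        with pytest.raises(ValueError):
            cm.fit_mcmc(m, n_iter=100, n_burnin=100)
        with pytest.raises(ValueError):
            cm.fit_mcmc(matrix_from_array(np.zeros((1, 5))))

    def test_recovery_sanity_small_scale(self, small_fit):
        """Posterior means track the simulation truth on a small study."""
        study, model, res = small_fit
        truth = study.entry_groups(model.matrix.entry_index)
        a = res.assign_groups()
        acc = max((a.modal_group == truth).mean(),
                  ((1 - a.modal_group) == truth).mean())
        assert acc >= 0.8


def make_samples(beta, mu, z, n_chains=2, relabeled=False):
    """Constant-per-draw synthetic samples with consistent shapes."""
    C = n_chains
    D, G, I = beta.shape[0] // C, beta.shape[1], beta.shape[2]
    P = z.shape[1]
    return PosteriorSamples(
        pi=np.full((C, D, G), 1.0 / G), z=z.reshape(C, D, P).astype(np.int8),
        beta=beta.reshape(C, D, G, I),
        theta=np.zeros((C, D, P)), mu=mu.reshape(C, D, G),
        alpha=np.ones((C, D, G)), n_chains=C, n_iter=2 * D, n_burnin=D,
        seed=0, relabeled=relabeled)


class TestRelabel:
    def _switched_samples(self):
        rng = np.random.default_rng(0)
        D, P = 40, 6
        base_beta = np.stack([np.linspace(-2, 2, 8), np.linspace(2, -2, 8)])
        base_mu = np.array([-1.0, 1.0])
        base_z = np.tile(np.array([0, 0, 0, 1, 1, 1]), (2 * D, 1))
        beta = np.tile(base_beta, (2 * D, 1, 1)) + 0.05 * rng.normal(
            size=(2 * D, 2, 8))
        mu = np.tile(base_mu, (2 * D, 1)) + 0.05 * rng.normal(size=(2 * D, 2))
        z = base_z.copy()
        flip = rng.random(2 * D) < 0.5       # permute half the draws
        beta[flip] = beta[flip][:, ::-1]
        mu[flip] = mu[flip][:, ::-1]
        z[flip] = 1 - z[flip]
        return make_samples(beta, mu, z)

    def test_restores_single_labeling(self):
        s = self._switched_samples()
        r = cm.relabel(s)
        flat = r.beta.reshape(-1, 2, 8)
        ref = flat[0, 0]
        for d in range(flat.shape[0]):
            c = np.corrcoef(ref, flat[d, 0])[0, 1]
            assert c > 0.99
        # z flips must track the beta permutation
        assert (r.z.reshape(-1, 6) == np.array([0, 0, 0, 1, 1, 1])).all()

    def test_loglik_of_each_draw_unchanged(self):
        s = self._switched_samples()
        r = cm.relabel(s)
        x = np.array([[1, 0, 1, 0, 1, 0, 1, 0]] * 6, dtype=float)
        m = matrix_from_array(x)
        for c in range(s.n_chains):
            for d in (0, 5, 19):
                assert cm.complete_loglik(r.draw(c, d), m) == pytest.approx(
                    cm.complete_loglik(s.draw(c, d), m), rel=1e-12)

    def test_idempotent(self):
        s = self._switched_samples()
        once = cm.relabel(s)
        twice = cm.relabel(once)
        for name in ("pi", "z", "beta", "theta", "mu", "alpha"):
            np.testing.assert_array_equal(getattr(once, name), getattr(twice, name))

    def test_identical_beta_rows_tie_broken_by_mu_order(self):
        D = 10
        beta = np.tile(np.ones((2, 4)), (2 * D, 1, 1))
        mu = np.tile(np.array([1.0, -1.0]), (2 * D, 1))   # deliberately reversed
        z = np.zeros((2 * D, 3), dtype=int)
        s = make_samples(beta, mu, z)
        r = cm.relabel(s)
        assert (np.diff(r.mu, axis=-1) >= 0).all()


class TestDiagnostics:
    def _iid_samples(self, shift=0.0, constant=False):
        rng = np.random.default_rng(1)
        C, D, G, P, I = 2, 1000, 2, 3, 2
        def draw(shape):
            if constant:
                return np.ones(shape)
            return rng.normal(size=shape)
        s = PosteriorSamples(
            pi=np.full((C, D, G), 0.5), z=np.zeros((C, D, P), dtype=np.int8),
            beta=draw((C, D, G, I)), theta=draw((C, D, P)),
            mu=draw((C, D, G)) + np.array([0.0, shift])[:, None, None][:C],
            alpha=np.abs(draw((C, D, G))) + 0.01,
            n_chains=C, n_iter=2 * D, n_burnin=D, seed=0, relabeled=True)
        return s

    def test_iid_chains_have_rhat_near_one(self):
        diag = cm.convergence_diagnostics(self._iid_samples())
        mu_rows = diag.loc[[f"mu[{k}]" for k in range(2)]]
        beta_rows = diag.loc[[f"beta[{k}]" for k in range(4)]]
        for r in np.concatenate([mu_rows["rhat"], beta_rows["rhat"]]):
            assert 0.99 <= r <= 1.02

    def test_disjoint_chains_flagged(self):
        diag = cm.convergence_diagnostics(self._iid_samples(shift=10.0))
        assert (diag.loc[["mu[1]"], "rhat"] > 1.5).all()

    def test_constant_chains_marked_degenerate(self):
        diag = cm.convergence_diagnostics(self._iid_samples(constant=True))
        assert diag["degenerate"].all()
        assert diag["rhat"].isna().all()

    def test_single_chain_rejected(self):
        s = self._iid_samples()
        single = PosteriorSamples(
            pi=s.pi[:1], z=s.z[:1], beta=s.beta[:1], theta=s.theta[:1],
            mu=s.mu[:1], alpha=s.alpha[:1], n_chains=1, n_iter=s.n_iter,
            n_burnin=s.n_burnin, seed=0, relabeled=True)
        with pytest.raises(ValueError, match="2 chains"):
            cm.convergence_diagnostics(single)


class TestAssignGroups:
    def _samples_with_z(self, z_draws):
        z = np.asarray(z_draws, dtype=np.int8)[None, :, :]  # one chain
        z = np.concatenate([z, z])                           # two chains
        C, D, P = z.shape
        return PosteriorSamples(
            pi=np.full((C, D, 2), 0.5), z=z, beta=np.zeros((C, D, 2, 2)),
            theta=np.zeros((C, D, P)), mu=np.zeros((C, D, 2)),
            alpha=np.ones((C, D, 2)), n_chains=C, n_iter=2 * D, n_burnin=D,
            seed=0, relabeled=True)

    def test_unanimous_entry(self):
        a = cm.assign_groups(self._samples_with_z([[0], [0], [0], [0]]))
        assert a.modal_group[0] == 0
        np.testing.assert_allclose(a.prob[0], [1.0, 0.0])
        assert not a.tie_flag[0]

    def test_exact_tie_flagged_and_broken_low(self):
        a = cm.assign_groups(self._samples_with_z([[0], [1], [0], [1]]))
        assert a.tie_flag[0]
        assert a.modal_group[0] == 0
        np.testing.assert_allclose(a.prob[0], [0.5, 0.5])

    def test_unrelabeled_samples_rejected(self):
        s = self._samples_with_z([[0], [0]])
        s.relabeled = False
        with pytest.raises(ValueError, match="relabel"):
            cm.assign_groups(s)
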