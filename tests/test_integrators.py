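"""Euler-Maruyama stepping, stochastic gradients, seeding contract."""

import numpy as np
import pytest

from irrlangevin import (InvalidInputError, PerturbationSpec, SamplerConfig,
                         build_skew, derive_chain_seed, drift_diffusion,
                         em_stationary_law, em_step, gaussian_posterior,
                         run_chain, run_ensemble, stochastic_gradient)
from irrlangevin.integrators import draw_minibatch_indices, simulate_ensemble

PHI = {"phi1": lambda s: s.sum(axis=-1),
       "phi2": lambda s: np.square(s).sum(axis=-1)}


@pytest.fixture(scope="module")
def gauss1d():
    # unit posterior precision around a nonzero mean
    return gaussian_posterior([[0.5]], [[0.5]], [[2.0]]).make_target()


class TestEmStep:
    def test_zero_noise_is_deterministic_drift_step(self, gauss1d):
        dd = drift_diffusion("ld", gauss1d, PerturbationSpec("ld"))
        theta = np.array([3.0])
        out = em_step(theta, dd, 0.1, np.zeros(1))
        assert np.allclose(out, theta + 0.1 * dd.drift(theta))

    def test_matches_closed_linear_recurrence(self, gaussian3_spec):
        """The generic stepper on the Gaussian target reproduces the exact
        linear recurrence theta' = (I - A h) theta + D h + sqrt(h) xi."""
        target = gaussian3_spec.make_target()
        dd = drift_diffusion("ld", target, PerturbationSpec("ld"))
        h = 0.01
        rng = np.random.default_rng(5)
        theta = rng.normal(size=3)
        for _ in range(20):
            xi = rng.normal(size=3)
            expected = ((np.eye(3) - gaussian3_spec.drift_matrix * h) @ theta
                        + gaussian3_spec.drift_offset * h + np.sqrt(h) * xi)
            theta_new = em_step(theta, dd, h, xi)
            assert np.allclose(theta_new, expected)
            theta = theta_new

    def test_increment_covariance(self, normal30_target):
        """Cov(theta' - theta - h b) = 2 beta h B(theta) empirically."""
        dd = drift_diffusion("rm", normal30_target, PerturbationSpec("rm"))
        theta = np.array([1.0, 9.0])
        h, n = 0.01, 10**5
        rng = np.random.default_rng(0)
        states = np.broadcast_to(theta, (n, 2))
        b, sigma = dd.evaluate(np.array(states), None)
        noise = rng.standard_normal((n, 2))
        incr = h * b + np.sqrt(h) * np.einsum("mij,mj->mi", sigma, noise)
        resid = incr - h * b
        cov = resid.T @ resid / n
        expected = 2 * 0.5 * h * normal30_target.metric(theta)
        assert np.allclose(cov, expected, rtol=0.05, atol=5e-4)


class TestStochasticGradient:
    def test_full_batch_equals_exact_gradient(self, normal30_target):
        g = stochastic_gradient(normal30_target, [1.0, 8.0], n=30, rng=0)
        assert np.allclose(g, normal30_target.grad_log_density([1.0, 8.0]))

    def test_forced_index_scaling(self, normal30_target):
        """n = 1 of N: gradient is prior + N * that datum's term."""
        state = np.array([0.5, 7.0])
        expected = (normal30_target.prior_grad(state)
                    + 30 * normal30_target.datum_grad(state, 2))
        got = normal30_target.minibatch_grad(state, np.array([2]))
        assert np.allclose(got, expected)

    def test_unbiasedness(self, normal30_target):
        """Mean of the stochastic gradient over draws matches the full
        gradient within 4 standard errors, componentwise."""
        state = np.array([2.0, 12.0])
        n_draws = 10**5
        rng = np.random.default_rng(9)
        idx = draw_minibatch_indices(rng, n_draws, 30, 6)
        states = np.broadcast_to(state, (n_draws, 2))
        grads = normal30_target.minibatch_grad(np.array(states), idx)
        full = normal30_target.grad_log_density(state)
        se = grads.std(axis=0, ddof=1) / np.sqrt(n_draws)
        assert np.all(np.abs(grads.mean(axis=0) - full) < 4 * se + 1e-12)

    def test_invalid_sizes(self, normal30_target):
        with pytest.raises(InvalidInputError):
            stochastic_gradient(normal30_target, [0.0, 1.0], n=31, rng=0)
        with pytest.raises(InvalidInputError):
            draw_minibatch_indices(np.random.default_rng(0), 1, 10, 0)

    def test_without_replacement_indices_distinct(self):
        idx = draw_minibatch_indices(np.random.default_rng(1), 200, 30, 6)
        assert all(len(set(row)) == 6 for row in idx)


class TestRunChain:
    def test_zero_steps_holds_only_initial_state(self, gauss1d):
        cfg = SamplerConfig(step_size=0.1, n_steps=0, initial_state=[1.5])
        res = run_chain(gauss1d, PerturbationSpec("ld"), cfg, PHI)
        assert res.states.shape == (1, 1)
        assert np.allclose(res.states[0], [1.5])
        assert res.observable_values["phi1"].size == 0

    def test_same_seed_reproduces_bitwise(self, normal30_target):
        cfg = SamplerConfig(step_size=1e-3, n_steps=500, seed=42,
                            initial_state=[5.0, 20.0], minibatch_size=6)
        pert = PerturbationSpec("giirr",
                               skew=build_skew("dense_upper_ones", 2, 2.0))
        a = run_chain(normal30_target, pert, cfg, PHI)
        b = run_chain(normal30_target, pert, cfg, PHI)
        assert np.array_equal(a.states, b.states)
        assert a.config_digest == b.config_digest

    def test_minibatching_does_not_perturb_noise_stream(self, normal30_target):
        """Separate substreams: turning SG on keeps the same noise draws,
        so the full-data chain and the SG chain agree at step one when the
        gradient happens to be identical (n = N)."""
        pert = PerturbationSpec("ld")
        cfg_full = SamplerConfig(step_size=1e-3, n_steps=50, seed=3,
                                 initial_state=[5.0, 20.0])
        cfg_sg = SamplerConfig(step_size=1e-3, n_steps=50, seed=3,
                               initial_state=[5.0, 20.0], minibatch_size=30)
        a = run_chain(normal30_target, pert, cfg_full, PHI)
        b = run_chain(normal30_target, pert, cfg_sg, PHI)
        assert np.array_equal(a.states, b.states)

    def test_stationary_variance_matches_discrete_oracle(self, gauss1d):
        """Long LD chain on a 1-D Gaussian: the empirical stationary
        variance matches the discrete Lyapunov solution."""
        h, k = 0.01, 2 * 10**5
        cfg = SamplerConfig(step_size=h, n_steps=k, seed=0,
                            initial_state=[2.0])
        res = run_chain(gauss1d, PerturbationSpec("ld"), cfg, PHI,
                        store_states=True)
        gamma_p = 1.0  # 0.5 prior + 1 * 0.5 noise
        _, cov = em_stationary_law([[0.5 * gamma_p]], [0.0], [[1.0]], h)
        samples = res.states[k // 10:, 0]
        assert np.var(samples) == pytest.approx(cov[0, 0], rel=0.1)

    def test_domain_failure_carries_step_index(self, gauss1d):
        # |1 - h A| > 1 makes the linear recurrence explode to overflow
        from irrlangevin import NumericalDomainError
        cfg = SamplerConfig(step_size=50.0, n_steps=500, seed=0,
                            initial_state=[1.0])
        with pytest.raises(NumericalDomainError) as err:
            run_chain(gauss1d, PerturbationSpec("ld"), cfg, {})
        assert err.value.step is not None and err.value.step > 0


class TestEnsemble:
    def test_single_chain_reduces_to_run_chain(self, normal30_target):
        pert = PerturbationSpec("rm")
        cfg = SamplerConfig(step_size=1e-3, n_steps=300,
                            initial_state=[5.0, 20.0])
        ens = run_ensemble(normal30_target, pert, cfg, PHI, n_chains=1,
                           base_seed=17, store_states=True)
        solo_cfg = SamplerConfig(step_size=1e-3, n_steps=300,
                                 initial_state=[5.0, 20.0],
                                 seed=derive_chain_seed(17, 0))
        solo = run_chain(normal30_target, pert, solo_cfg, PHI)
        assert np.array_equal(ens[0].states, solo.states)
        assert np.array_equal(ens[0].observable_values["phi1"],
                              solo.observable_values["phi1"])

    def test_same_base_seed_identical_ensembles(self, normal30_target):
        pert = PerturbationSpec("ld")
        cfg = SamplerConfig(step_size=1e-3, n_steps=200,
                            initial_state=[5.0, 20.0], minibatch_size=6)
        a = run_ensemble(normal30_target, pert, cfg, PHI, n_chains=4,
                         base_seed=5)
        b = run_ensemble(normal30_target, pert, cfg, PHI, n_chains=4,
                         base_seed=5)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.observable_values["phi2"],
                                  rb.observable_values["phi2"])

    def test_nesting_smaller_ensemble_is_prefix_of_larger(self, normal30_target):
        pert = PerturbationSpec("ld")
        cfg = SamplerConfig(step_size=1e-3, n_steps=200,
                            initial_state=[5.0, 20.0])
        small = run_ensemble(normal30_target, pert, cfg, PHI, n_chains=3,
                             base_seed=5)
        large = run_ensemble(normal30_target, pert, cfg, PHI, n_chains=6,
                             base_seed=5)
        for rs, rl in zip(small, large[:3]):
            assert np.array_equal(rs.observable_values["phi1"],
                                  rl.observable_values["phi1"])

    def test_first_step_increments_uncorrelated_across_chains(self, gauss1d):
        pert = PerturbationSpec("ld")
        cfg = SamplerConfig(step_size=0.01, n_steps=2, initial_state=[0.0])
        res = run_ensemble(gauss1d, pert, cfg, PHI, n_chains=100, base_seed=0,
                           store_states=True)
        first = np.array([r.states[1, 0] - r.states[0, 0] for r in res])
        second = np.array([r.states[2, 0] - r.states[1, 0] for r in res])
        r = np.corrcoef(first, second)[0, 1]
        assert abs(r) < 0.2  # no shared noise between steps/chains

    def test_irreversibility_breaks_time_symmetry(self, gaussian3_spec):
        """Smoke test that the irreversible drift is actually present: the
        antisymmetric lag-1 cross-moment E[x1_k x2_{k+1} - x2_k x1_{k+1}]
        vanishes for the reversible sampler but not for Irr."""
        target = gaussian3_spec.make_target(metric="identity")
        j = build_skew("dense_upper_ones", 3, delta=1.0)
        h, k = 0.05, 4 * 10**4

        def lag_asym(kind, skew):
            cfg = SamplerConfig(step_size=h, n_steps=k, seed=2,
                                initial_state=gaussian3_spec.posterior_mean)
            res = run_chain(target, PerturbationSpec(kind, skew=skew), cfg,
                            {}, store_states=True)
            x = res.states[k // 10:]
            a, b = x[:-1], x[1:]
            return np.mean(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])

        sym = lag_asym("ld", None)
        asym = lag_asym("irr", j)
        assert abs(asym) > 5 * abs(sym)

    def test_linear_gaussian_chains_match_lyapunov_oracle(self, gaussian3_spec):
        """Pooled stationary moments of every kind agree with the exact
        discrete-time law (joint test of drift, diffusion and stepping)."""
        from irrlangevin.cli import linear_gaussian_stationary_law

        target = gaussian3_spec.make_target()
        j = build_skew("dense_upper_ones", 3, delta=1.0)
        # keep h small enough that the rotation-stiffened kinds (Irr/RMIrr)
        # still equilibrate quickly: spectral radius of (I - hA) well below 1
        h, k, m, burn = 0.01, 8000, 120, 3000
        for kind in ("ld", "rm", "irr", "rmirr", "giirr"):
            skew = j if kind in ("irr", "rmirr", "giirr") else None
            pert = PerturbationSpec(kind, skew=skew)
            dd = drift_diffusion(kind, target, pert)
            sc_mean, sc_cov = linear_gaussian_stationary_law(target, kind, h,
                                                             skew=skew)
            seeds = [derive_chain_seed(100 + hash(kind) % 1000, i)
                     for i in range(m)]
            from irrlangevin.integrators import StateCollector
            coll = StateCollector(thin=1)
            x0 = np.broadcast_to(sc_mean, (m, 3))
            simulate_ensemble(target, dd, x0, h, k, seeds,
                              observables={}, collectors=[coll])
            pooled = coll.states[burn:].reshape(-1, 3)
            assert np.allclose(pooled.mean(axis=0), sc_mean, atol=0.05)
            emp_cov = np.cov(pooled.T)
            assert np.allclose(emp_cov, sc_cov, rtol=0.15, atol=0.02)


class TestSamplerConfigValidation:
    def test_burn_in_must_be_smaller_than_steps(self):
        with pytest.raises(InvalidInputError):
            SamplerConfig(step_size=0.1, n_steps=10, burn_in_steps=10,
                          initial_state=[0.0])

    def test_nonpositive_step_size(self):
        with pytest.raises(InvalidInputError):
            SamplerConfig(step_size=0.0, n_steps=10, initial_state=[0.0])
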