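"""Tests for the minibatch ABC-SMC engine (cheap stub models throughout)."""

import warnings
from types import SimpleNamespace

import numpy as np
import pytest
from scipy import stats

from scratchabc import (
    ABCConfig,
    ParticlePopulation,
    PriorSpec,
    SummaryVector,
    coverage_bound,
    importance_density,
    kernel_covariance,
    kl_between_generations,
    minibatch_distance,
    run_abc_smc,
    run_generation,
)
from scratchabc.inference import _propose_batch


# --- a scalar toy observation model -----------------------------------------
#
# Each "observation" carries a covariate x and a response y = m* x + noise;
# the stub simulator responds to the proposal's m only.  This exercises the
# whole engine (proposals, minibatching, ranking, weighting) at trivial cost.

TOY_TRUTH_M = 2.0
TOY_NOISE = 0.4


def toy_dataset(n_obs, seed=0):
    g = np.random.default_rng(seed)
    obs = []
    for _ in range(n_obs):
        x = g.uniform(0.5, 1.5)
        y = TOY_TRUTH_M * x + g.normal(0, TOY_NOISE)
        obs.append(SimpleNamespace(initial=None, final=y, x=x, phi=24.0))
    return obs


def toy_summarise(value):
    return SummaryVector(1, np.array([float(value)]), np.array([1]))


def toy_simulate(theta, obs, config, seed):
    g = np.random.default_rng(seed)
    return theta[0] * obs.x + g.normal(0, TOY_NOISE)


def echo_simulate(theta, obs, config, seed):
    """Stub returning the observation's own final state (distance 0)."""
    return obs.final


class TestPrior:
    def test_draws_inside_box_and_mean(self):
        prior = PriorSpec()
        g = np.random.default_rng(0)
        draws = prior.sample(g, size=100_000)
        assert np.all(prior.contains(draws))
        se = 10 / np.sqrt(12 * len(draws))
        assert abs(draws[:, 0].mean() - 5.0) < 3 * se

    def test_density(self):
        prior = PriorSpec()
        inside = np.array([5.0, 0.02, 0.02, 0.0, 0.02, 25.0])
        outside = np.array([11.0, 0.02, 0.02, 0.0, 0.02, 25.0])
        assert prior.pdf(inside) == pytest.approx(1.0 / prior.volume)
        assert prior.pdf(outside) == 0.0

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            PriorSpec(lower=np.ones(6), upper=np.zeros(6))


def _pop(thetas, weights=None, **kw):
    thetas = np.asarray(thetas, dtype=float)
    n = len(thetas)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    return ParticlePopulation(thetas, weights, np.zeros(n), **kw)


class TestKernelCovariance:
    def test_two_particle_hand_value(self):
        delta = 0.8
        base = np.array([1.0, 0.01, 0.01, 0.5, 0.02, 10.0])
        a, b = base.copy(), base.copy()
        a[0] -= delta / 2
        b[0] += delta / 2
        cov = kernel_covariance(_pop([a, b]))
        # 2 x weighted variance = 2 * (delta/2)^2 = delta^2 / 2
        assert cov[0, 0] == pytest.approx(delta ** 2 / 2)
        assert np.all(np.linalg.eigvalsh(cov) >= 0)

    def test_permutation_and_scaling(self, rng):
        th = rng.uniform(0, 1, (20, 6))
        w = rng.dirichlet(np.ones(20))
        c1 = kernel_covariance(_pop(th, w))
        perm = rng.permutation(20)
        c2 = kernel_covariance(_pop(th[perm], w[perm]))
        np.testing.assert_allclose(c1, c2, atol=1e-14)
        c3 = kernel_covariance(_pop(3.0 * th, w))
        np.testing.assert_allclose(c3, 9.0 * c1, rtol=1e-10)

    def test_degenerate_population_warns(self):
        th = np.tile(np.array([1.0, 0.01, 0.01, 0.0, 0.02, 10.0]), (5, 1))
        with pytest.warns(UserWarning):
            cov = kernel_covariance(_pop(th))
        assert np.all(np.linalg.eigvalsh(cov) > 0)


class TestProposals:
    def test_all_proposals_in_support(self, rng):
        prior = PriorSpec()
        prev = _pop(prior.sample(rng, size=50))
        cand = _propose_batch(prev, prior, 500, rng)
        assert np.all(prior.contains(cand))

    def test_tiny_kernel_concentrates_on_parents(self, rng):
        prior = PriorSpec()
        parents = prior.sample(rng, size=5)
        prev = _pop(parents, kernel_cov=1e-18 * np.eye(6))
        cand = _propose_batch(prev, prior, 100, rng)
        dists = np.min(np.linalg.norm(
            cand[:, None, :] - parents[None, :, :], axis=2), axis=1)
        assert np.all(dists < 1e-6)


class TestImportanceDensity:
    def test_single_parent_is_mvn(self, rng):
        mu = np.array([5.0, 0.02, 0.02, 0.0, 0.02, 25.0])
        cov = np.diag([1.0, 1e-4, 1e-4, 0.25, 1e-4, 25.0])
        prev = _pop([mu], kernel_cov=cov)
        theta = mu + rng.normal(0, 0.01, 6)
        expected = stats.multivariate_normal(mu, cov).pdf(theta)
        assert importance_density(theta, prev) == pytest.approx(expected)

    def test_mixture_matches_brute_force(self, rng):
        prior = PriorSpec()
        th = prior.sample(rng, size=8)
        w = rng.dirichlet(np.ones(8))
        cov = np.diag([1.0, 1e-4, 1e-4, 0.25, 1e-4, 25.0])
        prev = _pop(th, w, kernel_cov=cov)
        pts = prior.sample(rng, size=4)
        got = importance_density(pts, prev)
        mvns = [stats.multivariate_normal(t, cov) for t in th]
        brute = np.array([sum(wj * mj.pdf(x) for wj, mj in zip(w, mvns))
                          for x in pts])
        np.testing.assert_allclose(got, brute, rtol=1e-10)


class TestMinibatchDistance:
    def test_echo_stub_gives_zero(self, rng):
        data = toy_dataset(5)
        eps = minibatch_distance(np.zeros(6), data, 3, rng,
                                 simulate=echo_simulate,
                                 summarise=toy_summarise)
        assert eps == 0.0

    def test_single_batch_is_single_distance(self, rng):
        data = toy_dataset(1, seed=3)
        theta = np.array([1.0, 0, 0, 0, 0, 0])
        eps = minibatch_distance(theta, data, 1, rng, simulate=toy_simulate,
                                 summarise=toy_summarise)
        assert eps >= 0

    def test_expectation_equals_full_data_mean(self):
        """With a frozen deterministic stub, the minibatch score is unbiased
        for the full-data mean distance."""
        data = toy_dataset(3, seed=9)

        def frozen_sim(theta, obs, config, seed):
            return 1.7  # same output regardless of observation or seed

        obs_sums = [toy_summarise(o.final) for o in data]
        full = minibatch_distance(np.zeros(6), data, 3,
                                  np.random.default_rng(0),
                                  simulate=frozen_sim,
                                  summarise=toy_summarise,
                                  obs_summaries=obs_sums, replace=False)
        g = np.random.default_rng(5)
        draws = [minibatch_distance(np.zeros(6), data, 2, g,
                                    simulate=frozen_sim,
                                    summarise=toy_summarise,
                                    obs_summaries=obs_sums)
                 for _ in range(4000)]
        # exact per-observation distances underlying the enumeration
        per_obs = np.array([(1.7 - o.final) ** 2 / o.final ** 2 for o in data])
        assert full == pytest.approx(per_obs.mean())
        assert np.mean(draws) == pytest.approx(per_obs.mean(),
                                               abs=4 * np.std(draws) / 63.2)

    def test_empty_dataset_rejected(self, rng):
        with pytest.raises(ValueError):
            minibatch_distance(np.zeros(6), [], 2, rng)


class TestRunGeneration:
    def test_acceptance_count_and_uniform_weights(self, rng):
        data = toy_dataset(4)
        cfg = ABCConfig(n_gen_samples=200, n_accept=40, n_batch=2,
                        n_generations=1)
        pop = run_generation(data, cfg, PriorSpec(), rng,
                             simulate=toy_simulate, summarise=toy_summarise)
        assert len(pop) == 40
        assert pop.weights.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(pop.weights, 1 / 40)
        assert pop.generation == 1

    def test_constant_distance_returns_prior(self):
        """An uninformative distance must leave the prior untouched."""
        data = toy_dataset(4)
        prior = PriorSpec()
        cfg = ABCConfig(n_gen_samples=2000, n_accept=500, n_batch=1,
                        n_generations=1)
        pop = run_generation(data, cfg, prior, np.random.default_rng(2),
                             simulate=echo_simulate, summarise=toy_summarise)
        # accepted marginals are iid prior draws: KS against uniform
        for k, (lo, hi) in enumerate(zip(prior.lower, prior.upper)):
            u = (pop.thetas[:, k] - lo) / (hi - lo)
            assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_constant_distance_prior_identity_holds_across_generations(self):
        """With an uninformative distance, the *weighted* marginals of every
        generation (not just the first) must match the prior — this pins the
        importance weights pi/q against the perturbation kernel."""
        data = toy_dataset(4)
        prior = PriorSpec()
        cfg = ABCConfig(n_gen_samples=1500, n_accept=300, n_batch=2,
                        n_generations=3)
        gens = run_abc_smc(data, cfg, prior, rng=5, simulate=echo_simulate,
                           summarise=toy_summarise)
        for pop in gens[1:]:
            for k, (lo, hi) in enumerate(zip(prior.lower, prior.upper)):
                u = (pop.thetas[:, k] - lo) / (hi - lo)
                for q in (0.25, 0.5, 0.75):
                    assert abs(np.sum(pop.weights[u <= q]) - q) < 0.12

    def test_later_generation_weights_positive_finite(self, rng):
        data = toy_dataset(6)
        prior = PriorSpec()
        cfg = ABCConfig(n_gen_samples=300, n_accept=60, n_batch=2,
                        n_generations=2)
        g1 = run_generation(data, cfg, prior, rng, simulate=toy_simulate,
                            summarise=toy_summarise)
        g2 = run_generation(data, cfg, prior, rng, prev=g1,
                            simulate=toy_simulate, summarise=toy_summarise)
        assert g2.generation == 2
        assert np.all(np.isfinite(g2.weights)) and np.all(g2.weights > 0)
        assert g2.weights.sum() == pytest.approx(1.0)


class TestRunAbcSmc:
    def test_single_generation_is_rejection_abc(self):
        data = toy_dataset(5)
        cfg = ABCConfig(n_gen_samples=300, n_accept=50, n_batch=2,
                        n_generations=1)
        gens = run_abc_smc(data, cfg, rng=7, simulate=toy_simulate,
                           summarise=toy_summarise)
        ref = run_generation(data, cfg, PriorSpec(), np.random.default_rng(7),
                             simulate=toy_simulate, summarise=toy_summarise)
        assert len(gens) == 1
        np.testing.assert_array_equal(gens[0].thetas, ref.thetas)

    def test_reproducible_and_contracting(self):
        data = toy_dataset(20, seed=4)
        cfg = ABCConfig(n_gen_samples=1000, n_accept=100, n_batch=5,
                        n_generations=3)
        gens_a = run_abc_smc(data, cfg, rng=11, simulate=toy_simulate,
                             summarise=toy_summarise)
        gens_b = run_abc_smc(data, cfg, rng=11, simulate=toy_simulate,
                             summarise=toy_summarise)
        np.testing.assert_array_equal(gens_a[-1].thetas, gens_b[-1].thetas)
        # the informative parameter m concentrates around the truth
        sd = [g.posterior_std()[0] for g in gens_a]
        assert sd[-1] < sd[0]
        m_hat = gens_a[-1].posterior_mean()[0]
        assert abs(m_hat - TOY_TRUTH_M) < 0.5

    def test_kl_stopping(self):
        data = toy_dataset(10, seed=4)
        cfg = ABCConfig(n_gen_samples=400, n_accept=80, n_batch=2,
                        n_generations=6, kl_tolerance=1e9)
        gens = run_abc_smc(data, cfg, rng=3, simulate=toy_simulate,
                           summarise=toy_summarise)
        assert len(gens) == 2  # absurdly loose tolerance stops immediately


class TestKLEstimator:
    def test_identical_populations(self, rng):
        th = rng.normal(0, 1, (500, 6))
        pop = _pop(th)
        assert abs(kl_between_generations(pop, pop)) < 0.02

    def test_gaussian_closed_form(self):
        g = np.random.default_rng(0)
        a = _pop(g.normal(0.0, 1.0, (600, 6)))
        b = _pop(g.normal(1.0, 1.0, (600, 6)))
        kl = kl_between_generations(a, b)
        assert kl == pytest.approx(0.5, abs=0.1)

    def test_asymmetry(self):
        g = np.random.default_rng(1)
        a = _pop(g.normal(0.0, 1.0, (500, 6)))
        b = _pop(g.normal(0.0, 3.0, (500, 6)))
        assert kl_between_generations(a, b) != pytest.approx(
            kl_between_generations(b, a), abs=1e-3)


class TestCoverageBound:
    def test_single_observation(self):
        exact, bound = coverage_bound(1, 100, 2)
        assert exact == 0.0

    def test_screen_scale_log_values(self):
        log_exact, log_bound = coverage_bound(117, 20_000, 10, log=True)
        assert log_exact <= log_bound
        assert log_bound == pytest.approx(-200_000 / 117)
        assert log_exact < -700 * np.log(10)  # far below 1e-700

    def test_exact_below_bound_on_grid(self):
        for n_obs in (2, 5, 30, 117):
            for n_gen in (10, 1000):
                for n_batch in (1, 10):
                    exact, bound = coverage_bound(n_obs, n_gen, n_batch)
                    assert exact <= bound + 1e-15


class TestConfig:
    def test_bookkeeping_identities(self):
        cfg = ABCConfig()
        assert cfg.n_gen_samples == 20_000 and cfg.n_accept == 500
        assert cfg.acceptance_rate == pytest.approx(0.025)
        assert cfg.simulation_reduction(117) == pytest.approx(11.7)

    def test_validation(self):
        with pytest.raises(ValueError):
            ABCConfig(n_gen_samples=10, n_accept=20)
        with pytest.raises(ValueError):
            ABCConfig(n_batch=0)
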