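"""Joint model: component likelihoods, kernel agreement, sampler behavior."""

import warnings

import numpy as np
import pytest
from scipy.stats import binom, poisson

from flypop import _kernel
from flypop.data import (
    CensusSeries,
    DemographicParams,
    LatentStates,
    ProductivityTable,
    ValidationError,
    build_marrays,
)
from flypop.ipm import (
    FitConfig,
    ImmigrationParams,
    PriorConfig,
    census_loglik,
    fit_ipm,
    joint_log_posterior,
    state_process_loglik,
)
from flypop.simulate import SimulationConfig, simulate_population


def tiny_states():
    return LatentStates(N1=[3, 4, 2], Nad=[10, 8, 9], Nimm=[2, 3, 1])


def tiny_params(**kw):
    defaults = dict(mu_phi_j=0.15, mu_phi_a=0.45, mu_p=0.8, mu_f=1.13,
                    sigma_phi_j=0.2, sigma_phi_a=0.2, sigma_p=0.2,
                    sigma_f=0.1)
    defaults.update(kw)
    return DemographicParams(**defaults)


class TestStateProcess:
    def test_term_by_term_against_scipy(self):
        states = tiny_states()
        params = tiny_params()
        imm = ImmigrationParams([2.0, 4.0])
        expected = 0.0
        ntot = states.Ntot
        for t in range(2):
            expected += poisson.logpmf(states.N1[t + 1],
                                       ntot[t] * 1.13 * 0.15)
            expected += binom.logpmf(states.Nad[t + 1], ntot[t], 0.45)
            expected += poisson.logpmf(states.Nimm[t + 1], imm.m[t])
        assert state_process_loglik(states, params, imm) == pytest.approx(
            expected, abs=1e-10)

    def test_more_survivors_than_parents_impossible(self):
        states = LatentStates(N1=[2, 2, 2], Nad=[3, 20, 3], Nimm=[0, 0, 0])
        assert state_process_loglik(
            states, tiny_params(), ImmigrationParams([1.0, 1.0])) == -np.inf

    def test_expected_recruitment_mean(self):
        # Ntot=20, f=1, phi_j=0.15 -> next-year recruit mean 3
        states = LatentStates(N1=[5, 3, 3], Nad=[15, 14, 14],
                              Nimm=[0, 0, 0])
        params = tiny_params(mu_f=1.0)
        imm = ImmigrationParams([0.0, 0.0])
        ll = state_process_loglik(states, params, imm)
        direct = (poisson.logpmf(3, 20 * 0.15)
                  + binom.logpmf(14, 20, 0.45)
                  + poisson.logpmf(3, 17 * 0.15)
                  + binom.logpmf(14, 17, 0.45))
        assert ll == pytest.approx(direct, abs=1e-10)


class TestCensusLoglik:
    def test_closed_form_at_mean(self):
        census = CensusSeries("x", [2000, 2001, 2002], [28, 29, 28])
        states = LatentStates(N1=[5, 5, 5], Nad=[20, 21, 20],
                              Nimm=[3, 3, 3])
        expected = sum(poisson.logpmf(k, k) for k in (28, 29, 28))
        assert census_loglik(census, states) == pytest.approx(expected,
                                                              abs=1e-10)

    def test_empty_population_cannot_produce_counts(self):
        census = CensusSeries("x", [2000, 2001, 2002], [1, 0, 0])
        states = LatentStates(N1=[0, 0, 0], Nad=[0, 0, 0], Nimm=[0, 0, 0])
        assert census_loglik(census, states) == -np.inf

    def test_length_mismatch_rejected(self):
        census = CensusSeries("x", [2000, 2001, 2002], [1, 1, 1])
        with pytest.raises(ValidationError):
            census_loglik(census, LatentStates([1, 1], [1, 1], [0, 0]))


def random_inputs(seed):
    rng = np.random.default_rng(seed)
    res = simulate_population(SimulationConfig(T=8, seed=seed))
    T = 8
    params = DemographicParams(
        mu_phi_j=rng.uniform(0.1, 0.4), mu_phi_a=rng.uniform(0.3, 0.6),
        mu_p=rng.uniform(0.5, 0.9), mu_f=rng.uniform(0.8, 1.5),
        sigma_phi_j=rng.uniform(0.05, 0.5),
        sigma_phi_a=rng.uniform(0.05, 0.5),
        sigma_p=rng.uniform(0.05, 0.5), sigma_f=rng.uniform(0.02, 0.3),
        eps_phi_j=rng.normal(0, 0.3, T - 1),
        eps_phi_a=rng.normal(0, 0.3, T - 1),
        eps_p=rng.normal(0, 0.3, T - 1), eps_f=rng.normal(0, 0.2, T))
    y = res.census.y
    states = LatentStates(
        N1=np.maximum(1, (0.2 * y).astype(int)),
        Nad=np.maximum(1, (0.6 * y).astype(int)),
        Nimm=np.maximum(0, (0.15 * y).astype(int)))
    imm = ImmigrationParams(rng.uniform(0.5, 8.0, T - 1))
    return res, params, states, imm


class TestJointPosterior:
    def test_additivity_of_components(self):
        """Joint equals the sum of separately computed parts + priors."""
        from flypop.cjs import SurvivalParams, cjs_loglik
        from flypop.fecundity import fecundity_loglik
        from flypop.ipm import _log_prior

        res, params, states, imm = random_inputs(31)
        marrays = build_marrays(res.captures)
        T = res.census.n_years
        joint = joint_log_posterior(res.census, marrays, res.productivity,
                                    params, states, imm)
        parts = (_log_prior(params, states, imm, PriorConfig(), T)
                 + state_process_loglik(states, params, imm)
                 + census_loglik(res.census, states)
                 + fecundity_loglik(res.productivity, params.f(T))
                 + cjs_loglik(marrays, SurvivalParams(
                     params.phi_j(T - 1), params.phi_a(T - 1),
                     params.p(T - 1))))
        assert joint == pytest.approx(parts, abs=1e-10)

    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_python_matches_numba_kernel(self, seed):
        """Reference composition and the sampler kernel agree exactly."""
        from scipy.special import logit

        res, params, states, imm = random_inputs(seed)
        marrays = build_marrays(res.captures)
        T = res.census.n_years
        py = joint_log_posterior(res.census, marrays, res.productivity,
                                 params, states, imm)
        lmu = np.array([logit(params.mu_phi_j), logit(params.mu_phi_a),
                        logit(params.mu_p), np.log(params.mu_f)])
        sig = np.array([params.sigma_phi_j, params.sigma_phi_a,
                        params.sigma_p, params.sigma_f])
        N = np.stack([states.N1, states.Nad, states.Nimm])
        kern = _kernel.joint_logpost(
            res.census.y.astype(np.int64), res.productivity.J,
            res.productivity.R.astype(np.int64),
            marrays.marray_juv.astype(np.int64),
            marrays.marray_ad.astype(np.int64),
            lmu, sig, params.eps_phi_j, params.eps_phi_a, params.eps_p,
            params.eps_f, imm.m, N, 0.0, 30.0, 10.0, 10.0, 10.0, 100.0)
        assert py == pytest.approx(kern, abs=1e-8)

    def test_off_support_sigma_gives_neg_inf(self):
        res, params, states, imm = random_inputs(31)
        params.sigma_f = 0.0
        marrays = build_marrays(res.captures)
        assert joint_log_posterior(res.census, marrays, res.productivity,
                                   params, states, imm) == -np.inf

    def test_immigration_outside_prior_gives_neg_inf(self):
        res, params, states, imm = random_inputs(31)
        imm = ImmigrationParams(np.full(7, 40.0))
        marrays = build_marrays(res.captures)
        assert joint_log_posterior(res.census, marrays, res.productivity,
                                   params, states, imm) == -np.inf


class TestFit:
    def test_same_seed_identical_draws(self):
        res = simulate_population(SimulationConfig(T=8, seed=21))
        cfg = FitConfig(chains=2, iterations=600, burnin=300, thin=3,
                        seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_ipm(res.census, res.captures, res.productivity, cfg)
            b = fit_ipm(res.census, res.captures, res.productivity, cfg)
        for name in ("mu_phi_a", "Ntot", "m"):
            np.testing.assert_array_equal(a.params[name], b.params[name])

    def test_draw_invariants(self, small_fit):
        """Ntot identity and the binomial survival bound hold in every draw."""
        n1 = small_fit.stacked("N1")
        nad = small_fit.stacked("Nad")
        nimm = small_fit.stacked("Nimm")
        ntot = small_fit.stacked("Ntot")
        np.testing.assert_array_equal(ntot, n1 + nad + nimm)
        assert np.all(nad[:, 1:] <= ntot[:, :-1])
        assert np.all(n1 >= 0) and np.all(nimm >= 0)
        assert small_fit.n_chains == 2
        assert set(small_fit.meta["rhat"]) >= {"mu_phi_j", "mu_f"}

    def test_no_immigration_prior_pins_imm_stage(self):
        """m_bounds=(0,0): posterior immigrant counts are exactly zero."""
        res = simulate_population(
            SimulationConfig(T=10, seed=51, m=0.0,
                             second_brood_prob=0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_ipm(res.census, res.captures, res.productivity,
                          FitConfig(chains=2, iterations=1500, burnin=600,
                                    thin=3, seed=8),
                          PriorConfig(m_bounds=(0.0, 0.0)))
        assert np.all(fit.stacked("Nimm")[:, 1:] == 0)
        assert np.all(fit.stacked("m") == 0)
        # latent totals track the exactly observed census
        ntot = fit.stacked("Ntot").mean(axis=0)
        assert np.all(np.abs(ntot - res.census.y)
                      <= np.maximum(3, 0.35 * np.maximum(res.census.y, 1)))

    def test_census_vital_rate_gap_forces_immigrants(self):
        """Census inflated beyond local demography -> posterior Nimm > 0."""
        res = simulate_population(
            SimulationConfig(T=10, seed=52, m=0.0, second_brood_prob=0.0))
        inflated = CensusSeries(res.census.population_id, res.census.years,
                                res.census.y + 6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_ipm(inflated, res.captures, res.productivity,
                          FitConfig(chains=2, iterations=1500, burnin=600,
                                    thin=3, seed=8))
        total_imm = fit.stacked("Nimm")[:, 1:].sum(axis=1)
        assert total_imm.mean() > 5.0

    def test_vaasa_joint_fit_recovers_published_fecundity(self):
        """Real Vaasa census + productivity, with capture data simulated
        at the published-rate truth: joint posterior mode of mean
        fecundity ~= 1.13, inside the printed interval [0.98, 1.28]."""
        from flypop import datasets
        from flypop.analysis import summarize

        census = datasets.load_census("vaasa")
        prod = datasets.load_productivity("vaasa")
        params = DemographicParams(
            mu_phi_j=0.13, mu_phi_a=0.36, mu_p=0.85, mu_f=1.13,
            sigma_phi_j=0.2, sigma_phi_a=0.15, sigma_p=0.2, sigma_f=0.05)
        sim = simulate_population(SimulationConfig(
            T=13, start_year=2002, n1_init=6, nad_init=20, nimm_init=5,
            params=params, m=6.0, seed=314))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_ipm(census, sim.captures, prod,
                          FitConfig(chains=2, iterations=4000, burnin=1600,
                                    thin=3, seed=2))
        s = summarize(fit.stacked("mu_f"))
        assert s.mode == pytest.approx(1.13, abs=0.05)
        assert 0.98 <= s.mode <= 1.28

    def test_mismatched_years_rejected(self, sim_default):
        short = CensusSeries("x", sim_default.census.years[:-1],
                             sim_default.census.y[:-1])
        with pytest.raises(ValidationError):
            fit_ipm(short, sim_default.captures, sim_default.productivity,
                    FitConfig(chains=2, iterations=200, burnin=100, seed=1))
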