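"""Posterior summaries, derived rates, and correlation machinery."""

import numpy as np
import pytest

from flypop.analysis import (
    annual_pgr,
    correlate_draws,
    correlate_with_pgr,
    cross_population_correlation,
    cross_population_table,
    demographic_table,
    density_dependence,
    density_dependence_table,
    geometric_mean_pgr,
    hpd_interval,
    immigration_rate,
    pgr_correlation_table,
    summarize,
)
from flypop.data import LatentStates, PosteriorDraws, ValidationError


class TestSummarize:
    def test_standard_normal_mode_and_hpd(self, rng):
        x = rng.normal(0.0, 1.0, 50_000)
        s = summarize(x)
        assert abs(s.mode) < 0.1
        assert s.hpd_low == pytest.approx(-1.96, abs=0.1)
        assert s.hpd_high == pytest.approx(1.96, abs=0.1)

    def test_exponential_hpd_starts_at_zero(self, rng):
        """Narrowest 95% window of Exp(1) is (0, -log(0.05)) ~ (0, 3.0)."""
        x = rng.exponential(1.0, 100_000)
        s = summarize(x)
        assert s.hpd_low == pytest.approx(0.0, abs=0.05)
        assert s.hpd_high == pytest.approx(3.0, abs=0.12)
        # a Gaussian KDE overshoots a boundary mode by O(bandwidth)
        assert s.mode < 0.3

    def test_skewed_sample_mode_below_mean(self, rng):
        x = rng.lognormal(0.0, 0.8, 30_000)
        s = summarize(x)
        assert s.mode < x.mean()

    def test_constant_sample_degenerates(self):
        s = summarize(np.full(500, 2.5))
        assert (s.mode, s.hpd_low, s.hpd_high) == (2.5, 2.5, 2.5)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValidationError):
            summarize(np.arange(10))

    def test_mode_approaches_mean_for_symmetric_samples(self, rng):
        x = rng.normal(5.0, 2.0, 200_000)
        s = summarize(x)
        assert abs(s.mode - x.mean()) < 0.1


class TestDerivedSeries:
    def test_constant_trajectory_gives_unit_growth(self):
        states = LatentStates(N1=[2, 2, 2], Nad=[8, 8, 8], Nimm=[0, 0, 0])
        lam = annual_pgr(states)
        np.testing.assert_allclose(lam.values, 1.0)

    def test_halving_gives_half(self):
        lam = annual_pgr(np.array([[16.0, 8.0]]))
        assert lam.values[0, 0] == 0.5

    def test_matches_direct_ratio_on_truth(self, sim_default):
        st = sim_default.truth.states
        lam = annual_pgr(st)
        np.testing.assert_allclose(
            lam.values[0], st.Ntot[1:] / st.Ntot[:-1])

    def test_zero_denominator_draws_excluded(self):
        ntot = np.array([[10.0, 5.0, 2.0], [4.0, 0.0, 3.0]])
        lam = annual_pgr(ntot)
        assert lam.n_excluded == 1
        assert lam.values.shape == (1, 2)

    def test_immigration_rate_ratio(self):
        om = immigration_rate(np.array([[0.0, 5.0]]),
                              np.array([[25.0, 30.0]]))
        assert om.values[0, 0] == pytest.approx(0.2)

    def test_same_immigrants_in_larger_population_halves_rate(self):
        om1 = immigration_rate(np.array([[0.0, 6.0]]), np.array([[20.0, 26.0]]))
        om2 = immigration_rate(np.array([[0.0, 6.0]]), np.array([[40.0, 46.0]]))
        assert om2.values[0, 0] == pytest.approx(om1.values[0, 0] / 2)

    def test_zero_immigrants_zero_rate(self):
        om = immigration_rate(np.zeros((1, 4)), np.full((1, 4), 12.0))
        np.testing.assert_array_equal(om.values, 0.0)


class TestGeometricMean:
    def test_constant_trajectory_exactly_one(self):
        gm = geometric_mean_pgr(np.full((5, 8), 17.0))
        np.testing.assert_array_equal(gm, 1.0)

    def test_halving_closed_form(self):
        ntot = np.linspace(1.0, 0.5, 20)[None, :]
        gm = geometric_mean_pgr(ntot)
        assert gm[0] == pytest.approx(2 ** (-1 / 19))

    def test_subrange_equal_to_full_range(self, rng):
        ntot = rng.uniform(5, 40, (3, 10))
        np.testing.assert_allclose(
            geometric_mean_pgr(ntot),
            geometric_mean_pgr(ntot, start=0, end=9))

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValidationError):
            geometric_mean_pgr(rng.uniform(5, 40, (3, 10)), start=4, end=4)


class TestCorrelations:
    def test_identical_series_perfectly_correlated(self, rng):
        x = rng.normal(size=(200, 8))
        res = correlate_with_pgr(x, x.copy())
        np.testing.assert_allclose(res.draws, 1.0)
        assert res.p_positive == 1.0
        assert res.significant

    def test_independent_white_noise_centered(self, rng):
        res = correlate_draws(rng.normal(size=(2000, 10)),
                              rng.normal(size=(2000, 10)))
        assert 0.4 < res.p_positive < 0.6
        assert not res.significant

    def test_too_few_years_rejected(self, rng):
        with pytest.raises(ValidationError):
            correlate_draws(rng.normal(size=(50, 2)),
                            rng.normal(size=(50, 2)))

    def test_spearman_option(self, rng):
        x = rng.normal(size=(300, 9))
        res = correlate_draws(x, np.exp(x), method="spearman")
        np.testing.assert_allclose(res.draws, 1.0)

    def test_density_dependent_trajectory_detected(self, rng):
        """Growth declining in population size yields negative correlation."""
        n_draws, T = 400, 15
        ntot = np.empty((n_draws, T))
        ntot[:, 0] = 20.0
        for t in range(T - 1):
            lam = 2.0 - 0.05 * ntot[:, t] + rng.normal(0, 0.05, n_draws)
            ntot[:, t + 1] = np.clip(ntot[:, t] * lam, 2.0, None)
        res = density_dependence(ntot, annual_pgr(ntot).values)
        assert res.mode < 0
        assert res.p_positive < 0.025

    def test_constant_immigrant_number_dissociation(self, rng):
        """Fixed immigrant numbers: rate is density dependent, count not."""
        n_draws, T = 500, 12
        ntot = rng.uniform(10, 40, (n_draws, T))
        nimm = np.concatenate(
            [np.zeros((n_draws, 1)),
             5.0 + rng.normal(0, 0.3, (n_draws, T - 1))], axis=1)
        rate = density_dependence(ntot, nimm[:, 1:] / ntot[:, :-1])
        count = density_dependence(ntot, nimm[:, 1:])
        assert rate.mode < -0.3
        assert rate.p_positive < 0.025
        assert abs(count.p_positive - 0.5) < 0.3
        assert not count.significant

    def test_shuffled_years_break_association(self, rng):
        x = rng.normal(size=(800, 10))
        y = x + rng.normal(0, 0.1, size=(800, 10))
        perm = rng.permutation(10)
        res = correlate_draws(x[:, perm], y)
        assert 0.2 < res.p_positive < 0.8


def fake_fit(rng, T=12, n_draws=300, start_year=2001, series=None,
             noise=0.05):
    """Posterior-like draws around a common latent annual series."""
    if series is None:
        series = {
            "Ntot": rng.uniform(10, 30, T),
            "phi_j": rng.uniform(0.1, 0.25, T - 1),
            "phi_a": rng.uniform(0.35, 0.55, T - 1),
            "f": rng.uniform(0.9, 1.4, T),
            "Nimm": np.concatenate([[0], rng.uniform(1, 7, T - 1)]),
        }
    params = {}
    for name, base in series.items():
        k = len(base)
        draws = base[None, None, :] * np.exp(
            rng.normal(0, noise, (2, n_draws // 2, k)))
        params[name] = draws
    for extra in ("mu_phi_j", "mu_phi_a", "mu_p", "mu_f", "sigma_phi_j",
                  "sigma_phi_a", "sigma_p", "sigma_f"):
        params[extra] = np.abs(rng.normal(0.5, 0.05, (2, n_draws // 2)))
    draws = PosteriorDraws(params)
    draws.meta["years"] = list(range(start_year, start_year + T))
    return draws


class TestCrossPopulation:
    def test_identical_fits_perfectly_correlated(self, rng):
        fit = fake_fit(rng)
        res = cross_population_correlation(fit, fit)
        for name in ("pgr", "phi_j", "phi_a", "immigration_rate"):
            assert res[name].p_positive > 0.99

    def test_independent_fits_not_significant(self, rng):
        res = cross_population_correlation(fake_fit(rng), fake_fit(rng))
        assert set(res) == {"pgr", "phi_j", "phi_a", "immigration_rate"}
        for r in res.values():
            assert -1 <= r.mode <= 1

    def test_overlap_alignment(self, rng):
        a = fake_fit(rng, T=13, start_year=2002)
        b = fake_fit(rng, T=20, start_year=1995)
        res = cross_population_correlation(a, b)
        # overlapping transition steps 2002..2013 -> 12 paired years
        assert res["pgr"].draws.shape[0] > 0

    def test_no_overlap_rejected(self, rng):
        a = fake_fit(rng, T=5, start_year=2000)
        b = fake_fit(rng, T=5, start_year=2010)
        with pytest.raises(ValidationError):
            cross_population_correlation(a, b)

    def test_permuting_draw_order_preserves_distribution(self, rng):
        """Draw pairing must not fabricate dependence: permuting one
        population's draws leaves the correlation distribution unchanged
        in expectation."""
        a = fake_fit(rng, n_draws=600)
        b = fake_fit(rng, n_draws=600)
        base = cross_population_correlation(a, b)["pgr"]
        perm = rng.permutation(600)
        b_perm = PosteriorDraws(
            {k: v.reshape(-1, *v.shape[2:])[perm].reshape(v.shape)
             for k, v in b.params.items()})
        b_perm.meta["years"] = b.meta["years"]
        shuffled = cross_population_correlation(a, b_perm)["pgr"]
        assert abs(base.draws.mean() - shuffled.draws.mean()) < 0.1


class TestTables:
    def test_demographic_table_layout(self, small_fit):
        table = demographic_table(small_fit)
        assert list(table["parameter"]) == [
            "juvenile_survival", "adult_survival", "fecundity",
            "capture_prob", "gm_pgr"]
        assert (table["hpd_low"] <= table["mode"]).all()
        assert (table["mode"] <= table["hpd_high"]).all()

    def test_correlation_tables_layout(self, small_fit):
        t3a = pgr_correlation_table(small_fit)
        assert len(t3a) == 4
        t3b = density_dependence_table(small_fit)
        assert set(t3b["parameter"]) >= {"n_immigrants", "pgr",
                                         "immigration_rate"}
        assert t3b["correlation"].between(-1, 1).all()

    def test_cross_population_table(self, rng):
        table = cross_population_table(fake_fit(rng), fake_fit(rng))
        assert len(table) == 4
        assert table["p_positive"].between(0, 1).all()
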