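"""Likelihood, latent-state updates, sampler correctness and diagnostics."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from paceshape.bayes import (
    MCMCConfig,
    PriorEntry,
    PriorSpec,
    fit_zoo,
    latent_outmigration_probability,
    latent_outmigration_update,
    log_posterior,
    psrf,
    record_log_likelihood,
    run_mcmc,
    summarize,
)
from paceshape.cohorts import (
    CohortConfig,
    IndividualRecord,
    OutMigrationModel,
    simulate_cohort,
    zoo_cohort,
)
from paceshape.siler import SilerParams, death_density, survival

EXP02 = SilerParams(-30.0, 1.0, 0.2, -30.0, 0.1)  # effectively Exp(0.2)
OM = OutMigrationModel(pi=0.3, gamma_shape=2.0, gamma_rate=1.0, alpha=3.0)


def rec(x_f, x_l, fate="unknown", origin="natal"):
    return IndividualRecord(id="t", birth=0.0, first_detect=x_f, last_detect=x_l,
                            origin=origin, fate=fate)


class TestRecordLogLikelihood:
    def test_death_branch_worked_value(self):
        # f(5) (1-pi) = 0.2 e^-1 * 0.7
        ll = record_log_likelihood(rec(0.0, 5.0), EXP02, OM, o=0)
        assert math.exp(ll) == pytest.approx(0.0515031, rel=1e-6)

    def test_outmigration_branch_worked_value(self):
        # S(5) pi g(2) = e^-1 * 0.3 * 2 e^-2
        ll = record_log_likelihood(rec(0.0, 5.0), EXP02, OM, o=1)
        assert math.exp(ll) == pytest.approx(0.0298723, rel=1e-5)

    def test_left_truncation_worked_value(self):
        # truncation divides by S(2) = e^-0.4
        ll = record_log_likelihood(rec(2.0, 5.0), EXP02, OM, o=0)
        assert math.exp(ll) == pytest.approx(0.0768336, rel=1e-6)

    def test_censored_branch(self):
        ll = record_log_likelihood(rec(2.0, 5.0, fate="censored"), EXP02, OM, o=0,
                                   censored=True)
        assert ll == pytest.approx(-0.6, abs=1e-6)  # log S(5)/S(2) = -0.2*3

    def test_outmigration_below_minimum_age_rejected(self):
        with pytest.raises(ValueError):
            record_log_likelihood(rec(0.0, 2.0), EXP02, OM, o=1)

    def test_unknown_birth_rejected(self):
        r = IndividualRecord(id="u", birth=None, first_detect=0.0, last_detect=5.0)
        with pytest.raises(ValueError):
            record_log_likelihood(r, EXP02, OM, o=0)


class TestLatentUpdate:
    def test_degenerate_probabilities(self):
        om0 = OutMigrationModel(pi=0.0, gamma_shape=2.0, gamma_rate=1.0, alpha=3.0)
        om1 = OutMigrationModel(pi=1.0, gamma_shape=2.0, gamma_rate=1.0, alpha=3.0)
        assert latent_outmigration_probability(rec(0.0, 5.0), EXP02, om0) == 0.0
        assert latent_outmigration_probability(rec(0.0, 5.0), EXP02, om1) == 1.0

    def test_ratio_of_branch_likelihoods(self):
        p = latent_outmigration_probability(rec(0.0, 5.0), EXP02, OM)
        assert p == pytest.approx(0.0298723 / (0.0298723 + 0.0515031), rel=1e-4)

    def test_forced_zero_below_minimum_age(self):
        assert latent_outmigration_probability(rec(0.0, 2.0), EXP02, OM) == 0.0

    def test_draw_deterministic(self):
        draws = [latent_outmigration_update(rec(0.0, 5.0), EXP02, OM,
                                            np.random.default_rng(1)) for _ in range(2)]
        assert draws[0] == draws[1]
        many = [latent_outmigration_update(rec(0.0, 5.0), EXP02, OM, rng)
                for rng in [np.random.default_rng(s) for s in range(400)]]
        assert abs(np.mean(many) - 0.367) < 0.07


class TestLogPosterior:
    def test_additivity(self, theta_star):
        records = [rec(0.0, 5.0, fate="dead"), rec(1.0, 8.0, fate="dead")]
        priors = PriorSpec()
        args = (OM, None, [0, 0], [0.0, 0.0], priors)
        lp1 = log_posterior(records, theta_star, *args)
        other = theta_star.replace(c=0.05)
        lp2 = log_posterior(records, other, *args)
        dlik = sum(record_log_likelihood(r, other, OM, 0)
                   - record_log_likelihood(r, theta_star, OM, 0) for r in records)
        dprior = priors.entries["c"].logpdf(0.05) - priors.entries["c"].logpdf(0.01)
        assert lp2 - lp1 == pytest.approx(dlik + dprior, rel=1e-9)

    def test_grid_mode_matches_mle(self):
        # flat-ish prior: the 1-d posterior mode in c must sit at the MLE n/sum(x)
        rng = np.random.default_rng(0)
        x = rng.exponential(5.0, size=400)
        records = [IndividualRecord(id=f"e{i}", birth=0.0, first_detect=0.0,
                                    last_detect=float(v), fate="dead")
                   for i, v in enumerate(x)]
        entries = {k: PriorEntry(v.mean, 1e6, v.lower, v.upper)
                   for k, v in PriorSpec().entries.items()}
        priors = PriorSpec(entries=entries)
        grid = np.linspace(0.1, 0.4, 301)
        base = SilerParams(-30.0, 1.0, 0.2, -30.0, 0.001)
        lps = [log_posterior(records, base.replace(c=float(c)), OM, None,
                             [0] * 400, [0.0] * 400, priors) for c in grid]
        c_mode = grid[int(np.argmax(lps))]
        c_mle = len(x) / x.sum()
        assert abs(c_mode - c_mle) <= (grid[1] - grid[0])

    def test_pi_factors_give_beta_conditional(self):
        # with latents fixed, the pi-dependence of the posterior must be
        # proportional to pi^k (1-pi)^(n-k): check a log-ratio identity
        records = [rec(0.0, 5.0, fate="unknown") for _ in range(6)]
        o = [1, 1, 0, 0, 0, 0]
        priors = PriorSpec()

        def lp(pi):
            om = OutMigrationModel(pi=pi, gamma_shape=2.0, gamma_rate=1.0, alpha=3.0)
            return log_posterior(records, EXP02, om, None, o, [0.0] * 6, priors)

        k, n = 2, 6
        expected = (k * (math.log(0.6) - math.log(0.2))
                    + (n - k) * (math.log(0.4) - math.log(0.8)))
        assert lp(0.6) - lp(0.2) == pytest.approx(expected, rel=1e-9)

    def test_out_of_support_is_minus_inf(self, theta_star):
        priors = PriorSpec()
        bad = PriorSpec(entries={**priors.entries,
                                 "c": PriorEntry(0.01, 10.0, lower=0.0, upper=0.02)})
        records = [rec(0.0, 5.0, fate="dead")]
        lp = log_posterior(records, theta_star.replace(c=0.5), OM, None, [0], [0.0], bad)
        assert lp == -math.inf


class TestBranchPropriety:
    def test_observable_mass_accounting(self):
        # competing risks: death at X ~ f, dispersal at V = alpha + gamma with
        # prob pi; the observed out-migration density is pi g(v) S(v), and the
        # total observable mass (deaths + out-migrations) must be 1
        params, om = EXP02, OM
        out_mass, _ = integrate.quad(
            lambda v: om.pi * math.exp(float(om.dispersal_age_logpdf(v)))
            * survival(params, v), om.alpha, 200.0)
        rng = np.random.default_rng(12)
        n = 200_000
        deaths = rng.exponential(5.0, n)
        disperses = rng.random(n) < om.pi
        v = om.alpha + rng.gamma(om.gamma_shape, 1.0 / om.gamma_rate, n)
        observed_out = disperses & (v < deaths)
        assert observed_out.mean() == pytest.approx(out_mass, abs=0.01)
        assert (~observed_out).mean() == pytest.approx(1.0 - out_mass, abs=0.01)


class TestPSRF:
    def test_identical_chains(self):
        r = psrf(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        assert r["p0"] == pytest.approx(math.sqrt(2.0 / 3.0), rel=1e-9)

    def test_shifted_chains(self):
        r = psrf(np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]]))
        assert r["p0"] == pytest.approx(math.sqrt(8.0 / 3.0), rel=1e-9)

    def test_constant_chains_error(self):
        with pytest.raises(ValueError):
            psrf(np.array([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]]))

    def test_single_chain_error(self):
        with pytest.raises(ValueError):
            psrf(np.array([[1.0, 2.0, 3.0]]))


def small_cfg(**kw):
    d = dict(n_chains=2, n_iter=600, burn_in=250, seed=13)
    d.update(kw)
    return MCMCConfig(**d)


class TestSampler:
    def test_deterministic_given_seed(self, theta_star):
        recs = zoo_cohort(theta_star, 80, seed=1)
        a = fit_zoo(recs, config=small_cfg())
        b = fit_zoo(recs, config=small_cfg())
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_zoo_is_run_mcmc_without_outmigration(self, theta_star):
        recs = zoo_cohort(theta_star, 80, seed=1)
        a = fit_zoo(recs, config=small_cfg())
        b = run_mcmc(recs, config=small_cfg(), outmigration=False, censored_branch=True)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_zoo_rejects_outmigrants(self):
        r = IndividualRecord(id="o", birth=0.0, first_detect=0.0, last_detect=5.0,
                             fate="out_migrated")
        with pytest.raises(ValueError):
            fit_zoo([r])

    def test_censored_records_need_flag(self):
        rs = [IndividualRecord(id="c", birth=0.0, first_detect=0.0, last_detect=5.0,
                               fate="censored"),
              IndividualRecord(id="d", birth=0.0, first_detect=0.0, last_detect=5.0)]
        with pytest.raises(ValueError):
            run_mcmc(rs, config=small_cfg())

    def test_flat_likelihood_samples_prior(self):
        # records censored at age 0 carry no information: chains roam the prior
        rs = [IndividualRecord(id=f"c{i}", birth=0.0, first_detect=0.0,
                               last_detect=0.0, fate="censored") for i in range(20)]
        with pytest.warns(UserWarning):
            ch = fit_zoo(rs, config=small_cfg(n_iter=1500, burn_in=500))
        assert ch.pooled("a0").std() > 3.0  # vague prior sd is 10

    def test_invariance_when_started_at_truth(self, theta_star):
        recs = zoo_cohort(theta_star, 300, seed=3)
        ch = run_mcmc(recs, config=small_cfg(n_iter=1200, burn_in=400),
                      outmigration=False, censored_branch=True,
                      init_theta=theta_star)
        s = summarize(ch)
        for name in ("a0", "a1", "c", "b0", "b1"):
            sd = ch.pooled(name).std()
            assert abs(s.means[name] - getattr(theta_star, name)) < 3 * sd

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            run_mcmc([])


class TestSummarize:
    def test_degenerate_chain(self, theta_star):
        recs = zoo_cohort(theta_star, 50, seed=1)
        ch = fit_zoo(recs, config=small_cfg())
        ch.draws[:] = theta_star.as_array()  # one repeated draw
        s = summarize(ch)
        for name in ("a0", "a1", "c", "b0", "b1"):
            assert s.means[name] == pytest.approx(getattr(theta_star, name), rel=1e-12)
        assert s.e_se < 1e-10
        assert all(math.isnan(v) for v in s.psrf.values())

    def test_background_posterior_maps_to_pace_shape(self):
        recs = zoo_cohort(EXP02, 50, seed=1)
        ch = fit_zoo(recs, config=small_cfg())
        ch.draws[:] = EXP02.as_array()
        s = summarize(ch)
        assert s.e_hat == pytest.approx(5.0, rel=1e-3)
        assert s.epsilon_hat == pytest.approx(0.0, abs=1e-4)

    def test_ci_brackets_mean(self, theta_star):
        recs = zoo_cohort(theta_star, 200, seed=6)
        ch = fit_zoo(recs, config=small_cfg(n_iter=1000, burn_in=400))
        s = summarize(ch)
        for name in ("a0", "a1", "c", "b0", "b1"):
            lo, hi = s.ci[name]
            assert lo <= s.means[name] <= hi
        assert s.e_se > 0
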