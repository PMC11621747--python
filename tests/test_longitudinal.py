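"""Transmission likelihood, posterior sampling, HPDI, counterfactuals."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats as sps

from cultrans import (
    ABMParams,
    AgeSchedule,
    PanelStats,
    SamplerConfig,
    TransmissionParams,
    counterfactual_migration,
    fit_posterior,
    hpdi,
    log_likelihood,
    sample_longitudinal,
)

from conftest import build_panel
from oracles import panel_loglik_bruteforce

BOUNDS = AgeSchedule().boundaries  # (0, 3, 6, 12)


class TestLogLikelihood:
    def test_single_row_closed_form(self, single_row_panel):
        # learner (age 5 -> class 1) with contacts 20xA + 10xB, self A:
        # tally A=21, B=10; adopted A at theta=1
        params = TransmissionParams(mu=0.01, theta=1.0, m_a=(0.1, 0.2, 0.1, 0.05))
        expected = math.log(1 - 0.01) + math.log(1 - 0.2) + math.log(21 / 31)
        assert log_likelihood(single_row_panel, params, BOUNDS) == pytest.approx(expected)

    def test_theta_reweights_tally(self, single_row_panel):
        params = TransmissionParams(mu=0.0, theta=2.0, m_a=(0.0, 0.0, 0.0, 0.0))
        expected = math.log(21**2 / (21**2 + 10**2))
        assert log_likelihood(single_row_panel, params, BOUNDS) == pytest.approx(expected)

    def test_impossible_innovation_gives_minus_inf(self):
        panel = build_panel([(1, 0, 5, 0, 99, 0, 1, 1, 0)], [[0] * 5])
        params = TransmissionParams(mu=0.0, theta=1.0, m_a=(0.1,) * 4)
        assert log_likelihood(panel, params, BOUNDS) == -np.inf

    def test_adopted_variant_outside_support_flags_rows(self):
        panel = build_panel([(1, 0, 5, 0, 7, 3, 1, 0, 0)], [[0] * 5])
        params = TransmissionParams(mu=0.01, theta=1.0, m_a=(0.1,) * 4)
        with pytest.warns(UserWarning, match="outside self\\+contact"):
            assert log_likelihood(panel, params, BOUNDS) == -np.inf

    def test_matches_per_row_oracle_on_simulated_panels(self):
        abm = ABMParams(
            n_groups=4, group_size=25, n_partners=8,
            migration=AgeSchedule(), burn_in_years=80, record_years=0,
        )
        for seed in (1, 2):
            panel = sample_longitudinal(abm, 30, 6, seed=seed, settle_years=20)
            for params in (
                TransmissionParams(mu=0.02, theta=1.3, m_a=(0.05, 0.2, 0.1, 0.02)),
                TransmissionParams(mu=0.3, theta=0.6, m_a=(0.4, 0.1, 0.3, 0.2)),
            ):
                oracle = panel_loglik_bruteforce(
                    panel, params.mu, params.theta, params.m_a, BOUNDS
                )
                assert log_likelihood(panel, params, BOUNDS) == pytest.approx(oracle)

    def test_score_identity_at_generating_theta(self):
        """d/dtheta of the adoption term has mean ~0 at the true theta."""
        rng = np.random.default_rng(0)
        theta0, eps = 1.5, 1e-4
        scores = []
        for _ in range(300):
            counts = rng.integers(1, 10, size=3).astype(float)
            probs = counts**theta0 / np.sum(counts**theta0)
            adopted = rng.choice(3, p=probs)
            def term(th):
                return th * np.log(counts[adopted]) - np.log(np.sum(counts**th))
            scores.append((term(theta0 + eps) - term(theta0 - eps)) / (2 * eps))
        se = np.std(scores) / np.sqrt(len(scores))
        assert abs(np.mean(scores)) < 4 * se


class TestHPDI:
    def test_constant_samples_zero_width(self):
        assert hpdi(np.full(50, 3.7), 0.9) == (3.7, 3.7)

    def test_standard_normal_matches_quantiles(self):
        x = np.random.default_rng(1).normal(size=200_000)
        lo, hi = hpdi(x, 0.9)
        assert lo == pytest.approx(-1.645, abs=0.03)
        assert hi == pytest.approx(1.645, abs=0.03)

    def test_uniform_width_equals_mass(self):
        x = np.random.default_rng(2).uniform(size=100_000)
        lo, hi = hpdi(x, 0.9)
        assert hi - lo == pytest.approx(0.9, abs=0.01)


@pytest.fixture(scope="module")
def simulated_panel():
    abm = ABMParams(migration=AgeSchedule(), theta=1.7)
    return sample_longitudinal(abm, 400, 25, seed=31)


class TestPosterior:
    def test_recovers_generating_values(self, simulated_panel):
        """Single-panel smoke check: estimates land near the generating
        values (the replicated calibration study asserts exact coverage)."""
        draws = fit_posterior(
            simulated_panel, SamplerConfig(n_iter=1500, warmup=600, chains=1, seed=5)
        )
        assert 0.2 < draws.acceptance < 0.7
        lo, hi = draws.hpdi("theta", 0.95)
        assert lo < 1.7 < hi
        for k, true_m in enumerate(AgeSchedule().rates):
            m = draws.draws[f"m_{k}"]
            assert abs(m.mean() - true_m) < 4 * m.std()

    def test_mu_posterior_matches_conjugate_beta_oracle(self, simulated_panel):
        """The mu block is conjugate: posterior must be Beta(1+k, 1+n-k)."""
        draws = fit_posterior(
            simulated_panel, SamplerConfig(n_iter=4000, warmup=1000, chains=1, seed=6)
        )
        stats = PanelStats(simulated_panel, BOUNDS)
        ref = sps.beta(1 + stats.n_innov, 1 + stats.n_learn - stats.n_innov)
        thinned = draws.draws["mu"].to_numpy()[::8]
        ks = sps.kstest(thinned, ref.cdf)
        assert ks.pvalue > 0.001

    def test_posterior_concentrates_with_panel_size(self):
        abm = ABMParams(migration=AgeSchedule(), theta=1.7)
        widths = []
        for n_ind, n_years, seed in ((60, 8, 41), (500, 30, 42)):
            panel = sample_longitudinal(abm, n_ind, n_years, seed=seed)
            draws = fit_posterior(
                panel, SamplerConfig(n_iter=1500, warmup=600, chains=1, seed=7)
            )
            lo, hi = draws.hpdi("theta", 0.9)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_empty_event_panel_prior_dominated(self):
        # no learning events at all: theta posterior must match its prior
        rows = [(1, i, 20, 0, 5, 5, 0, 0, 0) for i in range(30)]
        panel = build_panel(rows, [[5] * 4] * 30)
        with pytest.warns(UserWarning, match="unidentified"):
            draws = fit_posterior(
                panel, SamplerConfig(n_iter=4000, warmup=1000, chains=1, seed=8)
            )
        ks = sps.kstest(
            np.log(draws.draws["theta"].to_numpy()[::8]), sps.norm(0, 1).cdf
        )
        assert ks.pvalue > 0.001

    def test_fixed_seed_identical_draws(self, simulated_panel):
        cfg = SamplerConfig(n_iter=400, warmup=200, chains=2, seed=9)
        a = fit_posterior(simulated_panel, cfg)
        b = fit_posterior(simulated_panel, cfg)
        assert a.draws.equals(b.draws)


class TestCounterfactual:
    def test_zero_delta_centered_at_zero(self):
        import pandas as pd
        from cultrans.longitudinal import PosteriorDraws

        draws = PosteriorDraws(
            draws=pd.DataFrame(
                {"mu": [0.01] * 5, "theta": [1.5] * 5,
                 "m_0": [0.05] * 5, "m_1": [0.2] * 5, "m_2": [0.1] * 5, "m_3": [0.02] * 5}
            ),
            acceptance=0.4, ess={}, n_chains=1,
        )
        params = ABMParams(
            n_groups=4, group_size=25, n_partners=8, migration=AgeSchedule(),
            burn_in_years=50, record_years=40,
        )
        diffs = counterfactual_migration(draws, 0.0, params, n_draws=3, seed=1, tail=20)
        np.testing.assert_allclose(diffs, 0.0)
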