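"""Priors, posterior sampling, bridge evidence, escapement summaries."""

import math

import numpy as np
import pytest

from escapefit.bayes import (BridgeConfig, McmcConfig, ModelEvidence,
                             PosteriorDraws, PriorSpec,
                             log_marginal_likelihood, log_prior,
                             model_probabilities,
                             posterior_escapement_summary, sample_posterior)
from escapefit.models import Model

from .conftest import make_series
from .oracles import quadrature_log_evidence

FAST = McmcConfig(chains=4, draws=2500, warmup=1500, seed=0, max_retries=2)


class TestLogPrior:
    def test_hand_value_inside_support(self):
        maxx = 50.0
        prior = PriorSpec(k_bounds=(0.1 * maxx, 10.0 * maxx), k_scale=maxx)
        got = log_prior(5.0, maxx, 1.0, prior)
        expected = (-math.log(9.0) - math.log(9.9 * maxx)
                    + math.log(2.0 / math.pi) - math.log(2.0))
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("r,k,sigma", [
        (0.5, 1.0, 1.0),     # r below Uniform[1, 10]
        (11.0, 1.0, 1.0),    # r above
        (5.0, 0.01, 1.0),    # k below per-series bounds
        (5.0, 1.0, -1.0),    # sigma outside half-Cauchy support
    ])
    def test_outside_support(self, r, k, sigma):
        prior = PriorSpec(k_bounds=(0.1, 10.0))
        assert log_prior(r, k, sigma, prior) == -math.inf


class TestSamplePosterior:
    def test_same_seed_identical_draws(self):
        series = make_series("ricker", 1.6, 40.0, 0.2, 15, seed=3)
        cfg = McmcConfig(chains=2, draws=400, warmup=400, seed=7)
        a = sample_posterior("ricker", series, cfg)
        b = sample_posterior("ricker", series, cfg)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.log_post, b.log_post)

    def test_prior_only_recovers_prior(self):
        """With the likelihood switched off the chains target the prior."""
        series = make_series("beverton_holt", 1.8, 60.0, 0.2, 20, seed=1)
        draws = sample_posterior("beverton_holt", series, FAST,
                                 prior_only=True)
        th = draws.flat
        maxx = series.max_biomass
        assert np.mean(th[:, 0]) == pytest.approx(5.5, abs=0.15)
        assert np.quantile(th[:, 0], 0.5) == pytest.approx(5.5, abs=0.25)
        assert np.mean(th[:, 1]) == pytest.approx(5.05 * maxx, rel=0.05)
        # half-Cauchy(0,1): median 1, quartiles tan(pi/8) and tan(3pi/8)
        assert np.median(th[:, 2]) == pytest.approx(1.0, abs=0.1)
        assert np.quantile(th[:, 2], 0.25) == pytest.approx(
            math.tan(math.pi / 8), abs=0.08)

    def test_posterior_concentrates_on_truth(self):
        """Long, low-noise series: posterior mean of r near the truth."""
        series = make_series("beverton_holt", 2.0, 100.0, 0.05, 150, seed=9)
        draws = sample_posterior("beverton_holt", series, FAST)
        r_draws = draws.flat[:, 0]
        assert abs(np.mean(r_draws) - 2.0) < 2.0 * np.std(r_draws) + 0.05

    def test_draws_stay_inside_prior_support(self):
        series = make_series("hockey_stick", 1.5, 30.0, 0.3, 12, seed=4)
        draws = sample_posterior("hockey_stick", series, FAST)
        th = draws.flat
        maxx = series.max_biomass
        assert th[:, 0].min() >= 1.0 and th[:, 0].max() <= 10.0
        assert th[:, 1].min() >= 0.1 * maxx and th[:, 1].max() <= 10 * maxx
        assert th[:, 2].min() > 0.0


def _degenerate_draws(model: Model, theta, series,
                      flagged=False) -> PosteriorDraws:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        theta = np.tile(theta, (200, 1))
    draws = theta[None, :, :]
    return PosteriorDraws(
        model=model, prior=PriorSpec.for_series(series), draws=draws,
        z=draws.copy(), log_post=np.zeros(draws.shape[:2]),
        rhat={"r": 1.0, "k": 1.0, "sigma": 1.0},
        ess={"r": 200.0, "k": 200.0, "sigma": 200.0},
        accept_rate=1.0, flagged=flagged)


class TestEscapementSummary:
    def test_point_mass_hockey_stick(self, toy_series):
        draws = _degenerate_draws(Model.HOCKEY_STICK, [2.0, 1.0, 0.1],
                                  toy_series)
        summ = posterior_escapement_summary("hockey_stick", draws,
                                            toy_series)
        assert summ.median_frac_k == pytest.approx(0.5)
        assert summ.median_frac_max_biomass == pytest.approx(
            0.5 / toy_series.max_biomass)

    def test_uniform_r_median_transform(self, toy_series):
        """With k fixed, median of k/r across draws = k/median(r)."""
        r = np.linspace(1.25, 2.0, 501)
        theta = np.column_stack([r, np.ones_like(r), np.full_like(r, 0.1)])
        draws = _degenerate_draws(Model.HOCKEY_STICK, theta, toy_series)
        summ = posterior_escapement_summary("hockey_stick", draws,
                                            toy_series)
        assert summ.median_frac_k == pytest.approx(1 / 1.625, rel=1e-12)

    def test_beverton_holt_fraction_range(self, toy_series):
        """1/(1+sqrt r) over the prior support lies in (0.240, 0.5)."""
        rng = np.random.default_rng(0)
        theta = np.column_stack([rng.uniform(1.0, 10.0, 400),
                                 rng.uniform(1.0, 110.0, 400),
                                 np.full(400, 0.2)])
        draws = _degenerate_draws(Model.BEVERTON_HOLT, theta, toy_series)
        summ = posterior_escapement_summary("beverton_holt", draws,
                                            toy_series)
        assert 0.2402 < summ.median_frac_k < 0.5

    def test_flagged_draws_refused(self, toy_series):
        draws = _degenerate_draws(Model.RICKER, [2.0, 1.0, 0.1], toy_series,
                                  flagged=True)
        with pytest.raises(ValueError, match="force"):
            posterior_escapement_summary("ricker", draws, toy_series)
        posterior_escapement_summary("ricker", draws, toy_series,
                                     force=True)


class TestModelProbabilities:
    def _ev(self, model, log_z):
        return ModelEvidence(model=model, log_z=log_z, mc_se=0.01,
                             n_iter=5, converged=True)

    def test_equal_evidence(self):
        evs = [self._ev(m, -20.0) for m in Model]
        probs = model_probabilities(evs)
        assert all(p == pytest.approx(1 / 3) for p in probs.values())

    def test_one_model_ruled_out(self):
        evs = [self._ev(Model.BEVERTON_HOLT, 0.0),
               self._ev(Model.RICKER, 0.0),
               self._ev(Model.HOCKEY_STICK, -math.inf)]
        probs = model_probabilities(evs)
        assert probs[Model.BEVERTON_HOLT] == pytest.approx(0.5)
        assert probs[Model.HOCKEY_STICK] == 0.0

    def test_nine_to_one_hand_value(self):
        """Z = (1, 1/9, 0) -> probabilities (0.9, 0.1, 0)."""
        evs = [self._ev(Model.BEVERTON_HOLT, 0.0),
               self._ev(Model.RICKER, -math.log(9.0)),
               self._ev(Model.HOCKEY_STICK, -math.inf)]
        probs = model_probabilities(evs)
        assert probs[Model.BEVERTON_HOLT] == pytest.approx(0.9)
        assert probs[Model.RICKER] == pytest.approx(0.1)

    def test_shift_invariance(self):
        """Only evidence differences matter."""
        evs_a = [self._ev(m, lz) for m, lz in
                 zip(Model, (-5.0, -6.0, -7.0))]
        evs_b = [self._ev(m, lz + 300.0) for m, lz in
                 zip(Model, (-5.0, -6.0, -7.0))]
        pa, pb = model_probabilities(evs_a), model_probabilities(evs_b)
        for m in Model:
            assert pa[m] == pytest.approx(pb[m], rel=1e-12)


class TestBridgeEvidence:
    def test_agrees_with_quadrature_oracle(self):
        """Bridge log Z within 3 MC-SEs of deterministic 3-D quadrature."""
        series = make_series("ricker", 1.5, 80.0, 0.25, 10, seed=21)
        draws = sample_posterior("ricker", series, FAST)
        ev = log_marginal_likelihood("ricker", series, draws,
                                     BridgeConfig(seed=2))
        oracle = quadrature_log_evidence(series, "ricker")
        assert abs(ev.log_z - oracle) < 3.0 * ev.mc_se
        assert ev.mc_se < 0.2

    def test_prior_only_draws_rejected(self):
        series = make_series("ricker", 1.5, 80.0, 0.25, 10, seed=21)
        cfg = McmcConfig(chains=2, draws=300, warmup=300, seed=0)
        draws = sample_posterior("ricker", series, cfg, prior_only=True)
        with pytest.raises(ValueError, match="prior-only"):
            log_marginal_likelihood("ricker", series, draws)

    def test_deterministic_given_seeds(self):
        series = make_series("beverton_holt", 1.7, 50.0, 0.2, 12, seed=8)
        cfg = McmcConfig(chains=2, draws=800, warmup=800, seed=3)
        draws = sample_posterior("beverton_holt", series, cfg)
        ev1 = log_marginal_likelihood("beverton_holt", series, draws,
                                      BridgeConfig(seed=5), force=True)
        ev2 = log_marginal_likelihood("beverton_holt", series, draws,
                                      BridgeConfig(seed=5), force=True)
        assert ev1.log_z == ev2.log_z
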