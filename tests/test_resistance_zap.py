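"""Hurdle-model likelihood oracles and posterior recovery checks."""

import math

import numpy as np
import pytest

from mitedef import MCMCSchedule
from mitedef.data_model import Phenotype, SurveyRecord
from mitedef.resistance_zap import (
    ResistancePosterior,
    fit_resistance,
    intensity_estimates,
    prevalence_estimates,
    truncated_poisson_mean,
    zap_loglikelihood,
)
from mitedef.synthetic_data import (
    DesignConfig,
    GeneratorConfig,
    ResistanceParams,
    simulate_resistance_survey,
)

QUICK = MCMCSchedule(chains=2, draws=500, burn_in=800, thin=1)


class TestZapLoglikelihood:
    @pytest.mark.parametrize("p,lam", [(0.3, 2.0), (0.5, 1.0), (0.9, 0.2), (0.16, 8.0)])
    def test_normalizes_over_counts(self, p, lam):
        """Direct summation over k = 0..200 must give total probability 1."""
        h = math.log(p / (1 - p))
        c = math.log(lam)
        total = np.exp(zap_loglikelihood(np.arange(201), h, c)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_single_count(self):
        # p = 0.5, lam = 1, k = 1
        expected = math.log(0.5) + math.log(math.exp(-1) / (1 - math.exp(-1)))
        assert zap_loglikelihood(1, 0.0, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_certain_zero_limit(self):
        # hurdle predictor -> -inf: P(0) -> 1
        assert zap_loglikelihood(0, -40.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_accepts_record(self):
        rec = SurveyRecord("p", 2003, Phenotype.A, 2, False, None)
        assert zap_loglikelihood(rec, 0.0, 0.5) == pytest.approx(
            zap_loglikelihood(2, 0.0, 0.5)
        )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            zap_loglikelihood(-1, 0.0, 0.0)


class TestTruncatedPoissonMean:
    def test_small_rate_limit_is_one(self):
        assert truncated_poisson_mean(1e-12) == pytest.approx(1.0)

    def test_reference_values(self):
        assert truncated_poisson_mean(1.0) == pytest.approx(1.5820, abs=5e-5)
        assert truncated_poisson_mean(10.0) == pytest.approx(10.00045, abs=5e-6)

    def test_matches_direct_summation(self):
        lam = 2.7
        k = np.arange(1, 200)
        from scipy.stats import poisson

        direct = (k * poisson.pmf(k, lam)).sum() / (1 - math.exp(-lam))
        assert truncated_poisson_mean(lam) == pytest.approx(direct, abs=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            truncated_poisson_mean(0.0)


def _degenerate_posterior(zeta=0.0, eta=0.0):
    shape = (2, 50, 2)
    return ResistancePosterior(
        phenotypes=("A", "M"),
        zeta=np.full(shape, zeta),
        eta=np.full(shape, eta),
        sigma2_g_logit=np.full(shape[:2], 1.0),
        sigma2_g_log=np.full(shape[:2], 1.0),
        sigma2_e_log=np.full(shape[:2], 1.0),
        sigma2_e_logit=1.0,
    )


class TestSummaries:
    def test_degenerate_prevalence_is_half(self):
        t = prevalence_estimates(_degenerate_posterior(zeta=0.0))
        assert (t["mean"] == 0.5).all()
        assert (t.ci_low == 0.5).all() and (t.ci_high == 0.5).all()

    def test_degenerate_intensity_from_unit_rate(self):
        t = intensity_estimates(_degenerate_posterior(eta=0.0))
        assert t["mean"].iloc[0] == pytest.approx(1.5820, abs=5e-5)
        assert (t.ci_high - t.ci_low == 0.0).all()

    def test_intensity_at_least_one(self):
        t = intensity_estimates(_degenerate_posterior(eta=-8.0))
        assert (t["mean"] >= 1.0).all()

    def test_raw_rate_option(self):
        t = intensity_estimates(_degenerate_posterior(eta=0.0), raw_rate=True)
        assert (t["mean"] == 1.0).all()

    def test_positive_variance_draws_enforced(self):
        with pytest.raises(ValueError):
            ResistancePosterior(
                phenotypes=("A", "M"),
                zeta=np.zeros((1, 5, 2)),
                eta=np.zeros((1, 5, 2)),
                sigma2_g_logit=np.zeros((1, 5)),
                sigma2_g_log=np.ones((1, 5)),
                sigma2_e_log=np.ones((1, 5)),
                sigma2_e_logit=1.0,
            )


def _norebalance_config(zeta, eta, n=400, seed=0):
    return GeneratorConfig(
        design=DesignConfig(
            populations=4, years=2, n_per_group={"A": n, "I": n, "O": 0, "M": n}
        ),
        resistance=ResistanceParams(
            zeta={k: zeta for k in "AIOM"},
            eta={k: eta for k in "AIOM"},
            sigma2_group_logit=1e-6,
            sigma2_group_log=1e-6,
            sigma2_unit_logit=1e-6,
            sigma2_unit_log=1e-6,
        ),
        seed=seed,
    )


class TestFitResistance:
    def test_recovers_fixed_effects_without_variance(self):
        """With no group or unit heterogeneity the phenotype effects should
        match the generating values (and the empirical MLE) closely."""
        zeta_true = math.log(0.2 / 0.8)  # prevalence 0.20
        eta_true = math.log(3.0)
        cfg = _norebalance_config(zeta_true, eta_true, seed=12)
        cfg.resistance.sigma2_unit_logit = 1e-6
        recs = simulate_resistance_survey(cfg)
        from mitedef.resistance_zap import ZapModelSpec

        post = fit_resistance(
            recs, spec=ZapModelSpec(sigma2_e_logit=1e-6), mcmc=QUICK, seed=3
        )
        prev = prevalence_estimates(post)
        # binomial MLE oracle per phenotype
        emp = np.mean([r.mites > 0 for r in recs])
        for _, row in prev.iterrows():
            assert row.ci_low - 0.02 < 0.20 < row.ci_high + 0.02
            assert row["mean"] == pytest.approx(emp, abs=0.03)
        inten = intensity_estimates(post)
        expect = truncated_poisson_mean(3.0)
        for _, row in inten.iterrows():
            assert row["mean"] == pytest.approx(expect, rel=0.06)

    def test_all_zero_counts_push_prevalence_to_zero(self):
        recs = [
            SurveyRecord(f"p{i % 4}", 2003 + (i % 2), Phenotype("AM"[i % 2]), 0, False, None)
            for i in range(400)
        ]
        post = fit_resistance(
            recs, mcmc=MCMCSchedule(chains=1, draws=300, burn_in=400, thin=1), seed=0
        )
        assert (prevalence_estimates(post)["mean"] < 0.05).all()

    def test_record_order_invariance(self, tiny_config):
        recs = simulate_resistance_survey(tiny_config)
        sched = MCMCSchedule(chains=1, draws=100, burn_in=200, thin=1)
        post1 = fit_resistance(recs, mcmc=sched, seed=5)
        post2 = fit_resistance(list(reversed(recs)), mcmc=sched, seed=5)
        # sums over records are permutation invariant, so the chains agree
        np.testing.assert_allclose(post1.zeta, post2.zeta)
        np.testing.assert_allclose(post1.sigma2_g_logit, post2.sigma2_g_logit)

    def test_requires_two_phenotypes_and_groups(self):
        recs = [SurveyRecord("p", 2003, Phenotype.A, 1, False, None)] * 50
        with pytest.raises(ValueError):
            fit_resistance(recs)

    def test_draws_frame_roundtrip(self, tiny_config):
        recs = simulate_resistance_survey(tiny_config)
        post = fit_resistance(
            recs, mcmc=MCMCSchedule(chains=2, draws=50, burn_in=100, thin=1), seed=2
        )
        frame = post.to_frame()
        again = ResistancePosterior.from_frame(frame)
        np.testing.assert_allclose(again.zeta, post.zeta)
        np.testing.assert_allclose(again.eta, post.eta)
        np.testing.assert_allclose(again.sigma2_g_log, post.sigma2_g_log)


def test_fixed_effect_interval_coverage():
    """Over replicated small surveys, the 95% credible intervals for the
    prevalence effects should cover the generating values most of the time
    (loose 80% bound on 20 replicates)."""
    zeta_true = math.log(0.25 / 0.75)
    eta_true = math.log(2.0)
    sched = MCMCSchedule(chains=1, draws=300, burn_in=500, thin=1)
    covered = 0
    reps = 20
    for rep in range(reps):
        cfg = _norebalance_config(zeta_true, eta_true, n=150, seed=100 + rep)
        cfg.resistance.sigma2_group_logit = 0.05
        cfg.resistance.sigma2_group_log = 0.02
        # match the fitted model's fixed unit-logit variance
        cfg.resistance.sigma2_unit_logit = 1.0
        cfg.resistance.sigma2_unit_log = 0.05
        recs = simulate_resistance_survey(cfg)
        post = fit_resistance(recs, mcmc=sched, seed=rep)
        lo, hi = np.percentile(post.zeta[:, :, 0], [2.5, 97.5])
        covered += lo <= zeta_true <= hi
    assert covered >= 0.8 * reps
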