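"""Tolerance-GLMM transforms, contrasts, predictions and recovery."""

import math

import numpy as np
import pytest

from mitedef import MCMCSchedule
from mitedef.data_model import records_to_frame
from mitedef.synthetic_data import simulate_fecundity_survey
from mitedef.tolerance_glmm import (
    TolerancePosterior,
    fit_tolerance,
    intercept_contrast,
    percent_decrease_per_mite,
    predict_fecundity,
    variance_partition,
)

from conftest import small_config

QUICK = MCMCSchedule(chains=2, draws=500, burn_in=800, thin=1)


def _point_posterior(alpha_a, alpha_i, beta_a, beta_i, s2u1=1e-4, s2eps=0.25):
    shape = (2, 40)
    return TolerancePosterior(
        morphs=("A", "I"),
        alpha=np.stack(
            [np.full(shape, alpha_a), np.full(shape, alpha_i)], axis=-1
        ),
        beta=np.stack([np.full(shape, beta_a), np.full(shape, beta_i)], axis=-1),
        sigma2_u0=np.full(shape, 0.01),
        cov_u01=np.full(shape, 0.0),
        sigma2_u1=np.full(shape, s2u1),
        sigma2_eps=np.full(shape, s2eps),
    )


class TestTransforms:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.0, 0.0), (math.log(0.963), 3.7), (math.log(0.917), 8.3)],
    )
    def test_percent_decrease_per_mite(self, beta, expected):
        s = percent_decrease_per_mite(np.full(100, beta))
        assert s["mean"] == pytest.approx(expected, abs=1e-9)
        assert s["ci_low"] == s["ci_high"] == pytest.approx(expected, abs=1e-9)

    def test_percent_decrease_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            percent_decrease_per_mite(np.array([0.0, np.nan]))

    def test_intercept_contrast_identical_morphs(self):
        post = _point_posterior(5.0, 5.0, -0.05, -0.05)
        c = intercept_contrast(post)
        assert c["difference"]["mean"] == pytest.approx(0.0)
        assert c["ratio"]["mean"] == pytest.approx(1.0)

    def test_intercept_contrast_reported_arithmetic(self):
        # the two published statements are mutually consistent:
        # 322.4 - 242.4 = 80.0 and 322.4/242.4 = 1.33
        post = _point_posterior(math.log(242.4), math.log(322.4), -0.04, -0.09)
        c = intercept_contrast(post)
        assert c["difference"]["mean"] == pytest.approx(80.0, abs=1e-9)
        assert c["ratio"]["mean"] == pytest.approx(1.33, abs=0.001)


class TestPredictFecundity:
    def test_zero_mites_returns_intercept(self):
        post = _point_posterior(math.log(242.4), math.log(322.4), -0.05, -0.05)
        pred = predict_fecundity(post, "A", [0])
        assert pred["mean"].iloc[0] == pytest.approx(242.4)

    def test_reference_point_prediction(self):
        # 242.4 * 0.963**10 = 166.4 eggs
        post = _point_posterior(math.log(242.4), 5.0, math.log(0.963), -0.05)
        pred = predict_fecundity(post, "A", [10])
        assert pred["mean"].iloc[0] == pytest.approx(242.4 * 0.963**10, abs=0.05)
        assert pred["mean"].iloc[0] == pytest.approx(166.26, abs=0.05)

    def test_monotone_decreasing_and_positive(self):
        post = _point_posterior(math.log(242.4), math.log(322.4), math.log(0.963),
                                math.log(0.917))
        pred = predict_fecundity(post, "I", range(0, 57))
        assert (pred["mean"].diff().dropna() < 0).all()
        assert (pred["mean"] > 0).all()

    def test_reaction_norms_cross_once(self):
        # higher intercept + steeper slope for I: the curves cross exactly once
        post = _point_posterior(math.log(242.4), math.log(322.4), math.log(0.963),
                                math.log(0.917))
        grid = range(0, 57)
        gap = (
            predict_fecundity(post, "I", grid)["mean"]
            - predict_fecundity(post, "A", grid)["mean"]
        )
        signs = np.sign(gap)
        assert (np.diff(signs) != 0).sum() == 1

    def test_negative_grid_rejected(self):
        with pytest.raises(ValueError):
            predict_fecundity(_point_posterior(5, 5, 0, 0), "A", [-1])


class TestVariancePartition:
    def test_equal_variances_give_half(self):
        post = _point_posterior(5, 5, 0, 0, s2eps=0.01)
        post.sigma2_u0[:] = 0.01
        assert variance_partition(post)["mean"] == pytest.approx(0.5)

    def test_zero_group_variance_gives_zero(self):
        post = _point_posterior(5, 5, 0, 0)
        post.sigma2_u0[:] = 0.0
        assert variance_partition(post)["mean"] == pytest.approx(0.0)

    def test_resistance_process_selector(self):
        from test_resistance_zap import _degenerate_posterior

        rpost = _degenerate_posterior()
        assert variance_partition(rpost, "logit")["mean"] == pytest.approx(0.5)
        assert variance_partition(rpost, "log")["mean"] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            variance_partition(rpost, "probit")


class TestFitTolerance:
    def test_null_slopes_recovered(self):
        cfg = small_config(
            seed=21, beta={"A": 0.0, "I": 0.0}, sigma2_intercept=0.01,
            sigma2_slope=1e-6, cov_intercept_slope=0.0, sigma2_resid=0.2,
        )
        recs = simulate_fecundity_survey(cfg)
        post = fit_tolerance(recs, mcmc=QUICK, seed=4)
        for m in ("A", "I"):
            lo, hi = np.percentile(post.beta_draws(m), [2.5, 97.5])
            assert lo < 0.0 < hi

    def test_matches_poisson_glm_oracle_without_random_effects(self):
        """With no group heterogeneity and no over-dispersion the posterior
        slope means must agree with the maximum-likelihood log-linear
        Poisson regression fitted to the same data."""
        import statsmodels.api as sm

        cfg = small_config(
            seed=22, sigma2_intercept=0.0, sigma2_slope=0.0,
            cov_intercept_slope=0.0, sigma2_resid=0.0,
        )
        recs = simulate_fecundity_survey(cfg)
        df = records_to_frame(recs)
        a = (df.phenotype == "A").to_numpy(float)
        i = (df.phenotype == "I").to_numpy(float)
        x = df.mites.to_numpy(float)
        design = np.column_stack([a, i, a * x, i * x])
        mle = sm.GLM(df.eggs.to_numpy(), design, family=sm.families.Poisson()).fit()
        post = fit_tolerance(recs, mcmc=QUICK, seed=5)
        for mi, m in enumerate(("A", "I")):
            assert post.beta_draws(m).mean() == pytest.approx(
                mle.params[2 + mi], abs=3e-3
            )
            assert post.alpha_draws(m).mean() == pytest.approx(
                mle.params[mi], abs=0.02
            )

    def test_single_morph_input_rejected(self, tiny_config):
        recs = [
            r for r in simulate_fecundity_survey(tiny_config) if r.phenotype.value == "A"
        ]
        with pytest.raises(ValueError, match="slope contrast"):
            fit_tolerance(recs)

    def test_draws_frame_roundtrip(self, tiny_config):
        recs = simulate_fecundity_survey(tiny_config)
        post = fit_tolerance(
            recs, mcmc=MCMCSchedule(chains=2, draws=50, burn_in=100, thin=1), seed=2
        )
        again = TolerancePosterior.from_frame(post.to_frame())
        np.testing.assert_allclose(again.beta, post.beta)
        np.testing.assert_allclose(again.sigma2_u1, post.sigma2_u1)
        np.testing.assert_allclose(again.cov_u01, post.cov_u01)


def test_slope_interval_coverage():
    """95% credible intervals for the morph slopes cover the generating
    values in most of 20 cheap replicates (loose 80% bound)."""
    sched = MCMCSchedule(chains=1, draws=300, burn_in=600, thin=1)
    covered = 0
    reps = 20
    for rep in range(reps):
        cfg = small_config(seed=300 + rep)
        cfg.design.n_mated_per_group = {"A": 25, "I": 15}
        recs = simulate_fecundity_survey(cfg)
        post = fit_tolerance(recs, mcmc=sched, seed=rep)
        lo, hi = np.percentile(post.beta_draws("A"), [2.5, 97.5])
        covered += lo <= cfg.tolerance.beta["A"] <= hi
    assert covered >= 0.8 * reps
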