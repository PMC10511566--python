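"""Bayesian model fitting: coefficient recovery, convergence
diagnostics, posterior prediction, predictive checks."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import hdnorms as hn
from hdnorms.design import build_design

from .conftest import brute_force_split_rhat, strong_nonlinear_truth


class TestFitAgainstOls:
    def test_flat_prior_posterior_matches_least_squares(self, config, truth, mcmc_fast):
        """With flat coefficient priors the Gaussian-likelihood posterior
        mean equals the least-squares solution up to Monte-Carlo error."""
        demo = hn.sample_demographics(config, 500, seed=21)
        coh = hn.sample_scores(demo, truth, seed=22, tests=["sdmt"])
        spec = hn.ModelSpec("sdmt", "lmr")
        fit = hn.fit_model(spec, coh, mcmc_fast)
        dm = build_design(spec, coh.dropna(subset=["sdmt"]).reset_index(drop=True))
        ols, *_ = np.linalg.lstsq(dm.X, coh["sdmt"].to_numpy(), rcond=None)
        post_mean = fit.coef.reshape(-1, fit.coef.shape[-1]).mean(axis=0)
        post_sd = fit.coef.reshape(-1, fit.coef.shape[-1]).std(axis=0)
        # MC error of a posterior mean over >=600 effective draws
        np.testing.assert_array_less(np.abs(post_mean - ols), 0.35 * post_sd + 1e-8)

    def test_sigma_recovery(self, config, mcmc_fast):
        tp = hn.TruthParams(
            "sdmt", 50.0, hn.AgeCurve(0.5), hn.EduCurve(5.0), 1.0,
            {l: 0.0 for l in hn.LANGUAGES}, 5.0,
        )
        demo = hn.sample_demographics(config, 1000, seed=23)
        coh = hn.sample_scores(demo, {"sdmt": tp}, seed=24, tests=["sdmt"])
        fit = hn.fit_model(hn.ModelSpec("sdmt", "gam"), coh, mcmc_fast)
        assert 4.5 < fit.sigma.mean() < 5.5

    def test_paper_profile_retains_4000_draws(self, cohort_small):
        cfg = hn.McmcConfig.paper_profile(seed=1)
        assert cfg.retained_draws == 4000
        fit = hn.fit_model(
            hn.ModelSpec("sdmt", "lmr", ("age", "gender")), cohort_small, cfg
        )
        assert fit.coef.shape[:2] == (4, 1000)
        assert fit.log_lik.shape[:2] == (4, 1000)

    def test_tmt_nonpositive_rejected(self, cohort_small):
        bad = cohort_small.copy()
        bad.loc[bad.index[0], "tmta"] = 0.0
        with pytest.raises(ValueError, match="log"):
            hn.fit_model(hn.ModelSpec("tmta", "lmr"), bad)

    def test_testwise_deletion(self, cohort_small, mcmc_fast):
        df = cohort_small.copy()
        df.loc[df.index[:30], "lft"] = np.nan
        fit = hn.fit_model(hn.ModelSpec("lft", "lmr", ("age",)), df, mcmc_fast)
        assert fit.n_obs == len(df) - 30


class TestParameterRecovery:
    def test_planted_gender_and_language_recovered(self, sdmt_gam_fit):
        """Posterior concentrates near the planted effects (n=1500)."""
        g = sdmt_gam_fit.coef_draws("female")
        assert abs(g.mean() - 2.78) < 3.5 * g.std()
        de = sdmt_gam_fit.coef_draws("lang[de]")
        assert abs(de.mean() - (-2.86)) < 3.5 * de.std()

    def test_interval_coverage_over_replicates(self, config, truth):
        """95% credible intervals cover the planted gender/language
        effects in >= 90% of 20 replicate fits."""
        mcmc = hn.McmcConfig(chains=2, iterations=500, warmup=250, seed=0)
        spec = hn.ModelSpec("sdmt", "gam")
        cover_g = cover_l = 0
        for rep in range(20):
            demo = hn.sample_demographics(config, 600, seed=300 + rep)
            coh = hn.sample_scores(demo, truth, seed=400 + rep, tests=["sdmt"])
            fit = hn.fit_model(spec, coh, dataclasses.replace(mcmc, seed=rep))
            g = np.quantile(fit.coef_draws("female"), [0.025, 0.975])
            cover_g += g[0] <= 2.78 <= g[1]
            d = np.quantile(fit.coef_draws("lang[de]"), [0.025, 0.975])
            cover_l += d[0] <= -2.86 <= d[1]
        assert cover_g >= 18
        assert cover_l >= 18

    def test_gam_smooth_recovers_planted_age_curve(self, config):
        truth = strong_nonlinear_truth()
        demo = hn.sample_demographics(config, 2000, seed=25)
        coh = hn.sample_scores(demo, truth, seed=26, tests=["sdmt"])
        fit = hn.fit_model(
            hn.ModelSpec("sdmt", "gam"), coh, hn.McmcConfig(chains=2, iterations=800, warmup=400, seed=27)
        )
        ages = np.linspace(20, 84, 60)
        grid = pd.DataFrame(
            {"age": ages, "edu_years": 14.0, "sex": "m", "lang": "en"}
        )
        mu, _, _ = fit.predict_grid(grid)
        planted = truth["sdmt"].f_age(ages)
        r = np.corrcoef(mu - mu.mean(), planted - planted.mean())[0, 1]
        assert r > 0.95


class TestConvergence:
    def test_well_mixed_fit_passes(self, sdmt_gam_fit):
        diag = hn.check_convergence(sdmt_gam_fit)
        assert diag.max_rhat < 1.01
        assert diag.passed
        assert diag.divergences == 0

    def test_non_mixing_chains_flagged(self, sdmt_gam_fit):
        broken = dataclasses.replace(
            sdmt_gam_fit,
            coef=np.concatenate(
                [np.zeros_like(sdmt_gam_fit.coef[:1]), np.ones_like(sdmt_gam_fit.coef[:1])]
            ),
        )
        diag = hn.check_convergence(broken)
        assert not diag.passed
        assert diag.max_rhat > 2.0 or not np.isfinite(diag.max_rhat)

    def test_single_chain_rejected(self, cohort_small):
        fit = hn.fit_model(
            hn.ModelSpec("sdmt", "lmr", ("age",)), cohort_small,
            hn.McmcConfig(chains=1, iterations=200, warmup=100, seed=1),
        )
        with pytest.raises(ValueError, match="chains"):
            hn.check_convergence(fit)

    def test_split_rhat_matches_direct_formula(self, sdmt_gam_fit):
        """arviz's split-R-hat agrees with a from-scratch implementation
        of the between/within variance formula."""
        diag = hn.check_convergence(sdmt_gam_fit)
        for j, name in enumerate(sdmt_gam_fit.coef_names[:5]):
            direct = brute_force_split_rhat(sdmt_gam_fit.coef[:, :, j])
            assert diag.rhat[name] == pytest.approx(direct, abs=1e-6)


class TestPosteriorPredict:
    def test_degenerate_posterior_collapses_to_linear_predictor(self, sdmt_gam_fit):
        point = dataclasses.replace(
            sdmt_gam_fit,
            coef=np.broadcast_to(
                sdmt_gam_fit.coef.mean(axis=(0, 1)), sdmt_gam_fit.coef.shape
            ).copy(),
            sigma=np.full_like(sdmt_gam_fit.sigma, 1e-12),
        )
        pred = point.posterior_predict(50, 14, "f", "en")
        x, _ = hn.design_row(point.info, 50, 14, "f", "en")
        assert pred.sd_pred == pytest.approx(0.0, abs=1e-9)
        assert pred.mu_hat == pytest.approx(float(x @ sdmt_gam_fit.coef.mean(axis=(0, 1))))

    def test_predictive_sd_exceeds_residual_sd(self, sdmt_gam_fit):
        rms_sigma = np.sqrt((sdmt_gam_fit.sigma ** 2).mean())
        for age, edu in [(20, 8), (48, 14), (80, 20)]:
            pred = sdmt_gam_fit.posterior_predict(age, edu, "f", "en")
            assert pred.sd_pred >= rms_sigma

    def test_95_interval_calibrated_on_fresh_data(self, config, truth, sdmt_gam_fit):
        fresh = hn.sample_scores(
            hn.sample_demographics(config, 2000, seed=28), truth, seed=29, tests=["sdmt"]
        )
        mu, sd, _ = sdmt_gam_fit.predict_grid(fresh)
        y = fresh["sdmt"].to_numpy()
        inside = np.mean((y > mu - 1.96 * sd) & (y < mu + 1.96 * sd))
        assert abs(inside - 0.95) < 0.02

    def test_extrapolation_flagged(self, sdmt_gam_fit):
        assert sdmt_gam_fit.posterior_predict(17.0, 14, "f", "en").extrapolated

    def test_log_scale_monotone_transform_invariance(self, tmta_fit):
        """Exponentiating predictive quantiles equals quantiles of
        exponentiated draws."""
        x, _ = hn.design_row(tmta_fit.info, 50, 14, "m", "en")
        rng = np.random.default_rng(0)
        eta = tmta_fit.linear_predictor(x[None, :])[:, 0]
        draws = rng.normal(eta, tmta_fit.sigma.reshape(-1))
        for q in (0.05, 0.5, 0.95):
            # order statistics commute exactly with a monotone transform
            assert np.exp(np.quantile(draws, q, method="lower")) == pytest.approx(
                np.quantile(np.exp(draws), q, method="lower"), rel=1e-12
            )


class TestPosteriorPredictiveCheck:
    def test_replicate_count_and_null_discrepancy(self, cohort_mid, sdmt_gam_fit):
        out = hn.posterior_predictive_check(sdmt_gam_fit, cohort_mid, n_rep=15, seed=3)
        assert out["replicates"].shape == (15, sdmt_gam_fit.n_obs)
        # well-specified model: KS distances sit in the small-null band
        assert out["ks_distance"].mean() < 0.05

    def test_misspecified_model_shows_larger_discrepancy(self, config, mcmc_fast):
        truth = strong_nonlinear_truth()
        coh = hn.sample_scores(
            hn.sample_demographics(config, 800, seed=31), truth, seed=32, tests=["sdmt"]
        )
        gam = hn.fit_model(hn.ModelSpec("sdmt", "gam"), coh, mcmc_fast)
        lmr = hn.fit_model(hn.ModelSpec("sdmt", "lmr"), coh, mcmc_fast)
        ks_g = hn.posterior_predictive_check(gam, coh, n_rep=20, seed=4)["ks_distance"]
        ks_l = hn.posterior_predictive_check(lmr, coh, n_rep=20, seed=4)["ks_distance"]
        assert np.mean(ks_l > ks_g.mean()) >= 0.9


def test_save_load_round_trip(sdmt_gam_fit, tmp_path):
    sdmt_gam_fit.save(tmp_path / "bundle")
    back = hn.FittedNormativeModel.load(tmp_path / "bundle")
    a = back.posterior_predict(48, 14, "f", "de")
    b = sdmt_gam_fit.posterior_predict(48, 14, "f", "de")
    assert a.mu_hat == pytest.approx(b.mu_hat)
    assert a.sd_pred == pytest.approx(b.sd_pred)
    assert back.coef_names == sdmt_gam_fit.coef_names
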