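"""Synthetic cohort generator: marginals, ground-truth oracles,
reproducibility, screening-violation injection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hdnorms as hn
from hdnorms.simulate import (
    TABLE1_AGE,
    TABLE1_EDU,
    TABLE1_P_FEMALE,
    TruncatedNormalSpec,
    match_truncated_normal,
)


class TestMomentMatching:
    @pytest.mark.parametrize("target", [TABLE1_AGE, TABLE1_EDU, {"mean": 40.0, "sd": 16.0, "low": 18.0, "high": 86.0}])
    def test_truncated_moments_hit_targets(self, target):
        mu, sigma = match_truncated_normal(**target)
        a, b = (target["low"] - mu) / sigma, (target["high"] - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        assert m == pytest.approx(target["mean"], abs=1e-6)
        assert np.sqrt(v) == pytest.approx(target["sd"], abs=1e-6)

    def test_heavy_truncation_needs_wider_parent(self):
        # with mean near a bound, the parent must be wider and shifted
        # past the bound to hit the target moments after truncation
        mu, sigma = match_truncated_normal(mean=75.0, sd=7.0, low=18.0, high=86.0)
        assert sigma > 7.0

    def test_mean_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            match_truncated_normal(mean=10.0, sd=5.0, low=18.0, high=86.0)


class TestSampleDemographics:
    def test_reproducible_bit_identical(self, config):
        a = hn.sample_demographics(config, 200, seed=42)
        b = hn.sample_demographics(config, 200, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cohort(self, config):
        df = hn.sample_demographics(config, 0, seed=1)
        assert len(df) == 0

    def test_point_mass_config_gives_identical_rows(self):
        cfg = hn.GeneratorConfig(
            age=TruncatedNormalSpec(48.0, 0.0, 18.0, 86.0),
            education=TruncatedNormalSpec(14.0, 0.0, 1.0, 24.0),
            p_female=1.0,
            language_freqs={"en": 1.0},
        )
        df = hn.sample_demographics(cfg, 50, seed=3)
        assert (df["age"] == 48.0).all()
        assert (df["edu_years"] == 14.0).all()
        assert (df["sex"] == "f").all()
        assert (df["lang"] == "en").all()

    def test_marginals_match_study_at_full_n(self, config):
        """Sampled moments within 3 Monte-Carlo SEs of the configured targets."""
        df = hn.sample_demographics(config, 3267, seed=7)
        se_age = TABLE1_AGE["sd"] / np.sqrt(3267)
        se_edu = TABLE1_EDU["sd"] / np.sqrt(3267)
        se_f = np.sqrt(TABLE1_P_FEMALE * (1 - TABLE1_P_FEMALE) / 3267)
        assert abs(df["age"].mean() - TABLE1_AGE["mean"]) < 3 * se_age
        assert abs(df["edu_years"].mean() - TABLE1_EDU["mean"]) < 3 * se_edu
        assert abs((df["sex"] == "f").mean() - TABLE1_P_FEMALE) < 3 * se_f
        # age/education SDs too
        assert df["age"].std() == pytest.approx(TABLE1_AGE["sd"], rel=0.05)
        assert df["edu_years"].std() == pytest.approx(TABLE1_EDU["sd"], rel=0.05)

    def test_invalid_language_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            hn.GeneratorConfig(language_freqs={"en": 0.5, "de": 0.4})

    def test_bundled_config_round_trip(self, config, tmp_path):
        loaded = hn.GeneratorConfig.from_json(hn.GeneratorConfig.bundled_config_path())
        assert loaded.age == config.age
        assert loaded.language_freqs == pytest.approx(config.language_freqs)


class TestTruthOracles:
    def test_constant_model(self):
        tp = hn.TruthParams(
            "sdmt", 50.0, hn.AgeCurve(0.0), hn.EduCurve(0.0), 0.0,
            {l: 0.0 for l in hn.LANGUAGES}, 5.0,
        )
        for age, edu, sex, lang in [(18, 1, "f", "en"), (86, 24, "m", "pl")]:
            assert hn.true_mean(tp, hn.TESTS["sdmt"], age, edu, sex, lang) == pytest.approx(50.0)
        assert isinstance(hn.true_mean(tp, hn.TESTS["sdmt"], 40, 12, "f", "en"), float)

    def test_polish_swrt_offset_shifts_mean_exactly(self, truth):
        tp = truth["swrt"]
        m_pl = hn.true_mean(tp, hn.TESTS["swrt"], 40, 12, "f", "pl")
        m_en = hn.true_mean(tp, hn.TESTS["swrt"], 40, 12, "f", "en")
        assert float(m_pl - m_en) == pytest.approx(-7.80)

    def test_age_curve_monotone_decline_on_grid(self, truth):
        grid = np.linspace(18, 86, 300)
        mu = truth["sdmt"].mean(grid, np.full_like(grid, 14.0), ["m"] * 300, ["en"] * 300)
        assert np.all(np.diff(mu) <= 1e-12)

    def test_education_curve_increasing_concave(self, truth):
        grid = np.linspace(1, 24, 200)
        f = truth["sdmt"].f_edu(grid)
        assert np.all(np.diff(f) > 0)
        assert np.all(np.diff(f, 2) < 1e-12)

    def test_unknown_language_rejected(self, truth):
        with pytest.raises(ValueError, match="language"):
            hn.true_mean(truth["sdmt"], hn.TESTS["sdmt"], 40, 12, "f", "xx")


class TestSampleScores:
    def test_zero_noise_reproduces_truth(self, config, truth):
        demo = hn.sample_demographics(config, 40, seed=9)
        noiseless = {t: dataclasses.replace(tp, sigma=0.0) for t, tp in truth.items()}
        coh = hn.sample_scores(demo, noiseless, seed=10)
        mu = noiseless["sdmt"].mean(demo["age"], demo["edu_years"], demo["sex"], demo["lang"])
        np.testing.assert_allclose(coh["sdmt"], mu, rtol=1e-12)
        mu_t = noiseless["tmta"].mean(demo["age"], demo["edu_years"], demo["sex"], demo["lang"])
        np.testing.assert_allclose(coh["tmta"], np.exp(mu_t), rtol=1e-12)

    def test_planted_gender_offset_recovered_in_sample_means(self, config, truth):
        demo = hn.sample_demographics(config, 20000, seed=11)
        coh = hn.sample_scores(demo, truth, seed=12, tests=["sdmt"])
        f = coh.loc[coh.sex == "f", "sdmt"]
        m = coh.loc[coh.sex == "m", "sdmt"]
        # raw group difference also picks up demographic imbalance noise
        se = np.sqrt(f.var() / len(f) + m.var() / len(m))
        assert abs((f.mean() - m.mean()) - 2.78) < 4 * se + 0.3

    def test_lognormal_median_identity(self, config, truth):
        tp = dataclasses.replace(truth["tmta"], sigma=0.3)
        demo = hn.sample_demographics(config, 20000, seed=13)
        coh = hn.sample_scores(demo, {"tmta": tp}, seed=14, tests=["tmta"])
        mu = tp.mean(demo["age"], demo["edu_years"], demo["sex"], demo["lang"])
        # median of a log-normal equals exp of its log-scale location
        assert np.median(coh["tmta"] / np.exp(mu)) == pytest.approx(1.0, abs=0.02)

    def test_clip_rate_below_one_percent_under_defaults(self, config, truth):
        demo = hn.sample_demographics(config, 3267, seed=15)
        coh = hn.sample_scores(demo, truth, seed=16)
        for t, c in coh.attrs["clip_counts"].items():
            assert c / 3267 < 0.01, t


class TestTrueZscore:
    def test_centered_raw_gives_zero(self, truth):
        tp, spec = truth["sdmt"], hn.TESTS["sdmt"]
        mu = hn.true_mean(tp, spec, 50, 12, "f", "en")
        assert hn.true_zscore(tp, spec, 50, 12, "f", "en", mu) == pytest.approx(0.0)

    def test_slow_tmt_time_scores_negative(self, truth):
        tp, spec = truth["tmta"], hn.TESTS["tmta"]
        mu = hn.true_mean(tp, spec, 50, 12, "f", "en")
        slow = np.exp(mu) * 2.0
        assert hn.true_zscore(tp, spec, 50, 12, "f", "en", slow) < 0

    def test_hand_computed_example(self):
        # fully written-out parameter set, z checked by hand:
        # mean = 40 - 1*((55-35)/10)^2 + 6*(1-exp(-(13-1)/6)) + 2 (female)
        #      = 40 - 4 + 6*(1-e^-2) + 2 = 43.18808...
        tp = hn.TruthParams(
            "sdmt", 40.0, hn.AgeCurve(1.0), hn.EduCurve(6.0), 2.0,
            {l: 0.0 for l in hn.LANGUAGES}, 4.0,
        )
        mu = 40 - 4 + 6 * (1 - np.exp(-2.0)) + 2
        z = hn.true_zscore(tp, hn.TESTS["sdmt"], 55, 13, "f", "en", mu + 6.0)
        assert z == pytest.approx(1.5, abs=1e-12)

    def test_nonpositive_raw_rejected_for_log_tests(self, truth):
        with pytest.raises(ValueError, match="positive"):
            hn.true_zscore(truth["tmta"], hn.TESTS["tmta"], 50, 12, "f", "en", 0.0)

    def test_zscore_calibration_standard_normal(self, config, truth):
        """Oracle z of freshly sampled scores is standard normal."""
        demo = hn.sample_demographics(config, 10000, seed=17)
        coh = hn.sample_scores(demo, truth, seed=18, tests=["sdmt", "tmtb"])
        for t in ("sdmt", "tmtb"):
            z = hn.true_zscore(
                truth[t], hn.TESTS[t], demo["age"], demo["edu_years"],
                demo["sex"], demo["lang"], coh[t],
            )
            assert abs(z.mean()) < 0.04
            assert 0.97 < z.std() < 1.03

    def test_language_shift_identity_exact(self, truth):
        """z(lang=L, raw) == z(EN, raw - Delta_L) for identity-scale tests."""
        tp, spec = truth["swrt"], hn.TESTS["swrt"]
        for lang in ("pl", "de", "es", "it"):
            delta = tp.beta_language[lang]
            z_l = hn.true_zscore(tp, spec, 34, 13, "f", lang, 77.0)
            z_en = hn.true_zscore(tp, spec, 34, 13, "f", "en", 77.0 - delta)
            assert z_l == pytest.approx(z_en, abs=1e-12)


class TestInjectViolations:
    def test_zero_rates_leave_cohort_unchanged(self, cohort_small):
        out = hn.inject_screening_violations(cohort_small, {}, seed=1)
        base_cols = [c for c in out.columns if not c.startswith("injected_")]
        pd.testing.assert_frame_equal(out[base_cols], cohort_small[base_cols])

    def test_saturated_hads_rate_violates_every_row(self, cohort_small):
        out = hn.inject_screening_violations(cohort_small, {"hads": 1.0}, seed=2)
        assert (out["hads"] > 10).all()

    def test_expected_survival_is_product_of_rates(self, config, truth):
        demo = hn.sample_demographics(config, 8000, seed=19)
        rates = {"hads": 0.1, "mmse": 0.2, "non_native": 0.05}
        out = hn.inject_screening_violations(demo, rates, seed=20)
        kept, _ = hn.apply_filters(out)
        p = (1 - 0.1) * (1 - 0.2) * (1 - 0.05)
        se = np.sqrt(p * (1 - p) / 8000)
        assert abs(len(kept) / 8000 - p) < 4 * se

    def test_invalid_rate_rejected(self, cohort_small):
        with pytest.raises(ValueError):
            hn.inject_screening_violations(cohort_small, {"hads": 1.5}, seed=0)


def test_cohort_csv_round_trip(cohort_small, tmp_path):
    path = tmp_path / "cohort.csv"
    hn.write_cohort(cohort_small, path)
    back = hn.read_cohort(path)
    assert list(back.columns) == list(cohort_small.columns)
    assert len(back) == len(cohort_small)
    np.testing.assert_allclose(back["sdmt"], cohort_small["sdmt"], rtol=1e-5)
    assert (back["lang"] == cohort_small["lang"]).all()


def test_simulation_fully_seeded_end_to_end(config, truth):
    a = hn.sample_scores(hn.sample_demographics(config, 100, seed=5), truth, seed=6)
    b = hn.sample_scores(hn.sample_demographics(config, 100, seed=5), truth, seed=6)
    pd.testing.assert_frame_equal(a, b)
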