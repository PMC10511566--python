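"""Shared fixtures: study-calibrated configs, synthetic cohorts, and a
few session-scoped fitted models reused across test modules."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import hdnorms as hn
from hdnorms.simulate import AgeCurve, EduCurve, TruthParams


@pytest.fixture(scope="session")
def config() -> hn.GeneratorConfig:
    return hn.GeneratorConfig.table1_default()

@pytest.fixture(scope="session")
def truth(config) -> dict[str, hn.TruthParams]:
    return hn.default_truth(config)


@pytest.fixture(scope="session")
def mcmc_fast() -> hn.McmcConfig:
    return hn.McmcConfig(chains=2, iterations=600, warmup=300, seed=0)


@pytest.fixture(scope="session")
def cohort_small(config, truth):
    """n=600 cohort with all eight scores."""
    demo = hn.sample_demographics(config, 600, seed=101)
    return hn.sample_scores(demo, truth, seed=102)


@pytest.fixture(scope="session")
def cohort_mid(config, truth):
    """n=1500 cohort used for the session model fits."""
    demo = hn.sample_demographics(config, 1500, seed=103)
    return hn.sample_scores(demo, truth, seed=104)


@pytest.fixture(scope="session")
def sdmt_gam_fit(cohort_mid) -> hn.FittedNormativeModel:
    """Full additive SDMT model on the mid-size cohort."""
    return hn.fit_model(
        hn.ModelSpec("sdmt", "gam"), cohort_mid, hn.McmcConfig(chains=2, iterations=800, warmup=400, seed=105)
    )


@pytest.fixture(scope="session")
def swrt_fit_nogender(cohort_mid) -> hn.FittedNormativeModel:
    """Additive SWRT model excluding gender (the selected SWRT form)."""
    spec = hn.ModelSpec("swrt", "gam", ("age", "education", "language"))
    return hn.fit_model(spec, cohort_mid, hn.McmcConfig(chains=2, iterations=800, warmup=400, seed=106))


@pytest.fixture(scope="session")
def tmta_fit(cohort_mid) -> hn.FittedNormativeModel:
    return hn.fit_model(
        hn.ModelSpec("tmta", "gam"), cohort_mid, hn.McmcConfig(chains=2, iterations=600, warmup=300, seed=107)
    )


def strong_nonlinear_truth(
    beta_gender: float = 2.78,
    language_effects: dict[str, float] | None = None,
) -> dict[str, TruthParams]:
    """SDMT-like ground truth with a pronounced age nonlinearity: the
    misfit of the best linear age fit is about half the residual SD, so
    additive and linear models are clearly separable at n of a few
    hundred."""
    betas = {l: 0.0 for l in hn.LANGUAGES}
    if language_effects:
        betas.update(language_effects)
    return {
        "sdmt": TruthParams(
            test_id="sdmt",
            intercept=62.0,
            f_age=AgeCurve(1.6),
            f_edu=EduCurve(9.0),
            beta_gender=beta_gender,
            beta_language=betas,
            sigma=5.0,
        )
    }


def brute_force_split_rhat(x: np.ndarray) -> float:
    """Direct split-R-hat: split each chain in half, then the classic
    between/within variance ratio.  x has shape (chains, draws)."""
    c, n = x.shape
    half = n // 2
    chains = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n2 = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n2 * means.var(ddof=1)
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def brute_force_hdi(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Exhaustive scan over all contiguous sorted windows holding
    ceil(level*n) draws."""
    x = np.sort(np.asarray(draws))
    n = len(x)
    m = int(np.ceil(level * n))
    best = (np.inf, 0)
    for i in range(n - m + 1):
        width = x[i + m - 1] - x[i]
        if width < best[0]:
            best = (width, i)
    i = best[1]
    return float(x[i]), float(x[i + m - 1])
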