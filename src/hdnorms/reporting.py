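"""Stratified table norms and posterior effect summaries.

Table norms report per-cell n / mean / SD stratified by age band (the
study's ten bands, read as left-closed right-open intervals), an
education dichotomy (<= 12 vs > 12 years), gender and language.  Effect
summaries report posterior means with 95% highest-density intervals;
gender/language effects on the log-modelled TMT tests are exponentiated
and reported as multiplicative ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .battery import LANGUAGES, REFERENCE_LANGUAGE, TEST_IDS
from .models import FittedNormativeModel
from .simulate import AGE_GROUP_EDGES

DEFAULT_STRATA = ("age_group", "edu_band", "sex", "lang")


def hdi(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Highest-density interval: the shortest contiguous interval of
    sorted draws containing ceil(level * n) of them."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 draws for a stable HDI")
    m = int(np.ceil(level * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def _age_band_labels() -> list[str]:
    edges = AGE_GROUP_EDGES
    return [f"[{edges[i]},{edges[i + 1]})" for i in range(len(edges) - 1)]


def build_norm_table(
    cohort: pd.DataFrame,
    strata: tuple[str, ...] = DEFAULT_STRATA,
    tests: tuple[str, ...] | None = None,
    edu_cut: float = 12.0,
) -> pd.DataFrame:
    """Per-cell (n, M, SD) table norms.

    `strata` selects the grouping keys from {age_group, edu_band, sex,
    lang}; an empty tuple yields whole-sample rows.  Education years of
    exactly `edu_cut` fall in the lower band.  SD uses the n-1
    denominator and is NaN for cells with fewer than two observations.
    Returns a long table with one row per (test, cell).
    """
    bad = set(strata) - set(DEFAULT_STRATA)
    if bad:
        raise ValueError(f"unknown strata: {sorted(bad)}")
    tests = tests or tuple(t for t in TEST_IDS if t in cohort.columns)
    df = cohort.copy()
    if len(df):
        df["age_group"] = pd.cut(
            df["age"], bins=list(AGE_GROUP_EDGES), right=False, labels=_age_band_labels()
        )
        df["edu_band"] = np.where(df["edu_years"] <= edu_cut, f"<={edu_cut:g}", f">{edu_cut:g}")
    rows = []
    for test in tests:
        sub = df.dropna(subset=[test]) if len(df) else df
        if len(sub) == 0:
            continue
        groups = sub.groupby(list(strata), observed=True) if strata else [((), sub)]
        for key, g in groups:
            key = key if isinstance(key, tuple) else (key,)
            vals = g[test].to_numpy(dtype=float)
            rows.append(
                {
                    "test": test,
                    **dict(zip(strata, key)),
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EffectSummary:
    test_id: str
    effect: str
    mean: float
    hdi95: tuple[float, float]
    scale: str  # "additive" or "ratio"


def _effect_draws(fit: FittedNormativeModel, name: str) -> tuple[np.ndarray, str]:
    """Posterior draws for one coefficient, ratio-transformed for log tests."""
    draws = fit.coef_draws(name)
    if fit.test.transform == "log":
        return np.exp(draws), "ratio"
    return draws, "additive"


def summarize_gender_effect(fit: FittedNormativeModel, level: float = 0.95) -> EffectSummary:
    """Female-minus-male effect (positive = females score higher).

    For log-modelled tests the summary is the multiplicative ratio
    exp(coefficient), so 1.0 means no difference.
    """
    if "gender" not in fit.spec.predictors:
        raise ValueError("effect not in model: gender was not a predictor")
    draws, scale = _effect_draws(fit, "female")
    return EffectSummary(
        test_id=fit.spec.test_id,
        effect="gender (female - male)",
        mean=float(np.mean(draws)),
        hdi95=hdi(draws, level),
        scale=scale,
    )


def summarize_language_effects(
    fit: FittedNormativeModel, reference: str = REFERENCE_LANGUAGE, level: float = 0.95
) -> pd.DataFrame:
    """Per-language posterior mean + 95% HDI relative to the reference.

    The reference row is identically zero (additive scale; the table is
    always reported additively on the model scale, i.e. log units for
    TMT, matching how such offsets are conventionally printed).
    """
    if "language" not in fit.spec.predictors:
        raise ValueError("effect not in model: language was not a predictor")
    fitted_levels = [REFERENCE_LANGUAGE] + list(fit.info.language_levels)
    if reference not in fitted_levels:
        raise ValueError(f"reference {reference!r} not among fitted levels {fitted_levels}")

    def draws_for(lang: str) -> np.ndarray:
        if lang == REFERENCE_LANGUAGE:
            return np.zeros(fit.mcmc.retained_draws)
        return fit.coef_draws(f"lang[{lang}]")

    ref_draws = draws_for(reference)
    rows = []
    for lang in [l for l in LANGUAGES if l in fitted_levels]:
        d = draws_for(lang) - ref_draws
        if lang == reference:
            mean, lo, hi = 0.0, 0.0, 0.0
        else:
            mean = float(np.mean(d))
            lo, hi = hdi(d, level)
        rows.append(
            {"lang": lang, "mean": mean, "hdi_lo": lo, "hdi_hi": hi,
             "scale": "log" if fit.test.transform == "log" else "additive"}
        )
    return pd.DataFrame(rows)
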