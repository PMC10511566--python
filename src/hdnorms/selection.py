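"""Predictive model comparison via PSIS-LOO.

Candidate models per test form a ladder: each of the two families
(linear, additive) fitted with all four predictors and with each single
predictor dropped in turn — ten fits.  Out-of-sample predictive accuracy
is estimated by Pareto-smoothed importance-sampling leave-one-out
cross-validation; models are ranked on LOO-IC = -2 * elpd_loo, and a
difference counts as significant when the normal 95% CI of the paired
pointwise difference excludes zero.  Per-observation Pareto k-hat values
above 0.5 flag observations whose importance weights are unreliable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd

from .design import PREDICTORS, ModelSpec
from .models import FittedNormativeModel, McmcConfig, fit_model

PARETO_K_THRESHOLD = 0.5


@dataclass
class LooResult:
    elpd: float
    se: float
    pointwise: np.ndarray  # per-observation elpd contributions
    pareto_k: np.ndarray
    n: int

    @property
    def loo_ic(self) -> float:
        return -2.0 * self.elpd

    @property
    def loo_ic_se(self) -> float:
        return 2.0 * self.se

    @property
    def n_high_k(self) -> int:
        return int(np.sum(self.pareto_k >= PARETO_K_THRESHOLD))


@dataclass
class ModelComparison:
    """Paired LOO-IC difference (a minus b); negative favors a."""

    delta_loo_ic: float
    se_diff: float
    ci95: tuple[float, float]

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return lo > 0 or hi < 0


def compute_loo(fit: FittedNormativeModel) -> LooResult:
    if not np.all(np.isfinite(fit.log_lik)):
        raise ValueError("non-finite entries in the pointwise log-likelihood")
    res = az.loo(fit.to_inference_data(), pointwise=True)
    return LooResult(
        elpd=float(res.elpd_loo),
        se=float(res.se),
        pointwise=np.asarray(res.loo_i.values, dtype=float),
        pareto_k=np.asarray(res.pareto_k.values, dtype=float),
        n=fit.n_obs,
    )


def compare_models(a: LooResult, b: LooResult) -> ModelComparison:
    """Compare two models fitted to the same observations.

    The SE of the difference comes from the paired pointwise elpd
    contributions (sqrt(n) * sd of the per-observation differences), and
    the CI is the normal 1.96-SE interval on the LOO-IC scale.
    """
    if a.n != b.n or len(a.pointwise) != len(b.pointwise):
        raise ValueError("models were not fitted to the same observations")
    diff = a.pointwise - b.pointwise
    delta_elpd = float(np.sum(diff))
    se_elpd = float(np.sqrt(len(diff)) * np.std(diff, ddof=1)) if len(diff) > 1 else 0.0
    delta = -2.0 * delta_elpd
    se = 2.0 * se_elpd
    return ModelComparison(
        delta_loo_ic=delta, se_diff=se, ci95=(delta - 1.96 * se, delta + 1.96 * se)
    )


@dataclass
class SelectionResult:
    """Ranked ladder for one test."""

    test_id: str
    table: pd.DataFrame  # one row per candidate, ranked by LOO-IC
    fits: dict[str, FittedNormativeModel]
    loos: dict[str, LooResult]
    best_label: str  # minimum LOO-IC
    selected_label: str  # after parsimony tie-breaking
    comparisons: dict[str, ModelComparison] = field(default_factory=dict)

    @property
    def selected(self) -> FittedNormativeModel:
        return self.fits[self.selected_label]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "test_id": self.test_id,
                "best": self.best_label,
                "selected": self.selected_label,
                "candidates": self.table.to_dict(orient="records"),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc


def ladder_specs(test_id: str) -> list[ModelSpec]:
    """The ten candidate specs: {LMR, GAM} x {full, drop-one}."""
    specs = []
    for form in ("lmr", "gam"):
        specs.append(ModelSpec(test_id, form, PREDICTORS))
        for drop in PREDICTORS:
            preds = tuple(p for p in PREDICTORS if p != drop)
            specs.append(ModelSpec(test_id, form, preds))
    return specs


def _parsimony_key(spec: ModelSpec) -> tuple[int, int]:
    return (len(spec.predictors), 0 if spec.form == "lmr" else 1)


def run_selection_ladder(
    cohort: pd.DataFrame,
    test_id: str,
    mcmc: McmcConfig | None = None,
    min_per_language: int = 50,
) -> SelectionResult:
    """Fit the full candidate ladder for one test and rank by LOO-IC.

    The minimum-LOO-IC model is 'best'; every other candidate is
    compared to it, and among the candidates whose difference from the
    best is not significant the simplest one (fewest predictors, linear
    before additive) is 'selected'.
    """
    mcmc = mcmc or McmcConfig()
    specs = ladder_specs(test_id)
    fits: dict[str, FittedNormativeModel] = {}
    loos: dict[str, LooResult] = {}
    for spec in specs:
        fit = fit_model(spec, cohort, mcmc, min_per_language=min_per_language)
        fits[spec.label] = fit
        loos[spec.label] = compute_loo(fit)

    best_label = min(loos, key=lambda k: loos[k].loo_ic)
    comparisons = {
        label: compare_models(loos[label], loos[best_label])
        for label in loos
        if label != best_label
    }
    tied = [best_label] + [l for l, c in comparisons.items() if not c.significant]
    selected_label = min(tied, key=lambda l: _parsimony_key(fits[l].spec))

    rows = []
    for label, loo in loos.items():
        cmp_ = comparisons.get(label)
        rows.append(
            {
                "label": label,
                "form": fits[label].spec.form,
                "predictors": "+".join(fits[label].spec.predictors),
                "loo_ic": loo.loo_ic,
                "loo_ic_se": loo.loo_ic_se,
                "elpd": loo.elpd,
                "n_high_pareto_k": loo.n_high_k,
                "delta_loo_ic_vs_best": 0.0 if cmp_ is None else cmp_.delta_loo_ic,
                "ci_lo": 0.0 if cmp_ is None else cmp_.ci95[0],
                "ci_hi": 0.0 if cmp_ is None else cmp_.ci95[1],
                "significant_vs_best": False if cmp_ is None else cmp_.significant,
            }
        )
    table = pd.DataFrame(rows).sort_values("loo_ic", ignore_index=True)
    return SelectionResult(
        test_id=test_id,
        table=table,
        fits=fits,
        loos=loos,
        best_label=best_label,
        selected_label=selected_label,
        comparisons=comparisons,
    )
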