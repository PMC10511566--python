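"""Inclusion/exclusion screening for the normative cohort.

Participants enter the normative sample only if they were assessed at
baseline, in their native language, with corrected vision and hearing,
have education and language recorded, show no evidence of ongoing
depression (HADS <= 10; scores above 10 are removed), and pass the
cognitive screen (MMSE > 26; scores of 26 or below are removed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .battery import TEST_IDS

#: Criterion keys in the narrative screening order.
DEFAULT_ORDER = (
    "baseline_only",
    "native_language",
    "corrected_vision_hearing",
    "education_language_present",
    "hads",
    "mmse",
)


@dataclass(frozen=True)
class FilterCriteria:
    baseline_only: bool = True
    require_native_language: bool = True
    require_corrected_vision_hearing: bool = True
    require_education_and_language_present: bool = True
    hads_max: float = 10.0  # retained iff HADS <= hads_max
    mmse_min_exclusive: float = 26.0  # retained iff MMSE > this
    drop_missing_screens: bool = False  # rows with missing HADS/MMSE kept by default
    order: tuple[str, ...] = DEFAULT_ORDER

    def __post_init__(self) -> None:
        if not 0 <= self.hads_max <= 21:
            raise ValueError("hads_max outside the HADS range 0-21")
        if not 0 <= self.mmse_min_exclusive <= 30:
            raise ValueError("mmse_min_exclusive outside the MMSE range 0-30")
        if set(self.order) != set(DEFAULT_ORDER):
            raise ValueError(f"order must be a permutation of {DEFAULT_ORDER}")


@dataclass
class FilterReport:
    """Per-criterion attrition; counts telescope step to step."""

    steps: list[dict] = field(default_factory=list)
    final_n: int = 0

    def add(self, criterion: str, n_before: int, n_removed: int) -> None:
        self.steps.append(
            {
                "criterion": criterion,
                "n_before": n_before,
                "n_removed": n_removed,
                "n_after": n_before - n_removed,
            }
        )

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({"steps": self.steps, "final_n": self.final_n}, indent=2)
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    def to_text(self) -> str:
        lines = [f"{'criterion':<30} {'before':>8} {'removed':>8} {'after':>8}"]
        for s in self.steps:
            lines.append(
                f"{s['criterion']:<30} {s['n_before']:>8} {s['n_removed']:>8} {s['n_after']:>8}"
            )
        lines.append(f"{'final':<30} {'':>8} {'':>8} {self.final_n:>8}")
        return "\n".join(lines)


def _require(cohort: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort is missing required column(s): {missing}")


def _keep_mask(cohort: pd.DataFrame, criterion: str, c: FilterCriteria) -> pd.Series | None:
    """Row-retention mask for one criterion, or None if it is disabled."""
    if criterion == "baseline_only":
        if not c.baseline_only:
            return None
        _require(cohort, ["visit"])
        return cohort["visit"] == cohort.groupby("subjid")["visit"].transform("min")
    if criterion == "native_language":
        if not c.require_native_language:
            return None
        _require(cohort, ["native_lang"])
        return cohort["native_lang"].astype(bool)
    if criterion == "corrected_vision_hearing":
        if not c.require_corrected_vision_hearing:
            return None
        _require(cohort, ["corrected_vision_hearing"])
        return cohort["corrected_vision_hearing"].astype(bool)
    if criterion == "education_language_present":
        if not c.require_education_and_language_present:
            return None
        _require(cohort, ["edu_years", "lang"])
        return cohort["edu_years"].notna() & cohort["lang"].notna()
    if criterion == "hads":
        _require(cohort, ["hads"])
        bad = cohort["hads"] > c.hads_max
        if c.drop_missing_screens:
            bad = bad | cohort["hads"].isna()
        return ~bad
    if criterion == "mmse":
        _require(cohort, ["mmse"])
        bad = cohort["mmse"] <= c.mmse_min_exclusive
        if c.drop_missing_screens:
            bad = bad | cohort["mmse"].isna()
        return ~bad
    raise ValueError(f"unknown criterion {criterion!r}")


def apply_filters(
    cohort: pd.DataFrame, criteria: FilterCriteria | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the screening chain; returns the surviving rows and the
    per-step attrition report.

    The surviving set is order-invariant (criteria are conjunctive); the
    report's step counts follow ``criteria.order``.
    """
    criteria = criteria or FilterCriteria()
    report = FilterReport()
    kept = cohort
    for criterion in criteria.order:
        mask = _keep_mask(kept, criterion, criteria)
        if mask is None:
            continue
        n_before = len(kept)
        kept = kept[mask]
        report.add(criterion, n_before, n_before - len(kept))
    report.final_n = len(kept)
    return kept.copy(), report


def summarize_battery_completeness(cohort: pd.DataFrame) -> dict:
    """Non-missing counts per test plus the complete-battery count
    (participants with all eight scores present)."""
    present = [t for t in TEST_IDS if t in cohort.columns]
    per_test = {t: int(cohort[t].notna().sum()) for t in present}
    if present:
        complete = int(np.all(cohort[present].notna(), axis=1).sum())
    else:
        complete = 0
    return {"per_test": per_test, "all_complete": complete, "n": len(cohort)}
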