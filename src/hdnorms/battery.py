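"""Metadata for the Enroll-HD cognitive battery.

The battery comprises eight timed tests: the Symbol Digit Modalities Test
(SDMT, 90 s), the three Stroop subtests (word reading SWRT, color naming
SCNT, interference SIT; 45 s each, number of correct responses), the Trail
Making Test parts A and B (completion time in seconds, capped at 240 s),
and letter/category verbal fluency (LFT/CFT, 60 s).

For six tests a higher raw score means better performance.  TMT-A/B are
timed to completion, so lower is better; they are also strongly
right-skewed and are modelled on the natural-log scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Direction = Literal["higher_better", "lower_better"]
Transform = Literal["identity", "log"]


@dataclass(frozen=True)
class TestSpec:
    """Scoring metadata for one cognitive test."""

    test_id: str
    name: str
    direction: Direction
    transform: Transform
    min_score: float
    max_score: float
    time_limit: float  # seconds, administration metadata

    @property
    def lower_better(self) -> bool:
        return self.direction == "lower_better"

    def check_raw(self, raw: float) -> None:
        """Validate a raw score against the admissible range."""
        if not (self.min_score <= raw <= self.max_score):
            raise ValueError(
                f"{self.test_id}: raw score {raw} outside admissible range "
                f"[{self.min_score}, {self.max_score}]"
            )
        if self.transform == "log" and raw <= 0:
            raise ValueError(f"{self.test_id}: log-scale test requires raw > 0")


# Admissible ranges follow the observed ranges of the normative sample
# (TMT capped at the 240 s administration limit; counts bounded by items).
TESTS: dict[str, TestSpec] = {
    t.test_id: t
    for t in [
        TestSpec("sdmt", "Symbol Digit Modalities Test", "higher_better", "identity", 0, 110, 90),
        TestSpec("cft", "Category Fluency Test", "higher_better", "identity", 0, 60, 60),
        TestSpec("scnt", "Stroop Color Naming Test", "higher_better", "identity", 0, 150, 45),
        TestSpec("swrt", "Stroop Word Reading Test", "higher_better", "identity", 0, 180, 45),
        TestSpec("sit", "Stroop Interference Test", "higher_better", "identity", 0, 125, 45),
        TestSpec("tmta", "Trail Making Test, Part A", "lower_better", "log", 1, 240, 240),
        TestSpec("tmtb", "Trail Making Test, Part B", "lower_better", "log", 1, 240, 240),
        TestSpec("lft", "Letter Fluency Test", "higher_better", "identity", 0, 100, 180),
    ]
}

TEST_IDS: tuple[str, ...] = tuple(TESTS)

# Language codes in descending order of frequency in the normative sample.
LANGUAGES: tuple[str, ...] = ("en", "de", "es", "it", "pl", "fr_ca", "nl", "es_la", "fr", "da")
REFERENCE_LANGUAGE = "en"

LANGUAGE_NAMES: dict[str, str] = {
    "en": "English",
    "de": "German",
    "es": "Spanish",
    "it": "Italian",
    "pl": "Polish",
    "fr_ca": "Canadian French",
    "fr": "French",
    "nl": "Dutch",
    "es_la": "Latin-American Spanish",
    "da": "Danish",
}


def isced_from_education(years: float) -> int:
    """Map years of formal education to an approximate ISCED 0-6 level.

    The mapping is a convention of this package (ISCED levels are reported
    descriptively alongside years; only years enter the models): <1 year ->
    0 (early childhood), primary (>=1) -> 1, lower secondary (>=6) -> 2,
    upper secondary (>=10) -> 3, post-secondary (>=13) -> 4, short-cycle
    tertiary (>=15) -> 5, bachelor's-or-higher (>=17) -> 6.
    """
    if years < 1:
        return 0
    if years < 6:
        return 1
    if years < 10:
        return 2
    if years < 13:
        return 3
    if years < 15:
        return 4
    if years < 17:
        return 5
    return 6
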