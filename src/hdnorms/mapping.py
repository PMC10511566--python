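"""Normative probability mapping: raw scores to z, percentile, band.

A raw score is standardized against the model's posterior-predictive
distribution at the individual's demographics:

    z = (transform(raw) - mu_hat(d)) / sd_pred(d)

where mu_hat/sd_pred are the predictive mean and SD (coefficient
uncertainty plus residual noise).  For the timed TMT tests the transform
is the natural log and the resulting z is multiplied by -1 so that
negative z always means worse-than-expected performance.  Percentiles
are 100 * Phi(z); the qualitative band is keyed to z (the +/-1 band is
"normal", mirroring the convention that scores within one SD of the
expectation are unremarkable).

For calculator-style use the predictive mean/SD are precomputed on a
dense demographic grid (the lookup table); scoring against the table
rounds age/education to the nearest grid node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .battery import LANGUAGES, TESTS, TestSpec
from .models import FittedNormativeModel


@dataclass(frozen=True)
class NormativeScore:
    z: float
    percentile: float
    band: str
    extrapolated: bool = False


BANDS = (
    (-np.inf, -2.0, "markedly below (red)"),
    (-2.0, -1.0, "below (orange)"),
    (-1.0, 1.0, "normal (green)"),
    (1.0, np.inf, "above (blue)"),
)


def to_percentile(z: float) -> float:
    """Percentile = 100 * Phi(z); strictly increasing in z."""
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    return 100.0 * float(ndtr(z))


def classify(z: float) -> str:
    """Qualitative color band for a z-score.

    Boundaries: z < -2 red, -2 <= z < -1 orange, -1 <= z <= 1 green
    (both endpoints inside the normal band), z > 1 blue.
    """
    if -1.0 <= z <= 1.0:
        return "normal (green)"
    if z < -2.0:
        return "markedly below (red)"
    if z < -1.0:
        return "below (orange)"
    return "above (blue)"


def _score_from(mu: float, sd: float, test: TestSpec, raw: float, extrapolated: bool) -> NormativeScore:
    test.check_raw(raw)
    y = np.log(raw) if test.transform == "log" else raw
    z = (y - mu) / sd
    if test.lower_better:
        z = -z
    z = float(z)
    return NormativeScore(z=z, percentile=to_percentile(z), band=classify(z), extrapolated=extrapolated)


def compute_z(
    fit: FittedNormativeModel, age: float, edu: float, sex: str, lang: str, raw: float
) -> NormativeScore:
    """Normative score straight from a fitted model's predictive
    distribution at the given demographics."""
    pred = fit.posterior_predict(age, edu, sex, lang)
    return _score_from(pred.mu_hat, pred.sd_pred, fit.test, raw, pred.extrapolated)


# ---------------------------------------------------------------------------
# Lookup tables


@dataclass(frozen=True)
class GridSpec:
    """Dense demographic grid for calculator lookup tables.

    Quarter-year default steps keep the nearest-node rounding error
    below 0.05 z-units even where the fitted smooths are steepest (the
    sparsely observed age/education boundaries, where edge slopes of
    several raw points per year occur); a 1-year grid is enough for the
    interior but not for those edges.
    """

    age_min: float = 18.0
    age_max: float = 86.0
    age_step: float = 0.25
    edu_min: float = 1.0
    edu_max: float = 24.0
    edu_step: float = 0.25
    sexes: tuple[str, ...] = ("f", "m")
    languages: tuple[str, ...] = LANGUAGES

    def age_grid(self) -> np.ndarray:
        return np.round(np.arange(self.age_min, self.age_max + 1e-9, self.age_step), 10)

    def edu_grid(self) -> np.ndarray:
        return np.round(np.arange(self.edu_min, self.edu_max + 1e-9, self.edu_step), 10)

    @property
    def n_cells(self) -> int:
        return (
            len(self.age_grid()) * len(self.edu_grid()) * len(self.sexes) * len(self.languages)
        )


@dataclass
class LookupTable:
    """Per-cell predictive mean/SD over a complete demographic grid.

    One table may hold several tests (a `test` column); `mu` and `sd`
    are on the model scale (log seconds for TMT).
    """

    grid: GridSpec
    cells: pd.DataFrame  # columns: test, age, edu, sex, lang, mu, sd
    provenance: dict

    def __post_init__(self) -> None:
        tests = self.cells["test"].unique()
        expected = self.grid.n_cells * len(tests)
        if len(self.cells) != expected:
            raise ValueError(f"incomplete grid: {len(self.cells)} cells, expected {expected}")
        if self.cells[["mu", "sd"]].isna().any().any():
            raise ValueError("lookup table has missing cells")

    def lookup(self, test_id: str, age: float, edu: float, sex: str, lang: str) -> tuple[float, float]:
        """Nearest-node predictive (mu, sd); errors outside the grid hull."""
        g = self.grid
        if not (g.age_min <= age <= g.age_max):
            raise ValueError(f"age {age} outside table range [{g.age_min}, {g.age_max}]")
        if not (g.edu_min <= edu <= g.edu_max):
            raise ValueError(f"education {edu} outside table range [{g.edu_min}, {g.edu_max}]")
        if sex not in g.sexes:
            raise ValueError(f"unknown sex code {sex!r}")
        if lang not in g.languages:
            raise ValueError(f"unknown language {lang!r}; valid: {list(g.languages)}")
        ages, edus = g.age_grid(), g.edu_grid()
        a = ages[np.argmin(np.abs(ages - age))]
        e = edus[np.argmin(np.abs(edus - edu))]
        key = (test_id, a, e, sex, lang)
        if "_indexed" not in self.__dict__:  # lazy index cache for repeated lookups
            self.__dict__["_indexed"] = self.cells.set_index(
                ["test", "age", "edu", "sex", "lang"]
            ).sort_index()
        try:
            row = self.__dict__["_indexed"].loc[key]
        except KeyError:
            raise KeyError(f"no cell for {key}") from None
        return float(row["mu"]), float(row["sd"])

    def save(self, path: str | Path) -> None:
        """Persist as Parquet with a JSON provenance sidecar."""
        path = Path(path)
        self.cells.to_parquet(path)
        sidecar = {
            "grid": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.grid).items()
            },
            "provenance": self.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LookupTable":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        g = sidecar["grid"]
        grid = GridSpec(
            age_min=g["age_min"], age_max=g["age_max"], age_step=g["age_step"],
            edu_min=g["edu_min"], edu_max=g["edu_max"], edu_step=g["edu_step"],
            sexes=tuple(g["sexes"]), languages=tuple(g["languages"]),
        )
        return cls(grid=grid, cells=pd.read_parquet(path), provenance=sidecar["provenance"])


def build_lookup(
    fits: dict[str, FittedNormativeModel], grid: GridSpec | None = None
) -> LookupTable:
    """Evaluate each test's predictive mean/SD over the full grid.

    `fits` maps test_id -> selected fitted model.  Deterministic given
    the posterior draws.
    """
    grid = grid or GridSpec()
    if not fits:
        raise ValueError("no fitted models supplied")
    for tid in fits:
        if tid not in TESTS:
            raise KeyError(f"unknown test {tid!r}")
    ages, edus = grid.age_grid(), grid.edu_grid()
    base = pd.MultiIndex.from_product(
        [ages, edus, list(grid.sexes), list(grid.languages)],
        names=["age", "edu", "sex", "lang"],
    ).to_frame(index=False)
    base = base.rename(columns={"edu": "edu_years"})
    frames = []
    for tid, fit in fits.items():
        mu, sd, _ = fit.predict_grid(base)
        frames.append(
            pd.DataFrame(
                {
                    "test": tid,
                    "age": base["age"],
                    "edu": base["edu_years"],
                    "sex": base["sex"],
                    "lang": base["lang"],
                    "mu": mu,
                    "sd": sd,
                }
            )
        )
    cells = pd.concat(frames, ignore_index=True)
    provenance = {
        "models": {
            tid: {"label": fit.spec.label, "draws": fit.mcmc.retained_draws, "n_obs": fit.n_obs}
            for tid, fit in fits.items()
        }
    }
    return LookupTable(grid=grid, cells=cells, provenance=provenance)


def lookup_z(
    table: LookupTable, test_id: str, age: float, edu: float, sex: str, lang: str, raw: float
) -> NormativeScore:
    """Normative score from the lookup table (nearest grid node)."""
    mu, sd = table.lookup(test_id, age, edu, sex, lang)
    return _score_from(mu, sd, TESTS[test_id], raw, extrapolated=False)
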