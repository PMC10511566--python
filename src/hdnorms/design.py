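"""Design matrices for the normative regressions.

The linear baseline (LMR) uses intercept + linear age + linear education
+ a female indicator + treatment-coded language dummies with English as
the reference level.  The additive model (GAM) replaces each linear
age/education term with a penalized cubic B-spline smooth.

Smooths use the standard mixed-model reparameterization of P-splines:
a K-function B-spline basis B with a second-order difference penalty
D'D is split into its penalty null space (intercept + linear trend,
kept among the fixed effects) and a penalized part Z = B D'(DD')^-1
whose coefficients are i.i.d. Gaussian with a free smoothing scale.
This makes the Bayesian fit conditionally conjugate while remaining an
exact reparameterization of the usual penalized spline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .battery import LANGUAGES, REFERENCE_LANGUAGE, TESTS

Form = Literal["lmr", "gam"]
PREDICTORS = ("age", "education", "gender", "language")

_COLUMN_FOR = {"age": "age", "education": "edu_years"}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate normative model: test, functional form, predictors."""

    test_id: str
    form: Form
    predictors: tuple[str, ...] = PREDICTORS
    n_basis: int = 8  # B-spline basis size per smooth
    degree: int = 3
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.test_id not in TESTS:
            raise ValueError(f"unknown test {self.test_id!r}")
        bad = set(self.predictors) - set(PREDICTORS)
        if bad:
            raise ValueError(f"unknown predictors: {sorted(bad)}")
        if self.form not in ("lmr", "gam"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "gam" and not ({"age", "education"} & set(self.predictors)):
            raise ValueError("a GAM needs at least one continuous predictor to smooth")
        if self.n_basis < self.degree + self.penalty_order:
            raise ValueError("n_basis too small for the requested degree/penalty")

    @property
    def label(self) -> str:
        dropped = [p for p in PREDICTORS if p not in self.predictors]
        tag = "full" if not dropped else "-".join(["drop"] + dropped)
        return f"{self.test_id}:{self.form}:{tag}"


@dataclass
class SmoothInfo:
    """Frozen description of one fitted smooth (reproducible basis)."""

    var: str
    knots: np.ndarray  # full (padded) knot vector
    degree: int
    lo: float
    hi: float
    transform: np.ndarray  # (K, K - penalty_order): random-coef -> basis-coef map

    def basis(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Penalized design columns at x (clipped to the training range)
        and a per-row extrapolation mask."""
        x = np.asarray(x, dtype=float)
        out_of_range = (x < self.lo) | (x > self.hi)
        xc = np.clip(x, self.lo, self.hi)
        B = BSpline.design_matrix(xc, self.knots, self.degree).toarray()
        return B @ self.transform, out_of_range


def _difference_matrix(k: int, order: int) -> np.ndarray:
    D = np.eye(k)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D


def make_smooth(var: str, x: np.ndarray, n_basis: int, degree: int, order: int) -> SmoothInfo:
    """Clamped B-spline basis with interior knots at data quantiles.

    Quantile placement leaves wide outer intervals where observations
    are sparse, so the fitted function stays stiff near the boundaries
    instead of chasing a handful of tail points."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError(f"smooth for {var!r} needs a non-degenerate range")
    n_interior = n_basis - degree - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs)
    # guard against ties in heavily discrete data
    interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
    if np.any(np.diff(interior) <= 0):
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    D = _difference_matrix(n_basis, order)
    transform = D.T @ np.linalg.inv(D @ D.T)
    return SmoothInfo(var=var, knots=knots, degree=degree, lo=lo, hi=hi, transform=transform)


@dataclass
class DesignInfo:
    """Everything needed to rebuild design rows at prediction time."""

    spec: ModelSpec
    fixed_names: list[str]
    random_blocks: list[tuple[str, int]]  # (label, n columns)
    smooths: dict[str, SmoothInfo] = field(default_factory=dict)
    language_levels: list[str] = field(default_factory=list)  # non-reference, fitted order
    centers: dict[str, float] = field(default_factory=dict)  # linear-term centering
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_names)

    @property
    def n_random(self) -> int:
        return sum(q for _, q in self.random_blocks)

    @property
    def column_names(self) -> list[str]:
        names = list(self.fixed_names)
        for label, q in self.random_blocks:
            names.extend(f"{label}[{j}]" for j in range(q))
        return names


@dataclass
class DesignMatrices:
    X: np.ndarray  # (n, n_fixed + n_random), fixed block first
    info: DesignInfo
    extrapolated: np.ndarray  # per-row flag


def build_design(
    spec: ModelSpec, data: pd.DataFrame, info: DesignInfo | None = None
) -> DesignMatrices:
    """Build the model matrix for `data`.

    When `info` is None the design (knot placement, centering, language
    levels) is learned from `data` (training); otherwise rows are built
    against the stored training design, erroring on unseen language
    levels and flagging out-of-range continuous values.
    """
    n = len(data)
    fitting = info is None
    if fitting:
        info = DesignInfo(spec=spec, fixed_names=[], random_blocks=[])
    cols: list[np.ndarray] = [np.ones(n)]
    extrapolated = np.zeros(n, dtype=bool)
    if fitting:
        info.fixed_names = ["intercept"]

    for var in ("age", "education"):
        if var not in spec.predictors:
            continue
        x = data[_COLUMN_FOR[var]].to_numpy(dtype=float)
        if np.any(np.isnan(x)):
            raise ValueError(f"missing {var} values in design data")
        if fitting:
            info.centers[var] = float(np.mean(x))
            info.ranges[var] = (float(np.min(x)), float(np.max(x)))
            info.fixed_names.append(var)
        else:
            lo, hi = info.ranges[var]
            extrapolated |= (x < lo) | (x > hi)
        cols.append(x - info.centers[var])

    if "gender" in spec.predictors:
        sex = data["sex"].astype(str)
        bad = set(sex.unique()) - {"f", "m"}
        if bad:
            raise ValueError(f"unknown sex codes: {sorted(bad)}")
        cols.append((sex == "f").to_numpy(dtype=float))
        if fitting:
            info.fixed_names.append("female")

    if "language" in spec.predictors:
        lang = data["lang"].astype(str)
        if fitting:
            seen = set(lang.unique())
            if REFERENCE_LANGUAGE not in seen:
                raise ValueError("training data lack the reference language")
            info.language_levels = [
                l for l in LANGUAGES if l in seen and l != REFERENCE_LANGUAGE
            ]
            info.fixed_names.extend(f"lang[{l}]" for l in info.language_levels)
        known = set(info.language_levels) | {REFERENCE_LANGUAGE}
        unseen = set(lang.unique()) - known
        if unseen:
            raise ValueError(f"language level(s) not in fitted model: {sorted(unseen)}")
        for l in info.language_levels:
            cols.append((lang == l).to_numpy(dtype=float))

    # penalized smooth blocks after all fixed columns
    if spec.form == "gam":
        for var in ("age", "education"):
            if var not in spec.predictors:
                continue
            x = data[_COLUMN_FOR[var]].to_numpy(dtype=float)
            if fitting:
                sm = make_smooth(var, x, spec.n_basis, spec.degree, spec.penalty_order)
                info.smooths[var] = sm
                info.random_blocks.append((f"s({var})", sm.transform.shape[1]))
            Z, oob = info.smooths[var].basis(x)
            extrapolated |= oob
            cols.append(Z)

    X = np.column_stack(cols)
    return DesignMatrices(X=X, info=info, extrapolated=extrapolated)


def design_row(info: DesignInfo, age: float, edu: float, sex: str, lang: str) -> tuple[np.ndarray, bool]:
    """Single design row for one individual's demographics."""
    df = pd.DataFrame({"age": [age], "edu_years": [edu], "sex": [sex], "lang": [lang]})
    dm = build_design(info.spec, df, info=info)
    return dm.X[0], bool(dm.extrapolated[0])
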