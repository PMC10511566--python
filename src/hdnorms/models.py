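"""Bayesian fitting of the normative regressions.

Both model families — the linear baseline and the penalized-spline
additive model — are Gaussian regressions that are conditionally
conjugate once the spline smooths are written in mixed-model form
(see :mod:`hdnorms.design`).  They are therefore sampled with a blocked
Gibbs sampler:

1. all regression coefficients jointly from their multivariate-normal
   full conditional (one Cholesky solve per sweep);
2. the residual variance from an inverse-gamma full conditional;
3. each smooth's variance from an inverse-gamma full conditional.

Priors: improper flat priors on the slope/offset coefficients, a wide
Gaussian on the intercept centered at the response median (SD = 10x the
response SD), and half-Student-t (nu=3) priors scaled to the response SD
on the residual and smoothing scales, implemented through their
inverse-gamma scale-mixture representation so every update stays exact.
The joint coefficient update makes the chain mix essentially as one
draw per sweep, so modest chain lengths give well-converged posteriors.

TMT-A/B responses are log-transformed before fitting; every fit stores
its pointwise log-likelihood matrix for PSIS-LOO model comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy import linalg, stats

from .battery import TESTS, TestSpec
from .design import DesignInfo, DesignMatrices, ModelSpec, SmoothInfo, build_design, design_row

logger = logging.getLogger(__name__)

_HALF_T_NU = 3.0  # df of the half-t priors on scale parameters


@dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration.

    The study profile runs 4 chains of 2000 iterations with a 1000-draw
    warm-up (4000 retained draws); the desk profile (default) halves
    everything, which this sampler's mixing makes ample.
    """

    chains: int = 2
    iterations: int = 1000
    warmup: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @classmethod
    def paper_profile(cls, seed: int = 0) -> "McmcConfig":
        return cls(chains=4, iterations=2000, warmup=1000, seed=seed)

    @property
    def retained_draws(self) -> int:
        return self.chains * (self.iterations - self.warmup)


@dataclass
class PredictiveSummary:
    """Posterior-predictive location/scale for one individual, on the
    model scale (raw score, or log seconds for TMT)."""

    mu_hat: float
    sd_pred: float
    interval: tuple[float, float]
    extrapolated: bool


@dataclass
class Diagnostics:
    rhat: dict[str, float]
    max_rhat: float
    divergences: int
    passed: bool


@dataclass
class FittedNormativeModel:
    """Posterior draws and design information for one test/model spec."""

    spec: ModelSpec
    mcmc: McmcConfig
    info: DesignInfo
    coef: np.ndarray  # (chains, draws, p)
    sigma: np.ndarray  # (chains, draws)
    tau: np.ndarray  # (chains, draws, n_smooths)
    log_lik: np.ndarray  # (chains, draws, n_obs)
    n_obs: int
    response_summary: dict

    @property
    def coef_names(self) -> list[str]:
        return self.info.column_names

    @property
    def test(self) -> TestSpec:
        return TESTS[self.spec.test_id]

    def coef_draws(self, name: str) -> np.ndarray:
        """Flattened posterior draws for one named coefficient."""
        try:
            j = self.coef_names.index(name)
        except ValueError:
            raise KeyError(f"no coefficient {name!r}; have {self.coef_names}") from None
        return self.coef[:, :, j].reshape(-1)

    def to_inference_data(self) -> az.InferenceData:
        posterior = {
            name: self.coef[:, :, j] for j, name in enumerate(self.coef_names)
        }
        posterior["sigma"] = self.sigma
        for j, (label, _) in enumerate(self.info.random_blocks):
            posterior[f"tau_{label}"] = self.tau[:, :, j]
        return az.from_dict(posterior=posterior, log_likelihood={"y": self.log_lik})

    # -- prediction -----------------------------------------------------

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """Draws of eta = X beta, shape (total draws, n rows)."""
        flat = self.coef.reshape(-1, self.coef.shape[-1])
        return flat @ X.T

    def posterior_predict(self, age: float, edu: float, sex: str, lang: str) -> PredictiveSummary:
        """Predictive mean/SD on the model scale, integrating coefficient
        uncertainty and residual noise; flags extrapolation beyond the
        training age/education range."""
        x, extrapolated = design_row(self.info, age, edu, sex, lang)
        eta = self.linear_predictor(x[None, :])[:, 0]
        sig2 = (self.sigma.reshape(-1) ** 2).mean()
        mu_hat = float(eta.mean())
        sd_pred = float(np.sqrt(eta.var() + sig2))
        if extrapolated:
            logger.warning("prediction outside the fitted age/education range")
        return PredictiveSummary(
            mu_hat=mu_hat,
            sd_pred=sd_pred,
            interval=(mu_hat - 1.96 * sd_pred, mu_hat + 1.96 * sd_pred),
            extrapolated=extrapolated,
        )

    def predict_grid(
        self, data: pd.DataFrame, chunk: int = 20_000
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized predictive mean/SD for many rows, chunked so the
        draws-by-rows intermediate stays bounded."""
        dm = build_design(self.spec, data, info=self.info)
        sig2 = (self.sigma.reshape(-1) ** 2).mean()
        n = dm.X.shape[0]
        mu = np.empty(n)
        sd = np.empty(n)
        for start in range(0, n, chunk):
            eta = self.linear_predictor(dm.X[start : start + chunk])
            mu[start : start + chunk] = eta.mean(axis=0)
            sd[start : start + chunk] = np.sqrt(eta.var(axis=0) + sig2)
        return mu, sd, dm.extrapolated

    # -- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize as <path>.json (metadata) + <path>.npz (draws)."""
        path = Path(path)
        meta = {
            "spec": {
                "test_id": self.spec.test_id,
                "form": self.spec.form,
                "predictors": list(self.spec.predictors),
                "n_basis": self.spec.n_basis,
                "degree": self.spec.degree,
                "penalty_order": self.spec.penalty_order,
            },
            "mcmc": vars(self.mcmc),
            "info": {
                "fixed_names": self.info.fixed_names,
                "random_blocks": self.info.random_blocks,
                "language_levels": self.info.language_levels,
                "centers": self.info.centers,
                "ranges": {k: list(v) for k, v in self.info.ranges.items()},
                "smooths": {
                    k: {
                        "var": s.var,
                        "degree": s.degree,
                        "lo": s.lo,
                        "hi": s.hi,
                    }
                    for k, s in self.info.smooths.items()
                },
            },
            "n_obs": self.n_obs,
            "response_summary": self.response_summary,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")
        arrays = {
            "coef": self.coef,
            "sigma": self.sigma,
            "tau": self.tau,
            "log_lik": self.log_lik,
        }
        for k, s in self.info.smooths.items():
            arrays[f"smooth_knots_{k}"] = s.knots
            arrays[f"smooth_transform_{k}"] = s.transform
        np.savez_compressed(path.with_suffix(".npz"), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FittedNormativeModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arrays = np.load(path.with_suffix(".npz"))
        spec = ModelSpec(
            test_id=meta["spec"]["test_id"],
            form=meta["spec"]["form"],
            predictors=tuple(meta["spec"]["predictors"]),
            n_basis=meta["spec"]["n_basis"],
            degree=meta["spec"]["degree"],
            penalty_order=meta["spec"]["penalty_order"],
        )
        smooths = {
            k: SmoothInfo(
                var=s["var"],
                knots=arrays[f"smooth_knots_{k}"],
                degree=s["degree"],
                lo=s["lo"],
                hi=s["hi"],
                transform=arrays[f"smooth_transform_{k}"],
            )
            for k, s in meta["info"]["smooths"].items()
        }
        info = DesignInfo(
            spec=spec,
            fixed_names=meta["info"]["fixed_names"],
            random_blocks=[tuple(b) for b in meta["info"]["random_blocks"]],
            smooths=smooths,
            language_levels=meta["info"]["language_levels"],
            centers=meta["info"]["centers"],
            ranges={k: tuple(v) for k, v in meta["info"]["ranges"].items()},
        )
        return cls(
            spec=spec,
            mcmc=McmcConfig(**meta["mcmc"]),
            info=info,
            coef=arrays["coef"],
            sigma=arrays["sigma"],
            tau=arrays["tau"],
            log_lik=arrays["log_lik"],
            n_obs=meta["n_obs"],
            response_summary=meta["response_summary"],
        )


# ---------------------------------------------------------------------------
# Gibbs sampler


def _slice_sample(logf, x0: float, rng: np.random.Generator, w: float = 1.0,
                  max_steps: int = 50, lo: float = -12.0, hi: float = 12.0) -> float:
    """Univariate stepping-out slice sampler (bounded support)."""
    fx0 = logf(x0)
    height = fx0 - rng.exponential()
    u = rng.random()
    left = max(x0 - w * u, lo)
    right = min(left + w, hi)
    steps = max_steps
    while steps > 0 and left > lo and logf(left) > height:
        left = max(left - w, lo)
        steps -= 1
    steps = max_steps
    while steps > 0 and right < hi and logf(right) > height:
        right = min(right + w, hi)
        steps -= 1
    while True:
        x1 = rng.uniform(left, right)
        if logf(x1) >= height:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _gibbs_chain(
    X: np.ndarray,
    y: np.ndarray,
    blocks: list[tuple[int, int]],
    mcmc: McmcConfig,
    chain_seed: int,
    intercept_prior: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One chain; returns retained (coef, sigma, tau) draws.

    Smoothing scales are updated by slice sampling their *collapsed*
    conditional (all regression coefficients integrated out in closed
    form), which breaks the strong tau-coefficient coupling that makes
    the naive conditional update mix slowly.
    """
    rng = np.random.default_rng(chain_seed)
    n, p = X.shape
    nu = _HALF_T_NU
    XtX = X.T @ X
    Xty = X.T @ y
    sd_y = float(np.std(y)) or 1.0
    m0, s0 = intercept_prior

    prior_prec_fixed = np.zeros(p)
    prior_prec_fixed[0] = 1.0 / s0**2
    prior_b = np.zeros(p)
    prior_b[0] = m0 / s0**2

    def chol_mean(sigma2: float, tau2: np.ndarray):
        prec = prior_prec_fixed.copy()
        for j, (lo_, hi_) in enumerate(blocks):
            prec[lo_:hi_] = 1.0 / tau2[j]
        P = XtX / sigma2 + np.diag(prec)
        L = linalg.cholesky(P, lower=True)
        b = Xty / sigma2 + prior_b
        mean = linalg.cho_solve((L, True), b)
        return L, mean, b

    def log_collapsed_tau(j: int, log_tau: float, sigma2: float, tau2: np.ndarray) -> float:
        """log p(tau_j | y, sigma2, tau_-j) up to a constant."""
        t2 = tau2.copy()
        t2[j] = np.exp(2.0 * log_tau)
        L, mean, b = chol_mean(sigma2, t2)
        q = blocks[j][1] - blocks[j][0]
        # log |Lambda_j|^(1/2) = -q log tau;  log |P|^(1/2) = sum log L_ii
        log_half_det_lambda = -q * log_tau
        log_half_det_P = float(np.sum(np.log(np.diag(L))))
        tau = np.exp(log_tau)
        # half-t(nu) prior on tau plus the log-scale Jacobian
        log_prior = -(nu + 1.0) / 2.0 * np.log1p(tau**2 / (nu * sd_y**2)) + log_tau
        return log_half_det_lambda - log_half_det_P + 0.5 * float(b @ mean) + log_prior

    sigma2 = sd_y**2
    a_sigma = 1.0
    tau2 = np.full(len(blocks), sd_y**2)
    log_tau = 0.5 * np.log(tau2) if len(blocks) else np.empty(0)

    kept = mcmc.iterations - mcmc.warmup
    coef_out = np.empty((kept, p))
    sigma_out = np.empty(kept)
    tau_out = np.zeros((kept, max(len(blocks), 1)))

    for it in range(mcmc.iterations):
        # 1. smoothing scales from their collapsed conditionals
        for j in range(len(blocks)):
            log_tau[j] = _slice_sample(
                lambda lt: log_collapsed_tau(j, lt, sigma2, tau2), log_tau[j], rng
            )
            tau2[j] = np.exp(2.0 * log_tau[j])

        # 2. joint coefficient draw
        L, mean, _ = chol_mean(sigma2, tau2)
        theta = mean + linalg.solve_triangular(L, rng.standard_normal(p), lower=True, trans="T")

        # 3. residual variance (half-t prior via inverse-gamma mixture)
        resid = y - X @ theta
        rss = float(resid @ resid)
        sigma2 = stats.invgamma.rvs(
            (nu + n) / 2.0, scale=nu / a_sigma + rss / 2.0, random_state=rng
        )
        a_sigma = stats.invgamma.rvs(
            (nu + 1) / 2.0, scale=nu / sigma2 + 1.0 / sd_y**2, random_state=rng
        )

        if it >= mcmc.warmup:
            k = it - mcmc.warmup
            coef_out[k] = theta
            sigma_out[k] = np.sqrt(sigma2)
            if len(blocks):
                tau_out[k, : len(blocks)] = np.sqrt(tau2)

    return coef_out, sigma_out, tau_out[:, : max(len(blocks), 1)]


def fit_model(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    mcmc: McmcConfig | None = None,
    min_per_language: int = 50,
) -> FittedNormativeModel:
    """Fit one normative model to a (filtered) cohort.

    Rows missing this test's score are dropped (test-wise deletion).
    TMT responses are log-transformed; non-positive times are an error.
    Language levels with fewer observations than `min_per_language` are
    reported with a warning, mirroring the caution the norms attach to
    sparsely observed languages.
    """
    mcmc = mcmc or McmcConfig()
    test = TESTS[spec.test_id]
    data = cohort.dropna(subset=[spec.test_id]).reset_index(drop=True)
    if len(data) == 0:
        raise ValueError(f"no observations with a {spec.test_id} score")
    raw = data[spec.test_id].to_numpy(dtype=float)
    if test.transform == "log":
        if np.any(raw <= 0):
            raise ValueError(f"{spec.test_id}: non-positive values cannot be log-transformed")
        y = np.log(raw)
    else:
        y = raw

    if "language" in spec.predictors:
        counts = data["lang"].value_counts()
        sparse = counts[counts < min_per_language]
        if len(sparse):
            logger.warning(
                "%s: language level(s) with < %d observations: %s",
                spec.test_id, min_per_language, dict(sparse),
            )

    dm = build_design(spec, data)
    X = dm.X
    n_fixed = dm.info.n_fixed
    blocks = []
    offset = n_fixed
    for _, q in dm.info.random_blocks:
        blocks.append((offset, offset + q))
        offset += q

    med, sd_y = float(np.median(y)), float(np.std(y)) or 1.0
    intercept_prior = (med, 10.0 * sd_y)

    kept = mcmc.iterations - mcmc.warmup
    p = X.shape[1]
    coef = np.empty((mcmc.chains, kept, p))
    sigma = np.empty((mcmc.chains, kept))
    tau = np.zeros((mcmc.chains, kept, max(len(blocks), 1)))
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    for c, ss in enumerate(seeds):
        coef[c], sigma[c], tau[c] = _gibbs_chain(
            X, y, blocks, mcmc, ss.generate_state(1)[0], intercept_prior
        )

    # pointwise log-likelihood per retained draw
    log_lik = np.empty((mcmc.chains, kept, len(y)))
    for c in range(mcmc.chains):
        eta = coef[c] @ X.T  # (kept, n)
        s = sigma[c][:, None]
        log_lik[c] = -0.5 * np.log(2 * np.pi * s**2) - (y[None, :] - eta) ** 2 / (2 * s**2)
    if not np.all(np.isfinite(log_lik)):
        raise FloatingPointError("non-finite pointwise log-likelihood")

    return FittedNormativeModel(
        spec=spec,
        mcmc=mcmc,
        info=dm.info,
        coef=coef,
        sigma=sigma,
        tau=tau,
        log_lik=log_lik,
        n_obs=len(y),
        response_summary={
            "n": len(y),
            "mean": float(np.mean(y)),
            "sd": sd_y,
            "median": med,
            "transform": test.transform,
        },
    )


def check_convergence(fit: FittedNormativeModel, rhat_max: float = 1.01) -> Diagnostics:
    """Split-R-hat per parameter; passes iff max R-hat < 1.01.

    The Gibbs sampler has no divergent transitions by construction, so
    the divergence count is always zero; the field is kept so reports
    read the same as for gradient-based samplers.
    """
    if fit.mcmc.chains < 2:
        raise ValueError("split R-hat requires at least two chains")
    idata = fit.to_inference_data()
    rhat_ds = az.rhat(idata, method="split")
    rhat = {k: float(rhat_ds[k].values) for k in rhat_ds.data_vars}
    finite = [v for v in rhat.values() if np.isfinite(v)]
    max_rhat = float(np.max(finite)) if finite else float("inf")
    if len(finite) < len(rhat):
        max_rhat = float("inf")
    return Diagnostics(rhat=rhat, max_rhat=max_rhat, divergences=0, passed=max_rhat < rhat_max)


def posterior_predictive_check(
    fit: FittedNormativeModel,
    cohort: pd.DataFrame,
    n_rep: int = 50,
    seed: int = 0,
) -> dict:
    """Replicate the training response from the posterior predictive and
    summarize the observed-vs-replicated discrepancy.

    Returns the replicated draws (model scale), the observed response,
    and the two-sample Kolmogorov-Smirnov distance of each replicate to
    the observed data.
    """
    data = cohort.dropna(subset=[fit.spec.test_id]).reset_index(drop=True)
    if len(data) != fit.n_obs:
        raise ValueError("cohort does not match the fitted training data size")
    raw = data[fit.spec.test_id].to_numpy(dtype=float)
    y = np.log(raw) if fit.test.transform == "log" else raw
    dm = build_design(fit.spec, data, info=fit.info)
    rng = np.random.default_rng(seed)
    flat_coef = fit.coef.reshape(-1, fit.coef.shape[-1])
    flat_sigma = fit.sigma.reshape(-1)
    idx = rng.choice(len(flat_sigma), size=n_rep, replace=True)
    reps = np.empty((n_rep, len(y)))
    ks = np.empty(n_rep)
    for r, i in enumerate(idx):
        reps[r] = dm.X @ flat_coef[i] + flat_sigma[i] * rng.standard_normal(len(y))
        ks[r] = stats.ks_2samp(reps[r], y).statistic
    return {"replicates": reps, "observed": y, "ks_distance": ks}
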