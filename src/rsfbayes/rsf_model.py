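"""Hierarchical Bayesian use-availability logistic regression.

The model contrasts used foraging locations (y = 1) with random available
points (y = 0) inside each individual's home range. For record j of
individual i with standardized covariate vector x_j,

    y_j ~ Bernoulli(logit^-1(x_j' beta_i)),
    beta_{i,k} ~ Normal(mu_k, sigma_k^2)   independently over terms k,
    mu_k ~ Normal(0, mu_sd^2),   sigma_k ~ Uniform(0, sigma_upper).

Covariates are the proportion of bare ground (b) and vegetation height (h),
optionally with their squares; squared terms are squares of the
*standardized* linear terms. Fitting is by an adaptive random-walk
Metropolis-within-Gibbs sampler written here: each individual's coefficient
block is updated by a joint random-walk proposal, mu by its exact conjugate
Gibbs draw, and sigma by a bounded random-walk step. Proposal scales are
tuned toward 35% acceptance during burn-in and frozen afterwards so
detailed balance holds for every retained draw.

Model comparison uses DIC with conditional focus (deviance given the
individual-level coefficients) and goodness of fit a chi-square discrepancy
posterior-predictive check reported as a Bayesian P-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import (
    ConfigError,
    DegenerateIndividualError,
    FormulaMismatchError,
    NumericError,
)
from .geometry import PatchCovariates

logger = logging.getLogger(__name__)

__all__ = [
    "TERM_ORDER",
    "UseRecord",
    "ModelFormula",
    "Priors",
    "Standardization",
    "MCMCConfig",
    "Design",
    "FitResult",
    "DicSummary",
    "ResponseCurve",
    "GofReport",
    "OptimumSummary",
    "build_design",
    "log_likelihood",
    "deviance",
    "fit",
    "compute_dic",
    "bayesian_p_value",
    "individual_response",
    "marginal_response",
    "optimum_covariate",
]

#: fixed design-column order; formulas select a subset
TERM_ORDER = ("b", "b2", "h", "h2")
_BASE = {"b2": "b", "h2": "h"}
PROB_CLAMP = 1e-12


@dataclass(frozen=True)
class UseRecord:
    """One used (y=1) or available (y=0) location with its patch covariates."""

    individual_id: str
    y: int
    covs: PatchCovariates
    habitat: str | None = None
    species: str | None = None

    def __post_init__(self):
        if self.y not in (0, 1):
            raise ValueError(f"use indicator must be 0 or 1, got {self.y}")


@dataclass(frozen=True)
class ModelFormula:
    """A candidate model: a subset of {b, b2, h, h2} plus an intercept.

    Marginality is enforced: a squared term requires its linear term.
    """

    terms: tuple[str, ...]

    def __post_init__(self):
        seen = set()
        for t in self.terms:
            if t not in TERM_ORDER:
                raise ValueError(f"unknown term {t!r}; allowed: {TERM_ORDER}")
            if t in seen:
                raise ValueError(f"duplicate term {t!r}")
            seen.add(t)
        for sq, lin in _BASE.items():
            if sq in seen and lin not in seen:
                raise ValueError(f"{sq} requires {lin} (marginality)")
        # canonical order
        object.__setattr__(
            self, "terms", tuple(t for t in TERM_ORDER if t in seen)
        )

    @classmethod
    def from_string(cls, s: str) -> "ModelFormula":
        s = s.strip()
        if s in ("intercept", "1", ""):
            return cls(())
        return cls(tuple(t.strip() for t in s.split("+")))

    @property
    def name(self) -> str:
        return "+".join(self.terms) if self.terms else "intercept"

    @property
    def columns(self) -> tuple[str, ...]:
        return ("intercept",) + self.terms

    @property
    def covariates(self) -> tuple[str, ...]:
        """Raw covariates the formula touches ('b' and/or 'h')."""
        return tuple(c for c in ("b", "h") if c in self.terms)

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Priors:
    """Vague priors on the standardized scale."""

    mu_mean: float = 0.0
    mu_sd: float = 10.0
    sigma_upper: float = 10.0

    def __post_init__(self):
        if self.mu_sd <= 0 or self.sigma_upper <= 0:
            raise ConfigError("mu_sd and sigma_upper must be positive")


@dataclass(frozen=True)
class Standardization:
    """Centering/scaling applied to the raw covariates before sampling."""

    mean: Mapping[str, float]
    sd: Mapping[str, float]

    def transform(self, raw: np.ndarray, covariate: str) -> np.ndarray:
        return (np.asarray(raw, dtype=float) - self.mean[covariate]) / self.sd[covariate]

    def inverse(self, z: np.ndarray, covariate: str) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd[covariate] + self.mean[covariate]


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 3
    iterations: int = 6000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    adapt_window: int = 50

    def __post_init__(self):
        if min(self.chains, self.iterations, self.burn_in, self.thin, self.adapt_window) <= 0:
            raise ConfigError("all MCMC counts must be positive")
        if self.burn_in >= self.iterations:
            raise ConfigError(
                f"burn_in ({self.burn_in}) must be < iterations ({self.iterations})"
            )

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass(frozen=True)
class Design:
    """Response, individual index and standardized design matrix."""

    y: np.ndarray                 # (n,) in {0,1}
    X: np.ndarray                 # (n, K) standardized, first column 1
    individual_index: np.ndarray  # (n,) in [0, I)
    individuals: tuple[str, ...]
    columns: tuple[str, ...]
    standardization: Standardization
    formula: ModelFormula

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_terms(self) -> int:
        return self.X.shape[1]


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        {
            "individual_id": r.individual_id,
            "y": r.y,
            "bare": r.covs.bare,
            "height": r.covs.height,
            "habitat": r.habitat,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def build_design(
    records: Iterable[UseRecord] | pd.DataFrame, formula: ModelFormula
) -> Design:
    """Assemble the standardized design matrix for one candidate model.

    Covariates are standardized to mean 0, sd 1 over all records; squared
    terms are squares of the standardized linear values. Column order is
    (intercept, b, b2, h, h2) restricted to the formula.

    Raises
    ------
    DegenerateIndividualError
        If any individual contributes only used or only available records
        (its intercept would be unidentified).
    """
    df = _records_to_frame(records)
    ids, ind_idx = np.unique(df["individual_id"].to_numpy(), return_inverse=True)
    if len(ids) < 2:
        raise DegenerateIndividualError(
            f"need >= 2 individuals, got {len(ids)}"
        )
    y = df["y"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("use indicator column must be 0/1")
    for i, ident in enumerate(ids):
        yi = y[ind_idx == i]
        if yi.min() == yi.max():
            raise DegenerateIndividualError(
                f"individual {ident!r} has only y={int(yi[0])} records; "
                "both used and available points are required"
            )
        n1, n0 = yi.sum(), len(yi) - yi.sum()
        ratio = max(n1, n0) / max(min(n1, n0), 1)
        if ratio > 1.25:
            logger.warning(
                "individual %s has used:available imbalance %.2f:1; the 0.5 "
                "neutrality convention assumes roughly balanced counts",
                ident,
                ratio,
            )

    mean, sd, zcols = {}, {}, {}
    raw_name = {"b": "bare", "h": "height"}
    for cov in formula.covariates:
        raw = df[raw_name[cov]].to_numpy(dtype=float)
        if not np.isfinite(raw).all():
            raise ValueError(
                f"covariate {raw_name[cov]!r} required by formula "
                f"{formula.name!r} has missing values"
            )
        m, s = float(raw.mean()), float(raw.std(ddof=0))
        if s <= 0:
            raise ValueError(f"covariate {raw_name[cov]!r} is constant")
        mean[cov], sd[cov] = m, s
        zcols[cov] = (raw - m) / s

    cols = [np.ones(len(df))]
    for t in formula.terms:
        cols.append(zcols[t] if t in zcols else zcols[_BASE[t]] ** 2)
    X = np.column_stack(cols)
    return Design(
        y=y,
        X=X,
        individual_index=ind_idx.astype(np.intp),
        individuals=tuple(str(i) for i in ids),
        columns=formula.columns,
        standardization=Standardization(mean=mean, sd=sd),
        formula=formula,
    )


def _linear_predictor(design: Design, B: np.ndarray) -> np.ndarray:
    return np.einsum("nk,nk->n", design.X, B[design.individual_index])


def log_likelihood(design: Design, B: np.ndarray) -> float:
    """Bernoulli-logit log likelihood conditional on individual coefficients.

    ``B`` is the (individuals x terms) coefficient matrix. Evaluated in the
    overflow-safe form y*eta - log(1 + exp(eta)).
    """
    B = np.asarray(B, dtype=float)
    if B.shape != (design.n_individuals, design.n_terms):
        raise ValueError(
            f"B has shape {B.shape}, expected "
            f"({design.n_individuals}, {design.n_terms})"
        )
    eta = _linear_predictor(design, B)
    if not np.isfinite(eta).all():
        bad = int(np.flatnonzero(~np.isfinite(eta))[0])
        raise NumericError(f"non-finite linear predictor at record {bad}")
    return float(np.sum(design.y * eta - np.logaddexp(0.0, eta)))


def deviance(design: Design, B: np.ndarray) -> float:
    """Conditional deviance D = -2 log L(B)."""
    return -2.0 * log_likelihood(design, B)


@dataclass
class FitResult:
    """Posterior draws and diagnostics from one MCMC fit.

    Draw arrays are stacked over chains; ``n_chains`` with
    ``draws_per_chain`` recovers the chain structure for diagnostics.
    """

    mu: np.ndarray        # (ndraws, K)
    sigma: np.ndarray     # (ndraws, K)
    beta: np.ndarray      # (ndraws, I, K)
    deviance: np.ndarray  # (ndraws,)
    n_chains: int
    columns: tuple[str, ...]
    individuals: tuple[str, ...]
    standardization: Standardization
    formula: ModelFormula
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return len(self.deviance)

    @property
    def draws_per_chain(self) -> int:
        return self.n_draws // self.n_chains

    def _chained(self, a: np.ndarray) -> np.ndarray:
        return a.reshape((self.n_chains, self.draws_per_chain) + a.shape[1:])


def _run_chain(
    design: Design, priors: Priors, config: MCMCConfig, seed_seq: np.random.SeedSequence
):
    rng = np.random.default_rng(seed_seq)
    X, y, idx = design.X, design.y, design.individual_index
    I, K = design.n_individuals, design.n_terms
    nd = config.draws_per_chain

    B = np.zeros((I, K))
    mu = np.zeros(K)
    sigma = np.ones(K)
    scale_b = np.full(I, 0.5)
    scale_s = np.full(K, 0.2)

    eta = np.zeros(len(y))
    ll_rec = y * eta - np.logaddexp(0.0, eta)
    ll_ind = np.bincount(idx, weights=ll_rec, minlength=I)

    out_mu = np.empty((nd, K))
    out_sigma = np.empty((nd, K))
    out_B = np.empty((nd, I, K))
    out_D = np.empty(nd)
    acc_b = np.zeros(I)
    acc_s = np.zeros(K)
    acc_b_total = np.zeros(I)
    n_post = 0
    j = 0

    prior_mu_prec = 1.0 / priors.mu_sd**2

    for it in range(config.iterations):
        # --- individual coefficient blocks (joint RW proposal per individual)
        prop = B + rng.standard_normal((I, K)) * scale_b[:, None]
        eta_p = np.einsum("nk,nk->n", X, prop[idx])
        llp_rec = y * eta_p - np.logaddexp(0.0, eta_p)
        llp_ind = np.bincount(idx, weights=llp_rec, minlength=I)
        dprior = -0.5 * (
            ((prop - mu) ** 2 - (B - mu) ** 2) / sigma**2
        ).sum(axis=1)
        accept = np.log(rng.random(I)) < (llp_ind - ll_ind + dprior)
        if accept.any():
            B[accept] = prop[accept]
            rows = accept[idx]
            eta[rows] = eta_p[rows]
            ll_rec[rows] = llp_rec[rows]
            ll_ind[accept] = llp_ind[accept]
        acc_b += accept

        # --- mu: exact conjugate Gibbs draw
        prec = I / sigma**2 + prior_mu_prec
        mean = (B.sum(axis=0) / sigma**2 + priors.mu_mean * prior_mu_prec) / prec
        mu = mean + rng.standard_normal(K) / np.sqrt(prec)

        # --- sigma: bounded random-walk Metropolis, target prop. to
        #     sigma^-I exp(-SS / 2 sigma^2) on (0, sigma_upper)
        sp = sigma + rng.standard_normal(K) * scale_s
        ss = ((B - mu) ** 2).sum(axis=0)
        ok = (sp > 0) & (sp < priors.sigma_upper)
        sp_safe = np.where(ok, sp, 1.0)
        logr = np.where(
            ok,
            -I * (np.log(sp_safe) - np.log(sigma))
            - 0.5 * ss * (1.0 / sp_safe**2 - 1.0 / sigma**2),
            -np.inf,
        )
        s_accept = np.log(rng.random(K)) < logr
        sigma = np.where(s_accept, sp, sigma)
        acc_s += s_accept

        # --- proposal adaptation, burn-in only
        if it < config.burn_in and (it + 1) % config.adapt_window == 0:
            w = config.adapt_window
            scale_b *= np.exp(np.clip(acc_b / w - 0.35, -0.5, 0.5))
            scale_s *= np.exp(np.clip(acc_s / w - 0.35, -0.5, 0.5))
            acc_b[:] = 0.0
            acc_s[:] = 0.0

        if it >= config.burn_in:
            acc_b_total += accept
            n_post += 1
            if (it - config.burn_in) % config.thin == 0:
                out_mu[j] = mu
                out_sigma[j] = sigma
                out_B[j] = B
                out_D[j] = -2.0 * ll_rec.sum()
                j += 1

    accept_rate = float((acc_b_total / max(n_post, 1)).mean())
    return out_mu, out_sigma, out_B, out_D, accept_rate


def _diagnostics(fit: FitResult) -> tuple[dict[str, float], dict[str, float]]:
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        import arviz as az

        post = {
            "mu": fit._chained(fit.mu),
            "sigma": fit._chained(fit.sigma),
            "beta": fit._chained(fit.beta),
            "deviance": fit._chained(fit.deviance),
        }
        idata = az.from_dict(posterior=post)
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)

    def _flatten(ds) -> dict[str, float]:
        out: dict[str, float] = {}
        for k in range(len(fit.columns)):
            out[f"mu[{fit.columns[k]}]"] = float(ds["mu"].values[k])
            out[f"sigma[{fit.columns[k]}]"] = float(ds["sigma"].values[k])
        for i, ident in enumerate(fit.individuals):
            for k, col in enumerate(fit.columns):
                out[f"beta[{ident},{col}]"] = float(ds["beta"].values[i, k])
        out["deviance"] = float(ds["deviance"].values)
        return out

    return _flatten(rhat_ds), _flatten(ess_ds)


def fit(
    design: Design,
    priors: Priors | None = None,
    config: MCMCConfig | None = None,
    *,
    compute_diagnostics: bool = True,
) -> FitResult:
    """Sample the posterior of the hierarchical logistic regression.

    Runs ``config.chains`` independent chains (seeded from ``config.seed``
    via spawned sub-streams, so results are bit-reproducible), discards
    burn-in, and stacks retained draws. Split R-hat and effective sample
    size are attached per parameter; R-hat above 1.1 is recorded as a
    warning on the result, not raised.
    """
    priors = priors or Priors()
    config = config or MCMCConfig()
    seqs = np.random.SeedSequence(config.seed).spawn(config.chains)
    parts = [_run_chain(design, priors, config, s) for s in seqs]
    res = FitResult(
        mu=np.concatenate([p[0] for p in parts]),
        sigma=np.concatenate([p[1] for p in parts]),
        beta=np.concatenate([p[2] for p in parts]),
        deviance=np.concatenate([p[3] for p in parts]),
        n_chains=config.chains,
        columns=design.columns,
        individuals=design.individuals,
        standardization=design.standardization,
        formula=design.formula,
    )
    if compute_diagnostics and config.chains > 1:
        res.rhat, res.ess = _diagnostics(res)
        bad = {k: v for k, v in res.rhat.items() if np.isfinite(v) and v > 1.1}
        if bad:
            worst = max(bad, key=bad.get)
            msg = (
                f"{len(bad)} parameter(s) with R-hat > 1.1 "
                f"(worst {worst}: {bad[worst]:.3f}); consider longer chains"
            )
            res.warnings.append(msg)
            logger.warning(msg)
    return res


@dataclass(frozen=True)
class DicSummary:
    """Deviance information criterion with conditional focus."""

    d_bar: float
    p_d: float

    @property
    def dic(self) -> float:
        return self.d_bar + self.p_d


def compute_dic(fit_result: FitResult, design: Design) -> DicSummary:
    """DIC from per-draw conditional deviance.

    d_bar is the posterior mean deviance; the effective number of
    parameters pD is d_bar minus the deviance at the posterior mean of the
    individual-level coefficient matrix (the conditional, plug-in focus).
    A negative pD is legal and only warned about.
    """
    d_bar = float(fit_result.deviance.mean())
    d_hat = deviance(design, fit_result.beta.mean(axis=0))
    p_d = d_bar - d_hat
    if p_d < 0:
        logger.warning("negative pD (%.3f); posterior may be far from normal", p_d)
    return DicSummary(d_bar=d_bar, p_d=p_d)


@dataclass
class GofReport:
    """Chi-square discrepancy posterior-predictive check."""

    t_obs: np.ndarray
    t_rep: np.ndarray
    bayes_p: float


def bayesian_p_value(
    fit_result: FitResult, design: Design, rng_seed: int | np.random.Generator = 0
) -> GofReport:
    """Posterior-predictive check with the chi-square discrepancy.

    For each retained draw, T(y) = sum_j (y_j - p_j)^2 / (p_j (1 - p_j))
    is computed for the observed responses and for a replicate drawn from
    the fitted Bernoulli probabilities; the Bayesian P-value is the
    fraction of draws with T(y_rep) >= T(y_obs). Probabilities are clamped
    to [1e-12, 1 - 1e-12] (logged) to keep the discrepancy finite.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    y = design.y
    nd = fit_result.n_draws
    t_obs = np.empty(nd)
    t_rep = np.empty(nd)
    n_clamped = 0
    for lo in range(0, nd, 512):
        hi = min(lo + 512, nd)
        block = fit_result.beta[lo:hi]  # (m, I, K)
        eta = np.einsum("nk,mnk->mn", design.X, block[:, design.individual_index, :])
        p = expit(eta)
        clip = (p < PROB_CLAMP) | (p > 1 - PROB_CLAMP)
        n_clamped += int(clip.sum())
        p = np.clip(p, PROB_CLAMP, 1 - PROB_CLAMP)
        v = p * (1 - p)
        t_obs[lo:hi] = ((y - p) ** 2 / v).sum(axis=1)
        yrep = (rng.random(p.shape) < p).astype(float)
        t_rep[lo:hi] = ((yrep - p) ** 2 / v).sum(axis=1)
    if n_clamped:
        logger.warning(
            "clamped %d fitted probabilities to [%g, %g] in the chi-square "
            "discrepancy",
            n_clamped,
            PROB_CLAMP,
            1 - PROB_CLAMP,
        )
    return GofReport(
        t_obs=t_obs, t_rep=t_rep, bayes_p=float((t_rep >= t_obs).mean())
    )


@dataclass
class ResponseCurve:
    """Selection probability against one covariate, with 80% credible band."""

    level: str                      # "individual" or "marginal"
    covariate: str                  # "b" or "h"
    grid: np.ndarray                # raw scale
    mean: np.ndarray
    lo80: np.ndarray
    hi80: np.ndarray
    individual_id: str | None = None

    def __post_init__(self):
        ok = (
            (self.lo80 <= self.mean + 1e-12)
            & (self.mean <= self.hi80 + 1e-12)
            & (self.lo80 >= -1e-12)
            & (self.hi80 <= 1 + 1e-12)
        )
        if not ok.all():
            raise ValueError("credible band must satisfy 0 <= lo80 <= mean <= hi80 <= 1")


def _grid_design(
    fit_result: FitResult,
    covariate: str,
    grid: np.ndarray,
    others_at: Mapping[str, float] | None,
) -> np.ndarray:
    """(G, K) standardized design matrix varying one covariate."""
    formula = fit_result.formula
    grid = np.asarray(grid, dtype=float)
    if covariate not in formula.covariates:
        if not formula.terms:
            # intercept-only model: a flat curve over the display grid
            return np.ones((len(grid), 1))
        raise FormulaMismatchError(
            f"covariate {covariate!r} is not in formula {formula.name!r}"
        )
    std = fit_result.standardization
    zvar = std.transform(grid, covariate)
    zfix = {}
    for cov in formula.covariates:
        if cov != covariate:
            raw = (others_at or {}).get(cov, std.mean[cov])
            zfix[cov] = float(std.transform(np.array([raw]), cov)[0])
    cols = [np.ones_like(grid)]
    for t in formula.terms:
        lin = _BASE.get(t, t)
        z = zvar if lin == covariate else np.full_like(grid, zfix[lin])
        cols.append(z if t == lin else z**2)
    return np.column_stack(cols)


def individual_response(
    fit_result: FitResult,
    covariate: str,
    grid: np.ndarray,
    others_at: Mapping[str, float] | None = None,
) -> list[ResponseCurve]:
    """One conditional selection curve per individual.

    The varied covariate runs over ``grid`` (raw scale); any other
    covariate in the formula is held at ``others_at`` (default: its raw
    mean). Mean and equal-tailed 80% interval are over posterior draws of
    the individual's own coefficients.
    """
    Xg = _grid_design(fit_result, covariate, grid, others_at)
    grid = np.asarray(grid, dtype=float)
    curves = []
    for i, ident in enumerate(fit_result.individuals):
        p = expit(fit_result.beta[:, i, :] @ Xg.T)  # (ndraws, G)
        lo, hi = np.quantile(p, [0.1, 0.9], axis=0)
        curves.append(
            ResponseCurve(
                level="individual",
                covariate=covariate,
                grid=grid,
                mean=p.mean(axis=0),
                lo80=np.minimum(lo, p.mean(axis=0)),
                hi80=np.maximum(hi, p.mean(axis=0)),
                individual_id=ident,
            )
        )
    return curves


def marginal_response(
    fit_result: FitResult,
    covariate: str,
    grid: np.ndarray,
    others_at: Mapping[str, float] | None = None,
    n_new_individuals: int = 500,
    rng_seed: int | np.random.Generator = 0,
) -> ResponseCurve:
    """Population-level (marginal) selection curve.

    For each posterior draw of (mu, sigma), ``n_new_individuals``
    hypothetical individuals are drawn from Normal(mu, sigma^2) and their
    inverse-logit responses averaged, giving one marginal curve per draw;
    the pointwise posterior mean and equal-tailed 80% interval across
    draws are reported.
    """
    if n_new_individuals < 100:
        raise ValueError("n_new_individuals must be >= 100")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    Xg = _grid_design(fit_result, covariate, grid, others_at)
    grid = np.asarray(grid, dtype=float)
    nd, K = fit_result.mu.shape
    G = len(grid)
    curves = np.empty((nd, G))
    for lo in range(0, nd, 256):
        hi = min(lo + 256, nd)
        m = hi - lo
        z = rng.standard_normal((m, n_new_individuals, K))
        coef = fit_result.mu[lo:hi, None, :] + fit_result.sigma[lo:hi, None, :] * z
        curves[lo:hi] = expit(np.einsum("mik,gk->mig", coef, Xg)).mean(axis=1)
    mean = curves.mean(axis=0)
    lo80, hi80 = np.quantile(curves, [0.1, 0.9], axis=0)
    return ResponseCurve(
        level="marginal",
        covariate=covariate,
        grid=grid,
        mean=mean,
        lo80=np.minimum(lo80, mean),
        hi80=np.maximum(hi80, mean),
    )


@dataclass(frozen=True)
class OptimumSummary:
    """Posterior summary of the raw-scale covariate optimum.

    The vertex -beta_lin / (2 beta_sq) of the population-mean quadratic is
    an interior optimum only when the curvature is negative; draws with
    non-negative curvature are flagged, not used.
    """

    covariate: str
    mean: float
    lo80: float
    hi80: float
    interior_fraction: float
    n_draws: int

    @property
    def defined(self) -> bool:
        return self.interior_fraction > 0


def optimum_covariate(fit_result: FitResult, covariate: str) -> OptimumSummary:
    """Posterior of the selection optimum for a quadratic covariate effect."""
    sq = covariate + "2"
    cols = fit_result.columns
    if covariate not in cols or sq not in cols:
        raise FormulaMismatchError(
            f"optimum needs both {covariate!r} and {sq!r} in formula "
            f"{fit_result.formula.name!r}"
        )
    k_lin, k_sq = cols.index(covariate), cols.index(sq)
    lin = fit_result.mu[:, k_lin]
    curv = fit_result.mu[:, k_sq]
    interior = curv < 0
    frac = float(interior.mean())
    if not interior.any():
        return OptimumSummary(covariate, np.nan, np.nan, np.nan, 0.0, fit_result.n_draws)
    x_std = -lin[interior] / (2.0 * curv[interior])
    x_raw = fit_result.standardization.inverse(x_std, covariate)
    lo, hi = np.quantile(x_raw, [0.1, 0.9])
    return OptimumSummary(
        covariate=covariate,
        mean=float(x_raw.mean()),
        lo80=float(lo),
        hi80=float(hi),
        interior_fraction=frac,
        n_draws=fit_result.n_draws,
    )
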