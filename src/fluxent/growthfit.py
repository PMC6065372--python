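"""Fitting the maximum-entropy growth-rate distribution to single-cell data.

The growth-rate marginal predicted by the flux ensemble near the optimum is

    Q(lambda) ~ (lambda_max - lambda)^(D-1) e^{beta lambda}   on [0, lambda_max],

parameterized by the optimization level beta (h), the maximal achievable rate
lambda_max (1/h) and the polytope dimension D.  This module fits (beta,
lambda_max[, D]) to samples of single-cell growth rates by maximum
likelihood, computes per-lineage summary statistics, and tests the
fluctuation scaling sigma ~ (lambda_max - lambda_bar) by linear regression.

Lineage SDs use the population (divide-by-n) convention so they match the
moment formulas of Q directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest, linregress

from .analytic_cone import ConeModel, log_partition, tilted_moments
from .errors import FluxentError, NotConvergedError

_BETA_TINY = 1e-10


@dataclass
class GrowthRateModel:
    """Q(lambda) ~ (lambda_max - lambda)^(D-1) e^{beta lambda} on [0, lambda_max]."""

    beta: float
    lambda_max: float
    D: int
    fit_info: dict = field(default_factory=dict)

    def _cone(self) -> ConeModel:
        return ConeModel(D=self.D, lambda_max=self.lambda_max)

    @property
    def mean(self) -> float:
        return tilted_moments(self._cone(), self.beta)[0]

    @property
    def sd(self) -> float:
        return tilted_moments(self._cone(), self.beta)[1]

    def logpdf(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        cone = self._cone()
        with np.errstate(divide="ignore"):
            lq = (np.log(self.D) + (self.D - 1) * np.log(self.lambda_max - lam)
                  - self.D * np.log(self.lambda_max))
        out = lq + self.beta * lam - log_partition(cone, self.beta)
        return np.where((lam >= 0) & (lam <= self.lambda_max), out, -np.inf)

    def pdf(self, lam) -> np.ndarray:
        return np.exp(self.logpdf(lam))

    def cdf(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        u = np.clip(self.lambda_max - lam, 0.0, self.lambda_max)
        x = self.beta * self.lambda_max
        if x < _BETA_TINY:
            Fu = (u / self.lambda_max) ** self.D
        else:
            Fu = gammainc(self.D, self.beta * u) / gammainc(self.D, x)
        return np.where(lam < 0, 0.0, np.where(lam > self.lambda_max, 1.0, 1.0 - Fu))

    def rvs(self, n: int, rng=None) -> np.ndarray:
        """Exact inverse-CDF draws via the truncated-gamma representation
        u = lambda_max - lambda ~ Gamma(D, 1/beta) restricted to [0, lambda_max]."""
        rng = np.random.default_rng(rng)
        U = rng.random(n)
        x = self.beta * self.lambda_max
        if x < _BETA_TINY:
            u = self.lambda_max * U ** (1.0 / self.D)
        else:
            u = gamma_dist.ppf(U * gammainc(self.D, x), a=self.D, scale=1.0 / self.beta)
        return self.lambda_max - u


def _nll(params, lam, D):
    beta, lmax = params
    if lmax <= lam.max():
        return np.inf
    cone = ConeModel(D=D, lambda_max=lmax)
    n = lam.size
    ll = (n * np.log(D) - n * D * np.log(lmax)
          + (D - 1) * np.sum(np.log(lmax - lam))
          + beta * lam.sum() - n * log_partition(cone, beta))
    return -ll


def _fit_fixed_D(lam, D):
    mean, sd = lam.mean(), lam.std()
    xmax = lam.max()
    span = max(xmax - lam.min(), sd, 1e-6 * max(xmax, 1.0))
    beta0 = np.sqrt(D) / max(sd, 1e-3 * span)
    lmax0 = max(mean + np.sqrt(D) * max(sd, 1e-3 * span), xmax * (1 + 1e-3) + 1e-9)
    lo = xmax + 1e-9 * max(xmax, 1.0)
    best = None
    for b0, l0 in ((beta0, lmax0), (0.0, max(lmax0, xmax + span)),
                   (2 * beta0, max(lo * 1.001, xmax + 0.5 * span))):
        res = minimize(_nll, x0=[b0, max(l0, lo * (1 + 1e-9))], args=(lam, D),
                       method="L-BFGS-B", bounds=[(0.0, None), (lo, None)])
        if best is None or (res.success and res.fun < best.fun):
            best = res
    return best


def fit_growth_distribution(samples, D: int | None = None,
                            d_range: tuple = (1, 50),
                            min_samples: int = 30) -> GrowthRateModel:
    """Maximum-likelihood fit of Q to growth-rate samples.

    With ``D`` given, (beta, lambda_max) are optimized jointly subject to
    lambda_max > max(sample); with ``D=None`` (default) the integer D is
    profiled over ``d_range`` and the best log-likelihood wins.  The returned
    model's ``fit_info`` records the log-likelihood, a Kolmogorov-Smirnov
    goodness-of-fit test against the fitted Q, and the optimizer trace.
    """
    lam = np.asarray(samples, dtype=float)
    if lam.size < min_samples:
        raise FluxentError(f"need >= {min_samples} samples, got {lam.size}")
    if np.any(lam <= 0):
        raise FluxentError("growth-rate samples must be positive")

    candidates = [D] if D is not None else list(range(d_range[0], d_range[1] + 1))
    best = None
    for d in candidates:
        res = _fit_fixed_D(lam, d)
        if res is not None and np.isfinite(res.fun):
            if best is None or res.fun < best[1].fun:
                best = (d, res)
    if best is None or not np.isfinite(best[1].fun):
        raise NotConvergedError("growth-distribution MLE failed to converge "
                                f"(last optimizer message: {res.message})")
    d, res = best
    model = GrowthRateModel(beta=float(res.x[0]), lambda_max=float(res.x[1]), D=d)
    ks = kstest(lam, model.cdf)
    model.fit_info = {"loglik": -float(res.fun), "n": int(lam.size),
                      "ks_statistic": float(ks.statistic),
                      "ks_pvalue": float(ks.pvalue),
                      "D_mode": "fixed" if D is not None else "fitted",
                      "optimizer_message": str(res.message)}
    return model


# ---------------------------------------------------------------------------
# lineage statistics and fluctuation scaling
# ---------------------------------------------------------------------------

def lineage_statistics(table: pd.DataFrame, min_events: int = 2,
                       rate_column: str = "growth_rate",
                       lineage_column: str = "lineage_id"):
    """Per-lineage mean, max, SD (ddof=0) and event count.

    Lineages with fewer than ``min_events`` events are dropped; returns
    ``(stats, n_dropped)``."""
    if rate_column not in table or lineage_column not in table:
        raise FluxentError(f"table needs columns '{lineage_column}', '{rate_column}'")
    g = table.groupby(lineage_column)[rate_column]
    stats = g.agg(lambda_mean="mean",
                  lambda_max="max",
                  sigma=lambda x: float(np.std(x)),
                  n_events="size")
    kept = stats[stats["n_events"] >= min_events]
    return kept, int(len(stats) - len(kept))


@dataclass
class ScalingRegression:
    slope: float
    intercept: float
    r_squared: float
    n: int


def scaling_regression(stats: pd.DataFrame) -> ScalingRegression:
    """OLS of sigma against (lambda_max - lambda_bar) across lineages: the
    fluctuation-scaling test.  Requires >= 3 lineages and non-degenerate x."""
    if len(stats) < 3:
        raise FluxentError("scaling regression needs >= 3 lineages")
    x = (stats["lambda_max"] - stats["lambda_mean"]).to_numpy()
    y = stats["sigma"].to_numpy()
    if np.std(x) < 1e-12 * max(np.max(np.abs(x)), 1.0):
        raise FluxentError("degenerate regressor: lambda_max - lambda_bar is constant")
    fit = linregress(x, y)
    return ScalingRegression(slope=float(fit.slope), intercept=float(fit.intercept),
                             r_squared=float(fit.rvalue ** 2), n=len(stats))


def binned_scaling(stats: pd.DataFrame, n_bins: int = 8) -> pd.DataFrame:
    """Equi-distant-bin display variant: mean +/- SD of sigma within bins of
    (lambda_max - lambda_bar)."""
    df = pd.DataFrame({"x": stats["lambda_max"] - stats["lambda_mean"],
                       "sigma": stats["sigma"]})
    bins = pd.cut(df["x"], n_bins)
    out = df.groupby(bins, observed=True).agg(
        x_mean=("x", "mean"), sigma_mean=("sigma", "mean"),
        sigma_sd=("sigma", lambda s: float(np.std(s))), n=("sigma", "size"))
    return out.reset_index(drop=True)
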