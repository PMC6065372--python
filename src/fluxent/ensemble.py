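"""Ensemble-level quantities computed from flux samples.

This module owns the beta ladder (tabulated mean growth, fluctuations, and
information over a beta grid), the fit of beta to a measured average growth
rate, the mean-squared error against measured fluxes, and the derived
statistics: fold changes, variability scaling, growth-rate marginals and
correlation clustering.

Information is computed by thermodynamic integration.  Since P_beta is an
exponential family on the polytope, S(beta) = ln Z(beta) - beta*lambda_bar
and d ln Z / d beta = lambda_bar, so the entropy drop from uniform is

    I(beta) = [ beta*lambda_bar(beta) - integral_0^beta lambda_bar db' ] / ln 2   (bits),

which needs only the lambda_bar(beta) curve the ladder already tabulates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.distance import squareform

from .errors import FluxentError, NotConvergedError
from .fba import solve_fba
from .model_io import MeasuredFluxTable
from .polytope import FluxPolytope
from .sampler import FluxSample, hit_and_run, lambda_standard_error

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

@dataclass
class Moments:
    means: pd.Series
    sds: pd.Series
    cvs: pd.Series                 # NaN where undefined (|mean| ~ 0)
    cv_undefined: pd.Series
    lambda_mean: float
    lambda_sd: float
    corr: pd.DataFrame | None = None
    corr_excluded: list = field(default_factory=list)


def _weighted_mean_sd(X: np.ndarray, w: np.ndarray | None):
    if w is None:
        return X.mean(axis=0), X.std(axis=0)
    w = w / w.sum()
    m = w @ X
    var = w @ (X - m) ** 2
    return m, np.sqrt(var)


def compute_moments(sample: FluxSample, flux_subset: list | None = None,
                    cv_tol: float = 1e-9, sd_tol: float = 1e-12) -> Moments:
    """Per-flux means, SDs and CVs plus the Pearson correlation matrix over a
    chosen flux subset.  Importance weights, when present, are honored.
    CV is flagged undefined (NaN) where the mean is numerically zero;
    near-constant fluxes are excluded from the correlation matrix."""
    ids = sample.polytope.model.reaction_ids
    X, w = sample.fluxes, sample.weights
    m, s = _weighted_mean_sd(X, w)
    lm, ls = _weighted_mean_sd(sample.lambdas[:, None], w)
    scale = max(np.max(np.abs(m)), 1.0)
    undef = np.abs(m) < cv_tol * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(undef, np.nan, s / np.abs(m))

    subset = flux_subset if flux_subset is not None else ids
    sub_idx = [ids.index(r) for r in subset]
    keep = [i for i in sub_idx if s[i] > sd_tol * scale]
    excluded = [ids[i] for i in sub_idx if i not in keep]
    corr = None
    if len(keep) >= 2:
        Xs = X[:, keep]
        if w is None:
            C = np.corrcoef(Xs, rowvar=False)
        else:
            wn = w / w.sum()
            mu = wn @ Xs
            Xc = Xs - mu
            cov = (Xc * wn[:, None]).T @ Xc
            d = np.sqrt(np.diag(cov))
            C = cov / np.outer(d, d)
        corr = pd.DataFrame(C, index=[ids[i] for i in keep],
                            columns=[ids[i] for i in keep])
    return Moments(means=pd.Series(m, index=ids), sds=pd.Series(s, index=ids),
                   cvs=pd.Series(cv, index=ids),
                   cv_undefined=pd.Series(undef, index=ids),
                   lambda_mean=float(lm[0]), lambda_sd=float(ls[0]),
                   corr=corr, corr_excluded=excluded)


# ---------------------------------------------------------------------------
# the beta ladder
# ---------------------------------------------------------------------------

@dataclass
class BetaLadder:
    """lambda_bar(beta), sigma(beta), per-flux moments and I(beta) on a grid."""

    betas: np.ndarray
    lambda_mean: np.ndarray
    lambda_sd: np.ndarray
    lambda_se: np.ndarray
    flux_means: np.ndarray         # (n_beta, N)
    flux_sds: np.ndarray
    lambda_max: float
    reaction_ids: list | None = None
    info_bits: np.ndarray | None = None
    info_se: np.ndarray | None = None
    samples: list | None = None

    @property
    def beta_lmax(self) -> np.ndarray:
        return self.betas * self.lambda_max

    def to_frame(self) -> pd.DataFrame:
        d = {"beta": self.betas, "beta_lambda_max": self.beta_lmax,
             "lambda_mean": self.lambda_mean, "lambda_sd": self.lambda_sd,
             "lambda_se": self.lambda_se}
        if self.info_bits is not None:
            d["info_bits"] = self.info_bits
        return pd.DataFrame(d)


def default_beta_grid(lambda_max: float, x_max: float = 400.0,
                      n: int = 12) -> np.ndarray:
    """Geometric grid in beta*lambda_max from 0 (prepended) up to ``x_max``."""
    return np.concatenate([[0.0], np.geomspace(1.0, x_max, n - 1)]) / lambda_max


def build_ladder(polytope: FluxPolytope, betas: np.ndarray | None = None,
                 n_samples: int = 5000, n_chains: int = 4, seed: int = 0,
                 lambda_max: float | None = None, keep_samples: bool = False,
                 compute_information: bool = True, **sampler_kw) -> BetaLadder:
    """Sample the ensemble over a beta grid and tabulate its statistics."""
    if lambda_max is None:
        lambda_max = solve_fba(polytope.model).lambda_max
    if betas is None:
        betas = default_beta_grid(lambda_max)
    betas = np.asarray(betas, dtype=float)
    if betas[0] != 0.0 or np.any(np.diff(betas) <= 0):
        raise FluxentError("beta grid must be ascending and start at 0")
    N = polytope.model.n_reactions
    lm = np.empty(betas.size)
    lsd = np.empty(betas.size)
    lse = np.empty(betas.size)
    fm = np.empty((betas.size, N))
    fsd = np.empty((betas.size, N))
    samples = [] if keep_samples else None
    for k, b in enumerate(betas):
        s = hit_and_run(polytope, b, n_samples, n_chains=n_chains,
                        seed=seed + 7919 * k, **sampler_kw)
        lm[k] = s.lambdas.mean()
        lsd[k] = s.lambdas.std()
        lse[k] = lambda_standard_error(s)
        fm[k] = s.fluxes.mean(axis=0)
        fsd[k] = s.fluxes.std(axis=0)
        if keep_samples:
            samples.append(s)
    ladder = BetaLadder(betas=betas, lambda_mean=lm, lambda_sd=lsd,
                        lambda_se=lse, flux_means=fm, flux_sds=fsd,
                        lambda_max=float(lambda_max),
                        reaction_ids=list(polytope.model.reaction_ids),
                        samples=samples)
    if compute_information:
        ladder.info_bits, ladder.info_se = information_curve(ladder)
    return ladder


def information_curve(ladder: BetaLadder) -> tuple[np.ndarray, np.ndarray]:
    """I(beta) in bits by thermodynamic integration over the ladder grid,
    with MC standard errors propagated from the per-point errors of
    lambda_bar.  Raises :class:`NotConvergedError` if lambda_bar decreases
    along the grid beyond MC tolerance (a bad ladder)."""
    b, lam, se = ladder.betas, ladder.lambda_mean, ladder.lambda_se
    drops = np.diff(lam) < -3.0 * np.hypot(se[:-1], se[1:]) - 1e-12
    if np.any(drops):
        k = int(np.argmax(drops))
        raise NotConvergedError(
            f"lambda_bar decreases between beta={b[k]:.4g} and {b[k+1]:.4g} "
            "beyond MC tolerance; refine the ladder or raise n_samples")
    integral = cumulative_trapezoid(lam, b, initial=0.0)
    info = np.clip((b * lam - integral) / _LN2, 0.0, None)
    # error propagation: I_k (nats) = b_k lam_k - sum_j w_{jk} lam_j with
    # trapezoid weights w; per-point samples are independent
    n = b.size
    var = np.zeros(n)
    for k in range(1, n):
        wts = np.zeros(n)
        db = np.diff(b[: k + 1])
        wts[0] = db[0] / 2
        wts[1:k] = (db[:-1] + db[1:]) / 2
        wts[k] = db[-1] / 2
        coef = -wts
        coef[k] += b[k]
        var[k] = np.sum((coef[: k + 1] * se[: k + 1]) ** 2)
    return info, np.sqrt(var) / _LN2


# ---------------------------------------------------------------------------
# beta fitting (match the measured average growth rate)
# ---------------------------------------------------------------------------

def fit_beta(polytope: FluxPolytope, lambda_data: float,
             beta_bracket: tuple | None = None, n_samples: int = 4000,
             seed: int = 0, lambda_max: float | None = None,
             rtol: float = 1e-3, **sampler_kw) -> tuple[float, dict]:
    """Find beta* with lambda_bar(beta*) = lambda_data.

    Uses common random numbers: every candidate beta is evaluated by a
    Hit-and-Run run driven by the *same* seed, which makes the Monte-Carlo
    estimate of lambda_bar(beta) a deterministic, continuous and increasing
    function of beta, so plain root bracketing applies.  The achievable
    tolerance is dominated by the MC error at ``n_samples``.
    """
    from scipy.optimize import brentq

    if lambda_max is None:
        lambda_max = solve_fba(polytope.model).lambda_max

    def lam_bar(b):
        s = hit_and_run(polytope, b, n_samples, seed=seed, **sampler_kw)
        return s.lambdas.mean()

    lam0 = lam_bar(0.0)
    if lambda_data <= lam0:
        warnings.warn(f"lambda_data = {lambda_data:.4g} is at or below the "
                      f"uniform mean {lam0:.4g}; returning beta* = 0")
        return 0.0, {"lambda_at_fit": lam0, "lambda_uniform": lam0}
    if lambda_data >= lambda_max:
        raise FluxentError(f"lambda_data = {lambda_data:.4g} >= lambda_max = "
                           f"{lambda_max:.4g}: unreachable")

    if beta_bracket is None:
        hi = 1.0 / lambda_max
        while lam_bar(hi) < lambda_data:
            hi *= 2.0
            if hi * lambda_max > 1e6:
                raise NotConvergedError("could not bracket beta*")
        beta_bracket = (0.0, hi)
    beta_star = brentq(lambda b: lam_bar(b) - lambda_data, *beta_bracket,
                       rtol=1e-12, xtol=rtol / lambda_max, maxiter=60)
    final = hit_and_run(polytope, beta_star, n_samples, seed=seed, **sampler_kw)
    return float(beta_star), {"lambda_at_fit": float(final.lambdas.mean()),
                              "lambda_se": lambda_standard_error(final),
                              "lambda_uniform": float(lam0),
                              "lambda_max": float(lambda_max)}


# ---------------------------------------------------------------------------
# comparison with measured fluxes
# ---------------------------------------------------------------------------

def mse_fluxes(sample, measured: MeasuredFluxTable,
               normalizing_reaction: str) -> float:
    """Mean-squared error between predicted relative fluxes and measured ones:
    MSE = N_f^-1 sum_i (<v_i>/<v_norm> - V_i)^2.

    ``sample`` may be a :class:`FluxSample` or a pandas Series of mean fluxes
    indexed by reaction id (e.g. the FBA vertex)."""
    if isinstance(sample, FluxSample):
        means = compute_moments(sample).means
    else:
        means = pd.Series(sample)
    norm = means[normalizing_reaction]
    if abs(norm) < 1e-12:
        raise FluxentError(
            f"normalizing reaction '{normalizing_reaction}' has zero mean flux")
    rel = means[list(measured.reaction_ids)].to_numpy() / norm
    return float(np.mean((rel - measured.values) ** 2))


def fold_change(sample_beta: FluxSample, sample_0: FluxSample,
                tol: float = 1e-9) -> pd.DataFrame:
    """Per-flux log fold change of the mean versus the uniform ensemble,
    log(|<v>_beta| / |<v>_0|), with sign-change flags; fluxes whose uniform
    mean is numerically zero are flagged excluded."""
    if sample_beta.polytope.model is not sample_0.polytope.model:
        ids_a = sample_beta.polytope.model.reaction_ids
        ids_b = sample_0.polytope.model.reaction_ids
        if ids_a != ids_b:
            raise FluxentError("samples come from different models")
    mb = compute_moments(sample_beta).means
    m0 = compute_moments(sample_0).means
    scale = max(m0.abs().max(), 1.0)
    excluded = m0.abs() < tol * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log(mb.abs() / m0.abs())
    return pd.DataFrame({"log_fold_change": lfc.where(~excluded),
                         "sign_change": (mb * m0 < 0) & ~excluded,
                         "excluded": excluded})


# ---------------------------------------------------------------------------
# variability scaling, growth marginal, clustering
# ---------------------------------------------------------------------------

@dataclass
class ScalingFit:
    per_flux_slope: pd.Series       # sigma_i(beta)/sigma_i(0) vs (1 - lam/lmax)
    growth_loglog_slope: float      # log sigma_lambda vs log(beta*lmax)
    growth_loglog_r2: float
    n_points: int


def variability_scaling(ladder: BetaLadder, scaling_min: float = 0.90,
                        x_min: float = 40.0,
                        reaction_ids: list | None = None) -> ScalingFit:
    """Fit the shrinkage of flux variability toward the growth optimum.

    Per flux, sigma_i(beta)/sigma_i(0) is regressed on (1 - lambda_bar/
    lambda_max) over the scaling regime lambda_bar/lambda_max >= ``scaling_min``;
    for the growth flux itself the log-log slope of sigma vs beta*lambda_max is
    fitted over beta*lambda_max >= ``x_min`` (expected -1 in the scaling regime).
    """
    frac = ladder.lambda_mean / ladder.lambda_max
    if frac.max() < scaling_min:
        raise NotConvergedError(
            f"ladder only reaches lambda_bar/lambda_max = {frac.max():.3f}; "
            f"scaling regime needs >= {scaling_min}")
    reg = frac >= scaling_min
    if np.unique(ladder.betas[reg]).size < 2:
        raise FluxentError("scaling fit needs >= 2 distinct beta values in regime")
    x = 1.0 - frac[reg]
    ratios = ladder.flux_sds[reg] / np.where(ladder.flux_sds[0] > 0,
                                             ladder.flux_sds[0], np.nan)
    # least squares through the origin, flux by flux (the scaling law is
    # proportional, not affine)
    denom = np.sum(x ** 2)
    slopes = (x @ ratios) / denom

    lg = reg & (ladder.beta_lmax >= x_min) & (ladder.lambda_sd > 0)
    if np.count_nonzero(lg) < 2:
        lg = ladder.beta_lmax >= x_min
    lx = np.log(ladder.beta_lmax[lg])
    ly = np.log(ladder.lambda_sd[lg])
    A = np.vstack([lx, np.ones_like(lx)]).T
    coef, res, *_ = np.linalg.lstsq(A, ly, rcond=None)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - (res[0] / ss_tot if res.size and ss_tot > 0 else 0.0)
    ids = reaction_ids or ladder.reaction_ids or list(range(ladder.flux_means.shape[1]))
    return ScalingFit(per_flux_slope=pd.Series(slopes, index=ids),
                      growth_loglog_slope=float(coef[0]),
                      growth_loglog_r2=float(r2),
                      n_points=int(np.count_nonzero(lg)))


def growth_marginal(sample: FluxSample, n_bins: int = 50,
                    support: tuple | None = None):
    """Normalized histogram estimate of the growth-rate marginal Q(lambda).

    Returns (bin_centers, density, edges); the density integrates to 1 over
    ``support`` (default [0, max lambda observed])."""
    lo, hi = support if support is not None else (0.0, float(sample.lambdas.max()))
    density, edges = np.histogram(sample.lambdas, bins=n_bins, range=(lo, hi),
                                  weights=sample.weights, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density, edges


def cluster_correlations(corr: pd.DataFrame | np.ndarray, n_groups: int) -> np.ndarray:
    """Agglomerative clustering (average linkage on distance 1 - correlation)
    cut at ``n_groups``; deterministic given its input.  Returns integer
    labels 0..n_groups-1 in input order."""
    C = np.asarray(corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise FluxentError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise FluxentError("correlation matrix must be symmetric")
    if n_groups > C.shape[0]:
        raise FluxentError(f"n_groups = {n_groups} exceeds matrix size {C.shape[0]}")
    dist = 1.0 - C
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=n_groups, criterion="maxclust") - 1
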