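"""Hit-and-Run sampling of the Boltzmann flux ensemble P_beta(v) ~ e^{beta lambda(v)}.

Each Markov step picks an isotropic random direction in rounded coordinates,
intersects the line through the current point with the polytope to obtain a
chord [s-, s+], and then draws the new position *exactly* from the
one-dimensional density proportional to exp(beta * lambda) restricted to the
chord -- a truncated exponential, sampled by inverse CDF with log-space
safeguards.  Because the chord step is exact, the chain has the target as its
stationary distribution for every beta >= 0, and the sampler can be validated
against closed forms.

Chains are advanced in parallel as rows of a matrix, which makes large
sample sizes (1e5 draws) reachable in pure numpy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import EffectiveSampleSizeError, FluxentError
from .polytope import FluxPolytope

_RATE_EPS = 1e-12   # |a * chord| below this: the tilt is numerically uniform


@dataclass
class FluxSample:
    """Monte-Carlo draws from P_beta with provenance and diagnostics hooks.

    ``fluxes`` has one row per draw in original flux coordinates; ``reduced``
    holds the same draws in the polytope's internal coordinates (kept for
    diagnostics and rounding).  ``chain_shape = (n_chains, n_per_chain)``
    allows per-chain views for convergence checks.
    """

    polytope: FluxPolytope
    fluxes: np.ndarray            # (n, N)
    reduced: np.ndarray           # (n, D)
    lambdas: np.ndarray           # (n,)
    beta: float
    seed: int
    n_chains: int
    burn_in: int
    thin: int
    weights: np.ndarray | None = None
    target_beta: float | None = None
    info: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.fluxes.shape[0]

    def per_chain(self, arr: np.ndarray) -> np.ndarray:
        """Reshape a per-draw array to (n_chains, n_per_chain, ...)."""
        per = self.n // self.n_chains
        return arr[: per * self.n_chains].reshape(self.n_chains, per, *arr.shape[1:])

    @property
    def ess_weights(self) -> float:
        if self.weights is None:
            return float(self.n)
        w = self.weights / self.weights.sum()
        return float(1.0 / np.sum(w * w))


def _sample_truncated_exp(rng, a, lo, hi):
    """Draw s ~ exp(a*s) on [lo, hi], elementwise over arrays, stably.

    Inverse CDF: s = lo + log1p(U*expm1(a*delta))/a, rewritten anchored at the
    favored endpoint when a*delta is large and positive so nothing overflows.
    """
    a = np.asarray(a, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    delta = hi - lo
    U = rng.random(a.shape)
    ad = a * delta
    out = lo + U * delta                         # |ad| ~ 0: uniform on the chord
    mod = np.abs(ad) >= _RATE_EPS
    safe = mod & (ad <= 30.0)
    with np.errstate(over="ignore", invalid="ignore"):
        s = lo + np.log1p(U * np.expm1(ad)) / a
        out = np.where(safe, s, out)
        big = mod & (ad > 30.0)                  # anchor at hi: e^{-ad} underflows harmlessly
        s_hi = hi + np.log(U + (1.0 - U) * np.exp(-ad)) / a
        out = np.where(big, s_hi, out)
    return np.clip(out, lo, hi)


def _chord(X, Dirs, A, b):
    """Chord extents [s-, s+] for points X (rows) along directions Dirs."""
    slack = b - X @ A.T                          # (nc, n_cons), >= 0 inside
    proj = Dirs @ A.T
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = slack / proj
    s_plus = np.where(proj > 0, ratio, np.inf).min(axis=1)
    s_minus = np.where(proj < 0, ratio, -np.inf).max(axis=1)
    return s_minus, s_plus


def hit_and_run(polytope: FluxPolytope, beta: float, n_samples: int,
                n_chains: int = 4, burn_in: int | None = None,
                thin: int | None = None, seed: int = 0,
                allow_negative_beta: bool = False,
                progress: bool = False) -> FluxSample:
    """Draw ``n_samples`` (total, across chains) from P_beta on the polytope.

    Defaults follow a D-scaled mixing heuristic: ``burn_in = 1000 * D`` steps
    and ``thin = D``.  All chains start from the interior point with a small
    isotropic jitter and are advanced simultaneously.  ``beta < 0`` is
    mathematically supported but disabled unless ``allow_negative_beta``.
    """
    if beta < 0 and not allow_negative_beta:
        raise FluxentError("beta < 0 requires allow_negative_beta=True")
    D = polytope.D
    if burn_in is None:
        burn_in = 1000 * D
    if thin is None:
        thin = D
    per_chain = -(-n_samples // n_chains)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x48_52]))

    A, b, T, g = polytope.A, polytope.b, polytope.T, polytope.g
    X = np.zeros((n_chains, D))
    # overdispersed but strictly interior starts
    X += 0.1 * polytope.margin * rng.standard_normal((n_chains, D)) / np.sqrt(D)
    draws = np.empty((per_chain, n_chains, D))
    degenerate_chords = 0

    total = burn_in + per_chain * thin
    for step in range(total):
        U = rng.standard_normal((n_chains, D))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        Dirs = U @ T.T                           # isotropic in rounded coordinates
        s_minus, s_plus = _chord(X, Dirs, A, b)
        bad = ~np.isfinite(s_minus) | ~np.isfinite(s_plus) | (s_plus < s_minus)
        if np.any(bad):
            if np.any(~np.isfinite(Dirs)):
                raise FluxentError("non-finite direction in Hit-and-Run")
            degenerate_chords += int(bad.sum())
            s_minus = np.where(bad, 0.0, s_minus)
            s_plus = np.where(bad, 0.0, s_plus)
        a = beta * (Dirs @ g)
        s = _sample_truncated_exp(rng, a, s_minus, s_plus)
        X = X + s[:, None] * Dirs
        k = step - burn_in
        if k >= 0 and (k + 1) % thin == 0:
            draws[(k + 1) // thin - 1] = X

    reduced = draws.transpose(1, 0, 2).reshape(n_chains * per_chain, D)[:n_samples]
    fluxes = polytope.to_fluxes(reduced)
    lambdas = polytope.growth_reduced(reduced)
    return FluxSample(polytope=polytope, fluxes=fluxes, reduced=reduced,
                      lambdas=lambdas, beta=float(beta), seed=seed,
                      n_chains=n_chains, burn_in=burn_in, thin=thin,
                      info={"degenerate_chords": degenerate_chords,
                            "per_chain": per_chain})


def reweight(sample: FluxSample, target_beta: float,
             ess_floor: float = 0.10) -> FluxSample:
    """Importance-reweight a sample from beta to ``target_beta`` within the
    exponential family: w_k ~ exp((beta' - beta) * lambda_k), self-normalized.

    Raises :class:`EffectiveSampleSizeError` when the normalized effective
    sample size falls below ``ess_floor * n`` -- sample directly instead.
    """
    logw = (target_beta - sample.beta) * sample.lambdas
    if sample.weights is not None:
        logw = logw + np.log(sample.weights)
    logw -= logsumexp(logw)
    w = np.exp(logw)
    ess = 1.0 / np.sum(w * w)
    if ess < ess_floor * sample.n:
        raise EffectiveSampleSizeError(
            f"reweighting {sample.beta} -> {target_beta} leaves ESS = {ess:.1f} "
            f"of n = {sample.n}; sample directly at the target beta")
    out = FluxSample(polytope=sample.polytope, fluxes=sample.fluxes,
                     reduced=sample.reduced, lambdas=sample.lambdas,
                     beta=sample.beta, seed=sample.seed, n_chains=sample.n_chains,
                     burn_in=sample.burn_in, thin=sample.thin,
                     weights=w * sample.n, target_beta=float(target_beta),
                     info=dict(sample.info, ess=float(ess)))
    return out


def diagnostics(sample: FluxSample, rhat_threshold: float = 1.01) -> dict:
    """Split-chain convergence report via ArviZ: potential scale reduction
    (R-hat) and effective sample size per reduced coordinate and for lambda."""
    import arviz as az

    if sample.n_chains < 2:
        raise FluxentError("diagnostics need >= 2 chains")
    lam = sample.per_chain(sample.lambdas)
    if lam.shape[1] < 4:
        raise FluxentError("diagnostics need >= 4 draws per chain")
    red = sample.per_chain(sample.reduced)
    with np.errstate(invalid="ignore"):
        rhat_lambda = float(az.rhat(lam))
        ess_lambda = float(az.ess(lam))
        rhat_coord = np.array([float(az.rhat(red[:, :, j]))
                               for j in range(red.shape[2])])
        ess_coord = np.array([float(az.ess(red[:, :, j]))
                              for j in range(red.shape[2])])
    vals = np.append(rhat_coord, rhat_lambda)
    worst = np.nan if np.all(np.isnan(vals)) else np.nanmax(vals)
    return {"rhat_lambda": rhat_lambda, "ess_lambda": ess_lambda,
            "rhat_per_coordinate": rhat_coord, "ess_per_coordinate": ess_coord,
            "max_rhat": float(worst),
            "converged": bool(np.isfinite(worst) and worst < rhat_threshold)}


def lambda_standard_error(sample: FluxSample) -> float:
    """Monte-Carlo standard error of the mean growth rate, from the ESS of
    lambda when >= 2 chains are available, else a naive sqrt(n) estimate."""
    sd = float(np.std(sample.lambdas))
    if sample.n_chains >= 2 and sample.n // sample.n_chains >= 4:
        try:
            ess = diagnostics(sample)["ess_lambda"]
        except Exception:
            ess = sample.n
        if not np.isfinite(ess) or ess <= 0:
            ess = sample.n
        return sd / np.sqrt(ess)
    return sd / np.sqrt(sample.n)
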