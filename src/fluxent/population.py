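"""Competitive logistic growth over heterogeneous growth rates.

A population of phenotypes with intrinsic growth rates lambda_i and counts
n_i obeys  dn_i/dt = lambda_i n_i (1 - N/N_C)  with N = sum_i n_i.  The
system integrates exactly to n_i(t) = n_i(0) exp(beta(t) lambda_i) with a
single collective coordinate beta(t) = t - (1/N_C) integral_0^t N dt', so the
whole dynamics reduces to the scalar ODE

    dbeta/dt = 1 - N(beta)/N_C,      N(beta) = sum_i n_i(0) e^{beta lambda_i}.

As t -> infinity, beta converges to the root beta* of N(beta*) = N_C: the
stationary phenotype frequencies are Boltzmann weights e^{beta* lambda_i} --
the maximum-entropy distribution at fixed average growth rate, emerging here
purely from competition for a shared carrying capacity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import logsumexp

from .errors import FluxentError, NotConvergedError


@dataclass
class PopulationTrajectory:
    lambdas: np.ndarray          # (n0,)
    n_init: np.ndarray
    N_C: float
    t: np.ndarray                # (n_t,)
    beta: np.ndarray             # (n_t,)
    N: np.ndarray                # (n_t,)
    counts: np.ndarray           # (n_t, n0): n_i(t) = n_i(0) e^{beta lambda_i}

    @property
    def beta_dot_end(self) -> float:
        return float(1.0 - self.N[-1] / self.N_C)


def _validate(lambdas, n_init, N_C):
    lam = np.asarray(lambdas, dtype=float)
    n0 = np.asarray(n_init, dtype=float)
    if lam.shape != n0.shape or lam.ndim != 1:
        raise FluxentError("lambdas and n_init must be 1-D with equal length")
    if np.any(lam < 0) or np.any(n0 <= 0):
        raise FluxentError("need lambda_i >= 0 and n_i(0) > 0")
    if N_C <= n0.sum():
        raise FluxentError("carrying capacity must exceed the inoculum")
    return lam, n0


def _total(beta, lam, n0):
    return np.exp(logsumexp(beta * lam + np.log(n0)))


def simulate_logistic(lambdas, n_init, N_C: float, t_end: float,
                      n_points: int = 200, rtol: float = 1e-10,
                      atol: float = 1e-12) -> PopulationTrajectory:
    """Integrate the scalar beta-ODE and reconstruct every phenotype count."""
    lam, n0 = _validate(lambdas, n_init, N_C)

    def rhs(t, y):
        return [1.0 - _total(y[0], lam, n0) / N_C]

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), [0.0], t_eval=t_eval, rtol=rtol,
                    atol=atol, method="RK45")
    if not sol.success:
        raise NotConvergedError(f"ODE integration failed: {sol.message}")
    beta = sol.y[0]
    counts = n0 * np.exp(np.outer(beta, lam))
    return PopulationTrajectory(lambdas=lam, n_init=n0, N_C=float(N_C),
                                t=sol.t, beta=beta, N=counts.sum(axis=1),
                                counts=counts)


def steady_state_beta(lambdas, n_init, N_C: float) -> float:
    """Fixed point beta*: sum_i n_i(0) e^{beta* lambda_i} = N_C.

    This is the empirical-distribution form of the mean-field condition
    <e^{beta* lambda}>_q = N_C/N_0; monotone in beta, solved by bracketing."""
    lam, n0 = _validate(lambdas, n_init, N_C)
    if np.all(lam == 0):
        raise FluxentError("all growth rates are zero: N never reaches N_C")
    target = np.log(N_C)

    def f(beta):
        return logsumexp(beta * lam + np.log(n0)) - target

    hi = 1.0 / max(lam.max(), 1e-300)
    while f(hi) < 0:
        hi *= 2.0
        if hi * lam.max() > 1e9:
            raise NotConvergedError("could not bracket beta*")
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14))


def stationary_weights(traj: PopulationTrajectory,
                       tol: float = 1e-6) -> np.ndarray:
    """Normalized phenotype frequencies at the end of a (near-)stationary
    trajectory; frequencies are Boltzmann, ~ e^{beta* lambda_i}."""
    rate_scale = max(traj.lambdas.max(), 1e-300)
    if traj.beta_dot_end > tol * max(rate_scale, 1.0):
        raise NotConvergedError(
            f"trajectory not stationary: beta_dot(t_end) = {traj.beta_dot_end:.3g}; "
            "extend t_end")
    w = traj.counts[-1]
    return w / w.sum()
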