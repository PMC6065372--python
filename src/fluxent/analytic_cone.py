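"""Vertex-cone approximation of the growth-rate marginal, in closed form.

When the growth optimum is a simple vertex of a D-dimensional polytope, the
marginal density of the growth rate under uniform sampling is

    q(lambda) = D (lambda_max - lambda)^(D-1) / lambda_max^D,   0 <= lambda <= lambda_max.

Tilting by exp(beta * lambda) maps, through u = lambda_max - lambda, onto a
Gamma(D, 1/beta) density truncated to [0, lambda_max]; every moment and the
log-partition function are therefore regularized incomplete-gamma
expressions, stable in log space up to beta * lambda_max ~ 1e4.  This module
provides those closed forms, the information I(beta) they imply, and the
mean-field fixed point of competitive logistic growth,

    integral q(lambda) e^{beta* lambda} d lambda = N_C / N_0 .
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammainc, gammaln

_LN2 = np.log(2.0)
_X_TINY = 1e-8


@dataclass(frozen=True)
class ConeModel:
    """q(lambda) ~ (lambda_max - lambda)^(D-1) on [0, lambda_max]."""

    D: int
    lambda_max: float = 1.0

    def __post_init__(self):
        if self.D < 1 or self.lambda_max <= 0:
            raise ValueError("need D >= 1 and lambda_max > 0")

    def pdf(self, lam):
        lam = np.asarray(lam, dtype=float)
        inside = (lam >= 0) & (lam <= self.lambda_max)
        u = np.clip(self.lambda_max - lam, 0.0, None)
        return np.where(inside, self.D * u ** (self.D - 1) / self.lambda_max ** self.D, 0.0)


def log_partition(cone: ConeModel, beta: float) -> float:
    """ln of Z(beta) = integral q(lambda) e^{beta lambda} d lambda (Z(0) = 1).

    With x = beta * lambda_max:  ln Z = x + ln D + ln Gamma(D)
    + ln P(D, x) - D ln x, where P is the regularized lower incomplete gamma.
    """
    D = cone.D
    x = beta * cone.lambda_max
    if x < _X_TINY:
        return x / (D + 1.0)      # ln<e^{beta lambda}> ~ beta * lambda_bar(0)
    P = gammainc(D, x)
    if P == 0.0:                  # x astronomically small relative to D
        return x / (D + 1.0)
    return x + np.log(D) + gammaln(D) + np.log(P) - D * np.log(x)


def tilted_moments(cone: ConeModel, beta: float) -> tuple[float, float]:
    """Mean and SD of the tilted density ~ q(lambda) e^{beta lambda}.

    Exact incomplete-gamma forms; for beta -> 0 the Beta(D, 1) limits
    lambda_bar = lambda_max / (D + 1) apply.  Overflow-safe to
    beta * lambda_max ~ 1e4 (no exponentials are formed).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    D, lmax = cone.D, cone.lambda_max
    x = beta * lmax
    P = gammainc(D, x) if x > 0 else 0.0
    if x < _X_TINY or P == 0.0:
        Eu = lmax * D / (D + 1.0)
        Eu2 = lmax * lmax * D / (D + 2.0)
    else:
        Eu = (D / beta) * gammainc(D + 1, x) / P
        Eu2 = (D * (D + 1) / beta ** 2) * gammainc(D + 2, x) / P
    var = max(Eu2 - Eu * Eu, 0.0)
    return lmax - Eu, float(np.sqrt(var))


def cone_information(cone: ConeModel, beta: float) -> float:
    """Entropy reduction from the uniform marginal, in bits:
    I = [beta * lambda_bar(beta) - ln Z(beta)] / ln 2  >=  0."""
    lam_bar, _ = tilted_moments(cone, beta)
    val = (beta * lam_bar - log_partition(cone, beta)) / _LN2
    return max(float(val), 0.0)


def solve_meanfield_beta(cone: ConeModel, ratio: float,
                         x_max: float = 1e6) -> float:
    """Steady-state optimization parameter of competitive logistic growth.

    Solves Z(beta*) = N_C/N_0 for beta*; the left side is strictly increasing
    in beta, so a unique root exists for every ratio >= 1.  Returns beta*
    (multiply by lambda_max for the dimensionless form).
    """
    if ratio < 1.0:
        raise ValueError("carrying-capacity ratio N_C/N_0 must be >= 1")
    target = np.log(ratio)
    if target == 0.0:
        return 0.0
    f = lambda x: log_partition(cone, x / cone.lambda_max) - target
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > x_max:
            raise ValueError(f"no root below beta*lambda_max = {x_max}")
    x_root = brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-12)
    return x_root / cone.lambda_max
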