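"""Affine parameterization and rounding of the steady-state flux polytope.

The feasible set {v : S v = 0, lb <= v <= ub} is re-expressed in reduced
coordinates t through v = v0 + B t, where B spans the null space of S
restricted to the non-fixed fluxes and v0 is a strictly interior point
(Chebyshev center).  All box bounds become a single inequality system
A t <= b, and the growth functional becomes lambda(t) = c0 + g . t.

Rounding replaces the isotropic direction distribution of Hit-and-Run with
one adapted to the polytope's shape: an invertible transform T is estimated
by iterative covariance whitening from uniform presamples, so that the
covariance of uniform samples in whitened coordinates is well conditioned.
T changes only the proposal geometry, never the stationary distribution.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import linprog

from .errors import DegeneratePolytopeError, InfeasibleModelError
from .model_io import StoichiometricModel

_MARGIN_TOL = 1e-9


@dataclass
class FluxPolytope:
    """Reduced-coordinate representation of the feasible flux set."""

    model: StoichiometricModel
    free_idx: np.ndarray          # indices of non-fixed fluxes
    fixed_idx: np.ndarray
    fixed_values: np.ndarray
    v0: np.ndarray                # interior feasible point, full flux space (N,)
    B: np.ndarray                 # (N, D); rows at fixed fluxes are zero
    A: np.ndarray                 # (n_cons, D): A t <= b, t = 0 at v0
    b: np.ndarray
    c0: float                     # lambda(t) = c0 + g . t
    g: np.ndarray
    T: np.ndarray                 # (D, D) rounding transform (invertible)
    margin: float                 # Chebyshev radius at v0
    rounding_info: dict = dataclasses.field(default_factory=dict)

    @property
    def D(self) -> int:
        return self.B.shape[1]

    def to_fluxes(self, t: np.ndarray) -> np.ndarray:
        """Map reduced coordinates (.., D) back to flux vectors (.., N)."""
        return self.v0 + np.asarray(t) @ self.B.T

    def growth_reduced(self, t: np.ndarray) -> np.ndarray:
        return self.c0 + np.asarray(t) @ self.g

    def contains(self, v: np.ndarray, tol: float = 1e-8) -> bool:
        v = np.asarray(v)
        Sv = self.model.S @ v if self.model.n_metabolites else np.zeros(0)
        sn = np.linalg.norm(self.model.S) if self.model.n_metabolites else 1.0
        return (np.all(np.abs(Sv) <= tol * max(sn, 1.0))
                and np.all(v >= self.model.lb - tol)
                and np.all(v <= self.model.ub + tol))

    def summary(self) -> dict:
        return {"D": self.D, "n_reactions": self.model.n_reactions,
                "n_metabolites": self.model.n_metabolites,
                "n_fixed": int(self.fixed_idx.size), "margin": float(self.margin),
                "rounding": self.rounding_info}


def _chebyshev_center(A, b, norms):
    """LP for the point maximizing the minimal (row-normalized) slack."""
    D = A.shape[1]
    c = np.zeros(D + 1)
    c[-1] = -1.0
    res = linprog(c, A_ub=np.hstack([A, norms[:, None]]), b_ub=b,
                  bounds=[(None, None)] * D + [(0.0, None)], method="highs")
    if res.status == 2:
        raise InfeasibleModelError("flux bounds and steady-state constraints "
                                   "admit no common solution")
    if not res.success:
        raise InfeasibleModelError(f"interior-point LP failed: {res.message}")
    return res.x[:D], res.x[-1]


def build_polytope(model: StoichiometricModel, rank_tol: float | None = None) -> FluxPolytope:
    """Construct the reduced polytope of a validated model.

    Fluxes with lb == ub are eliminated before the null-space computation and
    re-inserted as constants.  The null space of the remaining system is
    computed by SVD with relative rank tolerance ``rank_tol`` (default
    ``1e-9 * s_max``).  Raises :class:`InfeasibleModelError` if the
    constraints are inconsistent and :class:`DegeneratePolytopeError` if the
    feasible set has no interior (D = 0 or zero Chebyshev margin).
    """
    N = model.n_reactions
    fixed = np.isclose(model.lb, model.ub)
    free_idx = np.flatnonzero(~fixed)
    fixed_idx = np.flatnonzero(fixed)
    fixed_values = 0.5 * (model.lb[fixed_idx] + model.ub[fixed_idx])
    if free_idx.size == 0:
        raise DegeneratePolytopeError("all fluxes are fixed; nothing to sample")

    if model.n_metabolites:
        S_free = model.S[:, free_idx]
        rhs = -model.S[:, fixed_idx] @ fixed_values if fixed_idx.size else np.zeros(model.n_metabolites)
        vp_free, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
        resid = np.linalg.norm(S_free @ vp_free - rhs)
        scale = max(np.linalg.norm(S_free), 1.0)
        if resid > 1e-8 * scale * max(1.0, np.linalg.norm(fixed_values)):
            raise InfeasibleModelError(
                "steady-state equalities are inconsistent with the fixed fluxes "
                f"(residual {resid:.3g})")
        # rcond is relative to the largest singular value inside null_space
        B_free = scipy.linalg.null_space(S_free, rcond=rank_tol or 1e-9)
    else:
        vp_free = np.zeros(free_idx.size)
        B_free = np.eye(free_idx.size)

    D = B_free.shape[1]
    if D == 0:
        raise DegeneratePolytopeError(
            "the steady-state constraints fix every remaining flux (D = 0)")

    # box bounds in reduced coordinates, anchored at the particular solution
    lo = model.lb[free_idx] - vp_free
    hi = model.ub[free_idx] - vp_free
    keep = np.linalg.norm(B_free, axis=1) > 1e-12
    A = np.vstack([B_free[keep], -B_free[keep]])
    b_p = np.concatenate([hi[keep], -lo[keep]])
    norms = np.linalg.norm(A, axis=1)

    t_c, margin = _chebyshev_center(A, b_p, norms)
    if margin <= _MARGIN_TOL:
        raise DegeneratePolytopeError(
            f"polytope has empty interior (Chebyshev margin {margin:.3g})")

    v0 = np.empty(N)
    v0[free_idx] = vp_free + B_free @ t_c
    v0[fixed_idx] = fixed_values
    B = np.zeros((N, D))
    B[free_idx] = B_free
    b = b_p - A @ t_c                      # shift so t = 0 sits at v0

    g = B.T @ model.biomass
    return FluxPolytope(model=model, free_idx=free_idx, fixed_idx=fixed_idx,
                        fixed_values=fixed_values, v0=v0, B=B, A=A, b=b,
                        c0=float(model.biomass @ v0), g=g, T=np.eye(D),
                        margin=float(margin))


def find_interior_point(polytope: FluxPolytope) -> np.ndarray:
    """Chebyshev-center interior point of an existing polytope, in flux space."""
    norms = np.linalg.norm(polytope.A, axis=1)
    t_c, margin = _chebyshev_center(polytope.A, polytope.b, norms)
    if margin <= _MARGIN_TOL:
        raise DegeneratePolytopeError(f"zero maximal margin ({margin:.3g})")
    return polytope.to_fluxes(t_c)


def round_polytope(polytope: FluxPolytope, n_presamples: int = 2000,
                   max_rounds: int = 5, cond_target: float = 10.0,
                   seed: int = 0) -> FluxPolytope:
    """Estimate a rounding transform by iterative covariance whitening.

    Uniform (beta = 0) presamples are drawn with the current transform; the
    sample covariance C of the reduced coordinates is measured, and while the
    condition number of C in whitened coordinates exceeds ``cond_target`` the
    transform is replaced by a Cholesky factor of C.  Returns a new polytope
    with the updated T and a ``rounding_info`` record; non-convergence is
    reported there, never raised.
    """
    from .sampler import hit_and_run   # deferred: sampler imports this module

    P = dataclasses.replace(polytope, T=np.eye(polytope.D), rounding_info={})
    cond = np.inf
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        s = hit_and_run(P, beta=0.0, n_samples=n_presamples, n_chains=4,
                        seed=seed + rounds, progress=False)
        C = np.atleast_2d(np.cov(s.reduced, rowvar=False))
        Cw = np.linalg.solve(P.T, np.linalg.solve(P.T, C).T)  # T^-1 C T^-T
        w = np.linalg.eigvalsh(0.5 * (Cw + Cw.T))
        cond = float(w[-1] / max(w[0], 1e-300))
        if cond <= cond_target:
            break
        jitter = 1e-12 * np.trace(C) / P.D
        P = dataclasses.replace(P, T=np.linalg.cholesky(C + jitter * np.eye(P.D)))
    P.rounding_info.update({"rounds": rounds, "condition": cond,
                            "converged": bool(cond <= cond_target),
                            "cond_target": cond_target})
    return P
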