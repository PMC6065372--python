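"""Flux balance analysis: the beta -> infinity limit of the flux ensemble.

FBA finds the single flux configuration v_max maximizing the growth
functional lambda(v) = xi . v over the steady-state polytope, by linear
programming.  Alternate optima are not resolved; instead the returned vertex
carries a degeneracy flag detected by random objective perturbation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleModelError, UnboundedProblemError
from .model_io import StoichiometricModel


@dataclass
class FBASolution:
    lambda_max: float
    v_max: np.ndarray
    status: str
    degenerate: bool = False

    def zero_fluxes(self, zero_tol: float | None = None) -> np.ndarray:
        tol = zero_tol if zero_tol is not None else 1e-6 * np.max(np.abs(self.v_max))
        return np.abs(self.v_max) < tol


def _lp(model: StoichiometricModel, c: np.ndarray):
    A_eq = model.S if model.n_metabolites else None
    b_eq = np.zeros(model.n_metabolites) if model.n_metabolites else None
    return linprog(c, A_eq=A_eq, b_eq=b_eq,
                   bounds=list(zip(model.lb, model.ub)), method="highs")


def solve_fba(model: StoichiometricModel, *, check_degeneracy: bool = True,
              seed: int = 0) -> FBASolution:
    """Maximize growth by LP; raises on infeasible or unbounded problems."""
    res = _lp(model, -model.biomass)
    if res.status == 2:
        raise InfeasibleModelError("FBA problem is infeasible")
    if res.status == 3:
        # with finite bound caps this should not occur; name a culprit if we can
        big = np.flatnonzero(~np.isfinite(model.lb) | ~np.isfinite(model.ub))
        hint = f" (unbounded reaction: {model.reaction_ids[big[0]]})" if big.size else ""
        raise UnboundedProblemError("FBA objective is unbounded" + hint)
    if not res.success:
        raise InfeasibleModelError(f"LP solver failure: {res.message}")
    v_max = res.x
    lam = float(model.biomass @ v_max)

    degenerate = False
    if check_degeneracy:
        # perturb the objective along a random direction; if the optimal vertex
        # moves while the optimum stays (to tolerance), the optimal face has
        # dimension > 0
        rng = np.random.default_rng(seed)
        scale = max(np.max(np.abs(model.biomass)), 1.0)
        for _ in range(4):       # +-epsilon along a few random directions
            # must exceed the LP solver's dual tolerance to act as a tie-break
            pert = 1e-5 * scale * rng.standard_normal(model.n_reactions)
            res_p = _lp(model, -(model.biomass + pert))
            if not res_p.success:
                continue
            same_opt = abs(float(model.biomass @ res_p.x) - lam) <= 1e-6 * max(abs(lam), 1.0)
            moved = np.max(np.abs(res_p.x - v_max)) > 1e-4 * max(np.max(np.abs(v_max)), 1.0)
            if same_opt and moved:
                degenerate = True
                break

    return FBASolution(lambda_max=lam, v_max=v_max, status="optimal",
                       degenerate=degenerate)


def count_zero_fluxes(solution: FBASolution, zero_tol: float | None = None) -> int:
    """Number of fluxes at (numerical) zero in the FBA optimum."""
    return int(np.count_nonzero(solution.zero_fluxes(zero_tol)))
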