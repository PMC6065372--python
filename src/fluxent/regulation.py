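"""Cost of regulation: growth net of the price of information.

Localising the flux distribution to reach a mean growth rate lambda_bar(beta)
requires at least I(beta) bits of regulatory information.  If that
information is carried by K parallel Gaussian channels whose molecular cost
scales with signal-to-noise, the effective growth rate becomes

    lambda_eff(beta) = lambda_bar(beta) - alpha * K * (2^{2 I(beta)/K} - 1),

where alpha (1/h per regulatory unit) prices one unit of channel capacity.
Because I(beta) grows without bound as lambda_bar -> lambda_max while
lambda_bar stays bounded, any alpha > 0 turns the monotone lambda_bar(beta)
curve into one with an interior optimum: the model's resolution of the
speed-vs-control trade-off.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FluxentError


@dataclass
class RegulationModel:
    """alpha, K together with matched lambda_bar and I curves on one beta grid."""

    alpha: float
    K: int
    betas: np.ndarray
    lambda_mean: np.ndarray
    info_bits: np.ndarray

    def __post_init__(self):
        if self.alpha < 0 or self.K < 1:
            raise FluxentError("need alpha >= 0 and K >= 1")
        self.betas = np.asarray(self.betas, dtype=float)
        self.lambda_mean = np.asarray(self.lambda_mean, dtype=float)
        self.info_bits = np.asarray(self.info_bits, dtype=float)
        if not (self.betas.shape == self.lambda_mean.shape == self.info_bits.shape):
            raise FluxentError("beta, lambda_bar and I grids do not match")

    @classmethod
    def from_ladder(cls, ladder, alpha: float, K: int | None = None):
        """K defaults to the polytope dimension proxy: the number of fluxes
        whose variability the ladder resolves is not known here, so callers
        normally pass K = D explicitly; without it we fall back to K = grid
        length - 1 as a crude stand-in."""
        if ladder.info_bits is None:
            raise FluxentError("ladder carries no information curve")
        return cls(alpha=alpha, K=K if K is not None else max(len(ladder.betas) - 1, 1),
                   betas=ladder.betas, lambda_mean=ladder.lambda_mean,
                   info_bits=ladder.info_bits)


def effective_growth(model: RegulationModel) -> np.ndarray:
    """lambda_eff on the model's beta grid."""
    penalty = model.alpha * model.K * (np.exp2(2.0 * model.info_bits / model.K) - 1.0)
    return model.lambda_mean - penalty


def optimal_beta(model: RegulationModel) -> dict:
    """Argmax of lambda_eff with an {interior, boundary, degenerate} flag.

    The grid argmax is refined by a local quadratic fit through the argmax
    and its neighbours when it is interior."""
    eff = effective_growth(model)
    if np.ptp(eff) < 1e-12 * max(np.max(np.abs(eff)), 1.0):
        return {"beta_opt": float(model.betas[0]), "lambda_eff_opt": float(eff[0]),
                "flag": "degenerate"}
    k = int(np.argmax(eff))
    if k == 0 or k == eff.size - 1:
        return {"beta_opt": float(model.betas[k]), "lambda_eff_opt": float(eff[k]),
                "flag": "boundary"}
    b3, e3 = model.betas[k - 1: k + 2], eff[k - 1: k + 2]
    a2, a1, _ = np.polyfit(b3, e3, 2)
    beta_opt = -a1 / (2.0 * a2) if a2 < 0 else model.betas[k]
    beta_opt = float(np.clip(beta_opt, b3[0], b3[2]))
    return {"beta_opt": beta_opt,
            "lambda_eff_opt": float(np.polyval(np.polyfit(b3, e3, 2), beta_opt)),
            "flag": "interior"}
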