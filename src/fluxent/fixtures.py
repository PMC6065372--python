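"""Synthetic fixtures: toy networks with analytic ground truth, and synthetic
single-cell lineage data.

These stand in, at desk scale, for a genome-scale catabolic core: each toy's
polytope dimension, maximal growth rate and (where applicable) closed-form
growth marginal are known by construction, so the sampler and every ensemble
statistic can be validated without external model files.

Kinds
-----
interval
    One bounded reaction, lambda(v) = v on [lo, hi]; the ensemble's growth
    marginal is a truncated exponential with every moment in closed form.
chain
    Linear pathway uptake -> A -> B -> export; mass balance couples all three
    fluxes, so D = 1 with lambda_max set by the uptake cap.
diamond
    Uptake feeding two parallel routes of unequal yield; FBA picks the
    efficient branch and zeroes the dominated one.
simplex
    D fluxes plus a slack draining a single pool fed at a fixed rate;
    the growth marginal of lambda = v_1 is EXACTLY the vertex-cone density
    with dimension D, making the analytic cone an exact oracle end to end.
random
    Dense random stoichiometry with a known null-space dimension and bounds
    built around a feasible point; used for rounding and invariance tests.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FluxentError
from .growthfit import GrowthRateModel
from .model_io import StoichiometricModel


def interval_moments(beta: float, lo: float = 0.0, hi: float = 1.0):
    """Closed-form mean and SD of the truncated exponential ~ e^{beta v} on
    [lo, hi] -- the interval toy's growth marginal."""
    d = hi - lo
    x = beta * d
    if abs(x) < 1e-10:
        return lo + d / 2.0, d / np.sqrt(12.0)
    # moments of y = v - lo on [0, d]
    m1 = d / (1.0 - np.exp(-x)) - 1.0 / beta
    var = 1.0 / beta ** 2 - d ** 2 * np.exp(-x) / (1.0 - np.exp(-x)) ** 2
    return lo + m1, float(np.sqrt(max(var, 0.0)))


def interval_information_bits(beta: float, lo: float = 0.0, hi: float = 1.0) -> float:
    """Closed-form I(beta) in bits for the interval toy (Z relative to the
    uniform distribution on [lo, hi])."""
    d = hi - lo
    x = beta * d
    if abs(x) < 1e-10:
        return 0.0
    m1, _ = interval_moments(beta, lo, hi)
    lnZ = beta * lo + np.log(np.expm1(x) / x)      # <e^{beta v}> under uniform
    return float((beta * m1 - lnZ) / np.log(2.0))


def make_toy_network(kind: str, **params):
    """Build a toy model plus its machine-readable ground-truth record."""
    builders = {"interval": _interval, "chain": _chain, "diamond": _diamond,
                "simplex": _simplex, "random": _random_net}
    if kind not in builders:
        raise FluxentError(f"unknown toy network kind '{kind}' "
                           f"(known: {sorted(builders)})")
    return builders[kind](**params)


def _interval(lo: float = 0.0, hi: float = 1.0):
    model = StoichiometricModel([], ["v"], np.zeros((0, 1)), [lo], [hi], [1.0],
                                biomass_id="v", name="interval")
    gt = {"kind": "interval", "D": 1, "lambda_max": hi, "lo": lo, "hi": hi,
          "marginal": "truncated_exponential"}
    return model, gt


def _chain(uptake_cap: float = 10.0, internal_cap: float = 100.0):
    mets = ["A", "B"]
    rids = ["uptake", "conv", "export"]
    S = np.array([[1.0, -1.0, 0.0],
                  [0.0, 1.0, -1.0]])
    lb = [0.0, 0.0, 0.0]
    ub = [uptake_cap, internal_cap, internal_cap]
    xi = [0.0, 0.0, 1.0]
    model = StoichiometricModel(mets, rids, S, lb, ub, xi,
                                biomass_id="export", name="chain")
    gt = {"kind": "chain", "D": 1, "lambda_max": uptake_cap,
          "marginal": "truncated_exponential", "lo": 0.0, "hi": uptake_cap}
    return model, gt


def _diamond(uptake_cap: float = 10.0, low_yield: float = 0.5,
             internal_cap: float = 100.0):
    mets = ["A", "B"]
    rids = ["uptake", "branch_hi", "branch_lo", "bio"]
    S = np.array([[1.0, -1.0, -1.0, 0.0],
                  [0.0, 1.0, low_yield, -1.0]])
    lb = [0.0] * 4
    ub = [uptake_cap, internal_cap, internal_cap, internal_cap]
    xi = [0.0, 0.0, 0.0, 1.0]
    model = StoichiometricModel(mets, rids, S, lb, ub, xi,
                                biomass_id="bio", name="diamond")
    gt = {"kind": "diamond", "D": 2, "lambda_max": uptake_cap,
          "fba_vertex": {"uptake": uptake_cap, "branch_hi": uptake_cap,
                         "branch_lo": 0.0, "bio": uptake_cap},
          "dominated_branch": "branch_lo"}
    return model, gt


def _simplex(dim: int = 3, lambda_max: float = 1.0):
    if dim < 1:
        raise FluxentError("simplex dimension must be >= 1")
    rids = ["feed"] + [f"v{i}" for i in range(1, dim + 1)] + ["slack"]
    S = np.zeros((1, dim + 2))
    S[0, 0] = 1.0
    S[0, 1:] = -1.0
    lb = np.zeros(dim + 2)
    ub = np.full(dim + 2, lambda_max)
    lb[0] = lambda_max                      # feed fixed: sum of drains = lambda_max
    xi = np.zeros(dim + 2)
    xi[1] = 1.0
    model = StoichiometricModel(["pool"], rids, S, lb, ub, xi,
                                biomass_id="v1", name=f"simplex{dim}")
    gt = {"kind": "simplex", "D": dim, "lambda_max": lambda_max,
          "marginal": "cone", "cone_D": dim}
    return model, gt


def _random_net(dim: int = 5, n_reactions: int = 12, seed: int = 0):
    if n_reactions <= dim:
        raise FluxentError("need n_reactions > dim")
    rng = np.random.default_rng(seed)
    M = n_reactions - dim
    S = rng.standard_normal((M, n_reactions))
    # a feasible point in the null space, with bounds built around it
    from scipy.linalg import null_space
    B = null_space(S)
    v_star = B @ rng.standard_normal(dim)
    half = rng.uniform(0.5, 1.5, n_reactions)
    lb, ub = v_star - half, v_star + half
    xi = rng.standard_normal(n_reactions)
    xi /= np.linalg.norm(xi)
    mets = [f"m{j}" for j in range(M)]
    rids = [f"r{i}" for i in range(n_reactions)]
    model = StoichiometricModel(mets, rids, S, lb, ub, xi, name=f"random{dim}")
    return model, {"kind": "random", "D": dim, "seed": seed}


def generate_lineage_data(model: GrowthRateModel, n_lineages: int = 100,
                          events_per_lineage: int = 50,
                          lineage_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Synthetic mother-machine-style lineage table.

    Each lineage draws its division-event growth rates from Q with a
    per-lineage multiplicative jitter of lambda_max (relative SD
    ``lineage_sd``); event times accumulate one doubling time per event.
    Output is byte-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for lin in range(n_lineages):
        lmax = model.lambda_max * max(1.0 + lineage_sd * rng.standard_normal(), 0.05)
        q = GrowthRateModel(beta=model.beta, lambda_max=lmax, D=model.D)
        lam = q.rvs(events_per_lineage, rng=rng)
        lam = np.clip(lam, 1e-9 * lmax, None)
        t = np.cumsum(np.log(2.0) / lam)
        rows.append(pd.DataFrame({"lineage_id": lin, "time": t, "growth_rate": lam}))
    return pd.concat(rows, ignore_index=True)
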