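import numpy as np
import pytest

from fluxent import (DegeneratePolytopeError, InfeasibleModelError,
                     build_polytope, find_interior_point, hit_and_run,
                     make_toy_network, round_polytope)
from fluxent.model_io import StoichiometricModel


def test_dimension_bookkeeping(interval, simplex3):
    _, gt1, P1 = interval
    assert P1.D == gt1["D"] == 1
    _, gt3, P3 = simplex3
    # independent oracle: D = n_free - rank(S_free)
    m3 = P3.model
    free = ~np.isclose(m3.lb, m3.ub)
    rank = np.linalg.matrix_rank(m3.S[:, free])
    assert P3.D == free.sum() - rank == gt3["D"]


def test_chain_is_one_dimensional():
    model, gt = make_toy_network("chain")
    P = build_polytope(model)
    assert P.D == 1 == np.shape(model.S)[1] - np.linalg.matrix_rank(model.S)
    # all three fluxes move together along the single degree of freedom
    direction = P.B[:, 0]
    assert np.allclose(direction / direction[0], 1.0)


def test_single_reaction_interval(interval):
    model, _, P = interval
    assert P.D == 1
    assert model.lb[0] < P.v0[0] < model.ub[0]
    assert P.margin == pytest.approx(0.5)


def test_interior_point_symmetry(unit_square):
    _, P = unit_square
    v0 = find_interior_point(P)
    np.testing.assert_allclose(v0, [0.5, 0.5], atol=1e-8)

    model10 = StoichiometricModel([], ["v"], np.zeros((0, 1)), [0.0], [10.0], [1.0])
    P10 = build_polytope(model10)
    np.testing.assert_allclose(find_interior_point(P10), [5.0], atol=1e-8)


def test_interior_point_matches_grid_oracle(triangle):
    """Chebyshev center of the triangle agrees with a brute-force grid
    maximization of the minimal normalized slack."""
    _, _, P = triangle
    norms = np.linalg.norm(P.A, axis=1)

    def min_slack(t):
        return np.min((P.b - P.A @ t) / norms)

    grid = np.linspace(-1.0, 1.0, 241)
    best, best_t = -np.inf, None
    for t1 in grid:
        for t2 in grid:
            s = min_slack(np.array([t1, t2]))
            if s > best:
                best, best_t = s, np.array([t1, t2])
    assert P.margin == pytest.approx(best, abs=0.01)
    v_lp = find_interior_point(P)
    v_grid = P.to_fluxes(best_t)
    np.testing.assert_allclose(v_lp, v_grid, atol=0.02)


def test_infeasible_and_degenerate_signals():
    # bounds force v = 5 on both reactions of A -> (conservation broken)
    m = StoichiometricModel(["A"], ["in", "out"], [[1.0, -2.0]],
                            [5.0, 5.0], [5.0, 5.0], [0.0, 1.0])
    with pytest.raises((InfeasibleModelError, DegeneratePolytopeError)):
        build_polytope(m)
    # equalities fix the only free direction: D = 0
    m2 = StoichiometricModel(["A"], ["in", "out"], [[1.0, -1.0]],
                             [3.0, 0.0], [3.0, 10.0], [0.0, 1.0])
    with pytest.raises(DegeneratePolytopeError):
        build_polytope(m2)


def test_reconstruction_satisfies_constraints(simplex3):
    model, _, P = simplex3
    s = hit_and_run(P, 1.5, 2000, seed=0)
    V = s.fluxes
    Sv = V @ model.S.T
    assert np.max(np.abs(Sv)) <= 1e-8 * max(np.linalg.norm(model.S), 1.0)
    assert np.all(V >= model.lb - 1e-8)
    assert np.all(V <= model.ub + 1e-8)


def test_dimension_invariant_under_permutation():
    model, gt = make_toy_network("random", dim=4, n_reactions=9, seed=3)
    P = build_polytope(model)
    rng = np.random.default_rng(0)
    pr = rng.permutation(model.n_reactions)
    pm = rng.permutation(model.n_metabolites)
    perm = StoichiometricModel([model.metabolite_ids[i] for i in pm],
                               [model.reaction_ids[i] for i in pr],
                               model.S[np.ix_(pm, pr)], model.lb[pr],
                               model.ub[pr], model.biomass[pr])
    assert build_polytope(perm).D == P.D == gt["D"]


def test_rounding_whitens_anisotropic_box():
    """Rectangle [0,1] x [0,100]: raw uniform covariance has condition ~1e4;
    rounding must bring the whitened condition below 2."""
    model = StoichiometricModel([], ["x", "y"], np.zeros((0, 2)),
                                [0.0, 0.0], [1.0, 100.0], [1.0, 0.0])
    P = round_polytope(build_polytope(model), n_presamples=4000, seed=0)
    s = hit_and_run(P, 0.0, 4000, seed=1)
    C = np.cov(s.reduced, rowvar=False)
    Cw = np.linalg.solve(P.T, np.linalg.solve(P.T, C).T)
    w = np.linalg.eigvalsh(0.5 * (Cw + Cw.T))
    assert w[-1] / w[0] < 2.0
    assert P.rounding_info["converged"]


def test_rounding_reduces_condition_on_random_polytope():
    model, _ = make_toy_network("random", dim=5, n_reactions=12, seed=7)
    P0 = build_polytope(model)
    s0 = hit_and_run(P0, 0.0, 6000, seed=2)
    w0 = np.linalg.eigvalsh(np.cov(s0.reduced, rowvar=False))
    cond0 = w0[-1] / w0[0]
    P1 = round_polytope(P0, n_presamples=4000, cond_target=2.0, seed=3)
    s1 = hit_and_run(P1, 0.0, 6000, seed=4)
    C1 = np.cov(s1.reduced, rowvar=False)
    Cw = np.linalg.solve(P1.T, np.linalg.solve(P1.T, C1).T)
    w1 = np.linalg.eigvalsh(0.5 * (Cw + Cw.T))
    assert w1[-1] / w1[0] < cond0
    # rounding is an affine change of proposal geometry only: D unchanged
    assert P1.D == P0.D


def test_isotropic_box_needs_no_rounding(unit_square):
    _, P = unit_square
    Pr = round_polytope(P, n_presamples=3000, seed=5)
    assert Pr.rounding_info["rounds"] == 1
    np.testing.assert_allclose(Pr.T, np.eye(2))
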