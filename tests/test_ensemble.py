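import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from fluxent import (FluxentError, MeasuredFluxTable, NotConvergedError,
                     build_ladder, cluster_correlations, compute_moments,
                     fit_beta, fold_change, growth_marginal, hit_and_run,
                     information_curve, mse_fluxes, variability_scaling)
from fluxent.ensemble import BetaLadder
from fluxent.fixtures import interval_information_bits, interval_moments
from fluxent.sampler import FluxSample


def fabricate_sample(polytope, fluxes, beta=0.0):
    fluxes = np.asarray(fluxes, dtype=float)
    lam = fluxes @ polytope.model.biomass
    return FluxSample(polytope=polytope, fluxes=fluxes,
                      reduced=np.zeros((fluxes.shape[0], polytope.D)),
                      lambdas=lam, beta=beta, seed=0, n_chains=1,
                      burn_in=0, thin=1)


class TestMoments:
    def test_hand_computed_3x2(self, unit_square):
        _, P = unit_square
        s = fabricate_sample(P, [[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        m = compute_moments(s)
        np.testing.assert_allclose(m.means, [2.0, 4.0])
        np.testing.assert_allclose(m.sds, [np.sqrt(2 / 3), np.sqrt(8 / 3)])
        assert m.lambda_mean == pytest.approx(2.0)

    def test_constant_column_flagged(self, unit_square):
        _, P = unit_square
        s = fabricate_sample(P, [[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]])
        m = compute_moments(s)
        assert m.sds["x"] == 0.0
        assert m.cv_undefined["x"] and np.isnan(m.cvs["x"])
        assert "x" in m.corr_excluded          # no correlation for a constant

    def test_simplex_constraint_forces_anticorrelation(self, triangle):
        _, _, P = triangle
        s = hit_and_run(P, 5.0, 8000, seed=0)
        m = compute_moments(s, flux_subset=["v1", "v2"])
        assert m.corr.loc["v1", "v2"] < -0.1


class TestFitBeta:
    def test_uniform_mean_gives_zero(self, interval):
        _, _, P = interval
        with pytest.warns(UserWarning):
            b, _ = fit_beta(P, 0.2, n_samples=2000, seed=0)
        assert b == 0.0

    def test_interval_inverts_closed_form(self, interval):
        _, _, P = interval
        b, info = fit_beta(P, interval_moments(2.0)[0], n_samples=6000, seed=1)
        assert b == pytest.approx(2.0, abs=0.25)     # MC-limited tolerance
        assert info["lambda_at_fit"] == pytest.approx(0.6565, abs=0.01)

    def test_unreachable_growth_errors(self, interval):
        _, _, P = interval
        with pytest.raises(FluxentError):
            fit_beta(P, 1.5, n_samples=500, seed=2)


class TestInformation:
    def test_zero_at_beta_zero_and_nondecreasing(self, interval):
        _, _, P = interval
        lad = build_ladder(P, np.linspace(0, 2, 11), n_samples=3000, seed=3)
        assert lad.info_bits[0] == 0.0
        # non-decreasing within MC error of neighbouring estimates
        slack = 3 * np.hypot(lad.info_se[1:], lad.info_se[:-1])
        assert np.all(np.diff(lad.info_bits) > -slack)

    def test_interval_value_matches_closed_form(self, interval):
        _, _, P = interval
        lad = build_ladder(P, np.linspace(0, 2, 21), n_samples=4000, seed=4)
        expected = interval_information_bits(2.0)
        assert expected == pytest.approx(0.2187, abs=1e-3)
        assert abs(lad.info_bits[-1] - expected) < 3 * max(lad.info_se[-1], 1e-3)

    def test_decreasing_lambda_rejected(self):
        lad = BetaLadder(betas=np.array([0.0, 1.0, 2.0]),
                         lambda_mean=np.array([0.5, 0.7, 0.4]),
                         lambda_sd=np.zeros(3), lambda_se=np.full(3, 1e-4),
                         flux_means=np.zeros((3, 1)), flux_sds=np.zeros((3, 1)),
                         lambda_max=1.0)
        with pytest.raises(NotConvergedError):
            information_curve(lad)


class TestMSE:
    def test_perfect_prediction_is_zero(self, unit_square):
        _, P = unit_square
        s = fabricate_sample(P, [[1.0, 0.5], [1.0, 0.5]])
        t = MeasuredFluxTable(["y"], [0.5])
        assert mse_fluxes(s, t, "x") == pytest.approx(0.0)

    def test_hand_arithmetic(self, unit_square):
        _, P = unit_square
        # normalizer mean 1, predictions (2, 4) vs measured (1, 2) -> MSE 2.5
        means = pd.Series({"x": 1.0, "y": 2.0, "z": 4.0})
        t = MeasuredFluxTable(["y", "z"], [1.0, 2.0])
        assert mse_fluxes(means, t, "x") == pytest.approx(2.5)

    def test_zero_normalizer_errors(self, unit_square):
        _, P = unit_square
        s = fabricate_sample(P, [[0.0, 1.0], [0.0, 1.0]])
        with pytest.raises(FluxentError):
            mse_fluxes(s, MeasuredFluxTable(["y"], [1.0]), "x")


class TestFoldChange:
    def test_self_comparison_is_zero(self, interval):
        _, _, P = interval
        s = hit_and_run(P, 0.0, 2000, seed=5)
        fc = fold_change(s, s)
        np.testing.assert_allclose(fc["log_fold_change"].to_numpy(), 0.0)

    def test_interval_closed_form(self, interval):
        _, _, P = interval
        s0 = hit_and_run(P, 0.0, 15000, seed=6)
        s2 = hit_and_run(P, 2.0, 15000, seed=7)
        fc = fold_change(s2, s0)["log_fold_change"]["v"]
        assert fc == pytest.approx(np.log(interval_moments(2.0)[0] / 0.5), abs=0.02)

    def test_sign_change_flag(self, unit_square):
        _, P = unit_square
        s0 = fabricate_sample(P, [[0.5, 1.0]] * 4)
        sb = fabricate_sample(P, [[-0.3, 1.0]] * 4, beta=2.0)
        fc = fold_change(sb, s0)
        assert bool(fc["sign_change"]["x"])
        assert not bool(fc["sign_change"]["y"])


class TestGrowthMarginal:
    def test_uniform_interval_is_flat(self, interval):
        _, _, P = interval
        s = hit_and_run(P, 0.0, 20000, seed=8)
        centers, dens, edges = growth_marginal(s, n_bins=10, support=(0, 1))
        np.testing.assert_allclose(dens, 1.0, atol=0.1)
        assert (dens * np.diff(edges)).sum() == pytest.approx(1.0)

    def test_triangle_uniform_marginal_is_linear(self, triangle):
        _, _, P = triangle
        s = hit_and_run(P, 0.0, 20000, seed=9)
        centers, dens, _ = growth_marginal(s, n_bins=10, support=(0, 1))
        np.testing.assert_allclose(dens, 2 * (1 - centers), atol=0.12)


class TestClustering:
    def test_block_diagonal_exact_recovery(self):
        C = np.block([[np.ones((3, 3)), -np.ones((3, 2))],
                      [-np.ones((2, 3)), np.ones((2, 2))]])
        labels = cluster_correlations(C, 2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_noisy_blocks_mostly_recovered(self):
        rng = np.random.default_rng(0)
        sizes = [8, 8, 8]
        X = []
        for k, n in enumerate(sizes):
            base = rng.standard_normal(500)
            X.append(base[:, None] + 0.5 * rng.standard_normal((500, n)))
        C = np.corrcoef(np.hstack(X), rowvar=False)
        labels = cluster_correlations(C, 3)
        truth = np.repeat([0, 1, 2], 8)
        # agreement up to label permutation
        from itertools import permutations
        best = max(np.mean(np.array([p[t] for t in truth]) == labels)
                   for p in permutations(range(3)))
        assert best >= 0.9

    def test_identity_and_errors(self):
        I3 = np.eye(3)
        assert len(set(cluster_correlations(I3, 3))) == 3
        with pytest.raises(FluxentError):
            cluster_correlations(I3, 4)
        with pytest.raises(FluxentError):
            cluster_correlations(np.array([[1.0, 0.5], [0.1, 1.0]]), 2)


class TestVariabilityScaling:
    def test_interval_loglog_slope_minus_one(self, interval):
        _, _, P = interval
        betas = np.concatenate([[0.0], np.geomspace(1, 400, 10)])
        lad = build_ladder(P, betas, n_samples=4000, seed=10,
                           compute_information=False)
        fit = variability_scaling(lad)
        assert fit.growth_loglog_slope == pytest.approx(-1.0, abs=0.08)
        # per-flux shrinkage is proportional in (1 - lambda/lambda_max)
        slope = fit.per_flux_slope["v"]
        assert np.isfinite(slope) and slope > 0

    def test_shallow_ladder_rejected(self, interval):
        _, _, P = interval
        lad = build_ladder(P, np.array([0.0, 0.5, 1.0]), n_samples=1000,
                           seed=11, compute_information=False)
        with pytest.raises(NotConvergedError):
            variability_scaling(lad)
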