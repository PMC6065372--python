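import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from fluxent import (FluxentError, GrowthRateModel, binned_scaling,
                     fit_growth_distribution, generate_lineage_data,
                     lineage_statistics, scaling_regression)


class TestModel:
    def test_density_normalized_and_moments_match_quadrature(self):
        q = GrowthRateModel(beta=12.0, lambda_max=0.8, D=5)
        Z = integrate.quad(q.pdf, 0, q.lambda_max)[0]
        assert Z == pytest.approx(1.0, rel=1e-8)
        mean = integrate.quad(lambda l: l * q.pdf(l), 0, q.lambda_max)[0]
        assert q.mean == pytest.approx(mean, rel=1e-8)

    def test_rvs_matches_cdf(self):
        q = GrowthRateModel(beta=30.0, lambda_max=1.0, D=8)
        x = q.rvs(20000, rng=0)
        from scipy.stats import kstest
        assert kstest(x, q.cdf).pvalue > 0.01

    def test_uniform_limit_mle_lambda_max_is_sample_max(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 0.7, 2000)
        fit = fit_growth_distribution(x, D=1)
        assert fit.lambda_max == pytest.approx(x.max(), rel=1e-3)
        assert fit.beta * fit.lambda_max < 0.2       # essentially untilted


class TestFitting:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_parameter_recovery_fixed_D(self, seed):
        true = GrowthRateModel(beta=120.0, lambda_max=1.0, D=23)
        x = true.rvs(5000, rng=seed)
        fit = fit_growth_distribution(x, D=23)
        assert fit.beta * fit.lambda_max == pytest.approx(120.0, rel=0.15)
        assert fit.lambda_max == pytest.approx(1.0, rel=0.05)

    def test_fitted_D_recovers_reasonable_shape(self):
        true = GrowthRateModel(beta=40.0, lambda_max=1.0, D=5)
        x = true.rvs(8000, rng=3)
        fit = fit_growth_distribution(x, D=None, d_range=(1, 15))
        assert 3 <= fit.D <= 8
        assert fit.fit_info["ks_pvalue"] > 0.01

    def test_self_consistent_sigma(self):
        true = GrowthRateModel(beta=80.0, lambda_max=1.0, D=10)
        x = true.rvs(5000, rng=4)
        fit = fit_growth_distribution(x, D=10)
        assert fit.sd == pytest.approx(x.std(), rel=0.1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(FluxentError):
            fit_growth_distribution(np.linspace(0.1, 0.5, 10))
        with pytest.raises(FluxentError):
            fit_growth_distribution(np.array([-0.1] + [0.3] * 40))


class TestLineageStats:
    def test_hand_arithmetic(self):
        df = pd.DataFrame({"lineage_id": [0, 0], "growth_rate": [0.2, 0.4]})
        stats, dropped = lineage_statistics(df)
        assert dropped == 0
        row = stats.loc[0]
        assert row["lambda_mean"] == pytest.approx(0.3)
        assert row["lambda_max"] == pytest.approx(0.4)
        assert row["sigma"] == pytest.approx(0.1)    # population SD convention

    def test_constant_lineage_zero_sigma_and_floor(self):
        df = pd.DataFrame({"lineage_id": [0, 0, 0, 1],
                           "growth_rate": [0.5, 0.5, 0.5, 0.9]})
        stats, dropped = lineage_statistics(df, min_events=2)
        assert dropped == 1
        assert stats.loc[0, "sigma"] == 0.0

    def test_synthetic_lineages_match_generator_moments(self):
        q = GrowthRateModel(beta=60.0, lambda_max=1.0, D=10)
        df = generate_lineage_data(q, n_lineages=40, events_per_lineage=200,
                                   lineage_sd=0.0, seed=5)
        stats, _ = lineage_statistics(df)
        assert stats["lambda_mean"].mean() == pytest.approx(q.mean, rel=0.02)
        assert stats["sigma"].mean() == pytest.approx(q.sd, rel=0.1)


class TestScalingRegression:
    def test_collinear_points_give_r2_one(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        stats = pd.DataFrame({"lambda_mean": 1.0 - x, "lambda_max": 1.0,
                              "sigma": 2.0 * x})
        reg = scaling_regression(stats)
        assert reg.r_squared == pytest.approx(1.0)
        assert reg.slope == pytest.approx(2.0)

    def test_degenerate_regressor_rejected(self):
        stats = pd.DataFrame({"lambda_mean": [0.5] * 4, "lambda_max": [1.0] * 4,
                              "sigma": [0.1, 0.2, 0.3, 0.4]})
        with pytest.raises(FluxentError):
            scaling_regression(stats)

    def test_lineages_from_shared_model_show_positive_scaling(self):
        """Lineages spanning a range of optimization levels: sigma grows
        linearly with (lambda_max - lambda_bar)."""
        rows = []
        rng = np.random.default_rng(6)
        for k, x in enumerate(np.geomspace(30, 300, 30)):
            q = GrowthRateModel(beta=x, lambda_max=1.0, D=10)
            lam = q.rvs(50, rng=rng)
            rows.append(pd.DataFrame({"lineage_id": k, "growth_rate": lam}))
        stats, _ = lineage_statistics(pd.concat(rows))
        reg = scaling_regression(stats)
        assert reg.slope > 0
        assert reg.r_squared > 0.5
        binned = binned_scaling(stats, n_bins=5)
        assert binned["sigma_mean"].is_monotonic_increasing

    def test_determinism_of_generator(self):
        q = GrowthRateModel(beta=50.0, lambda_max=1.0, D=5)
        a = generate_lineage_data(q, 5, 10, lineage_sd=0.1, seed=7)
        b = generate_lineage_data(q, 5, 10, lineage_sd=0.1, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = generate_lineage_data(q, 5, 10, lineage_sd=0.1, seed=8)
        assert not a.equals(c)
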