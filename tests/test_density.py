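"""Shrinkage-normal and product-kernel log-density estimation."""

import math

import numpy as np
import pytest

from gdcoxs.density import (
    GaussianModel,
    fit_shrinkage_gaussian,
    log_density,
    log_density_samples,
    product_kernel_log_density,
    product_kernel_log_density_samples,
    silverman_bandwidths,
)


class TestShrinkageGaussian:
    def test_mean_is_row_mean(self, rng):
        x = rng.standard_normal((4, 30))
        model = fit_shrinkage_gaussian(x)
        np.testing.assert_allclose(model.mean, x.mean(axis=1))

    def test_full_shrinkage_gives_diagonal_covariance(self, rng):
        x = rng.standard_normal((5, 40))
        model = fit_shrinkage_gaussian(x, shrinkage_intensity=1.0)
        var = x.var(axis=1, ddof=1)
        np.testing.assert_allclose(model.covariance, np.diag(var), atol=1e-12)

    def test_zero_shrinkage_recovers_sample_covariance(self, rng):
        # n >> d, forced lambda = 0
        x = rng.standard_normal((3, 500))
        model = fit_shrinkage_gaussian(x, shrinkage_intensity=0.0)
        np.testing.assert_allclose(
            model.covariance, np.cov(x, ddof=1), atol=1e-10
        )

    def test_off_diagonals_shrink_toward_zero_when_truth_is_identity(self, rng):
        # with no real correlation the analytic intensity suppresses the
        # noisy off-diagonal estimates
        x = rng.standard_normal((2, 2000))
        model = fit_shrinkage_gaussian(x)
        assert 0.0 <= model.shrinkage_intensity <= 1.0
        assert abs(model.covariance[0, 1]) <= abs(np.cov(x)[0, 1]) + 1e-12

    def test_high_dimensional_fit_is_invertible(self, rng):
        # fewer samples than genes: shrinkage must keep the model valid
        x = rng.standard_normal((50, 5))
        model = fit_shrinkage_gaussian(x)
        assert np.isfinite(model.log_det)
        prod = model.precision @ model.covariance
        assert np.linalg.norm(prod - np.eye(50), ord=2) < 1e-8

    def test_covariance_symmetric_and_consistent_logdet(self, rng):
        x = rng.standard_normal((8, 12))
        model = fit_shrinkage_gaussian(x)
        np.testing.assert_allclose(model.covariance, model.covariance.T, atol=1e-10)
        sign, logdet = np.linalg.slogdet(model.covariance)
        assert sign > 0
        assert math.isclose(model.log_det, logdet, rel_tol=1e-9, abs_tol=1e-9)

    def test_zero_variance_gene_floored_with_warning(self, caplog, rng):
        x = rng.standard_normal((3, 10))
        x[1] = 0.0  # an all-neutral copy-number row
        with caplog.at_level("WARNING"):
            model = fit_shrinkage_gaussian(x)
        assert any("floored" in r.message for r in caplog.records)
        assert np.isfinite(model.log_det)
        assert model.covariance[1, 1] > 0

    def test_intensity_outside_unit_interval_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_shrinkage_gaussian(rng.standard_normal((3, 8)), shrinkage_intensity=1.5)

    def test_analytic_intensity_matches_brute_force(self, rng):
        # independent oracle: lambda* assembled with explicit loops over
        # gene pairs and samples
        x = rng.standard_normal((5, 12)) @ rng.standard_normal((12, 12)) * 0.3
        d, n = x.shape
        xc = x - x.mean(axis=1, keepdims=True)
        sd = np.sqrt((xc**2).sum(axis=1) / (n - 1))
        z = xc / sd[:, None]
        num = den = 0.0
        for i in range(d):
            for j in range(d):
                if i == j:
                    continue
                w = z[i] * z[j]
                r_ij = w.sum() / (n - 1)
                var_r = n / (n - 1) ** 3 * ((w - w.mean()) ** 2).sum()
                num += var_r
                den += r_ij**2
        expected = min(1.0, max(0.0, num / den))
        model = fit_shrinkage_gaussian(x)
        assert model.shrinkage_intensity == pytest.approx(expected, rel=1e-10)

    def test_large_sample_limit_agrees_with_ledoit_wolf(self, rng):
        # different shrinkage targets, same n >> d limit: both approach
        # the sample covariance
        from sklearn.covariance import LedoitWolf

        x = rng.standard_normal((4, 4000)) * np.array([[1.0], [2.0], [0.5], [1.5]])
        model = fit_shrinkage_gaussian(x)
        lw = LedoitWolf().fit(x.T).covariance_
        assert np.max(np.abs(model.covariance - lw)) < 0.05


class TestLogDensity:
    def test_standard_normal_at_origin(self):
        model = fit_shrinkage_gaussian(np.array([[1.0, -1.0, 0.5, -0.5]]))
        model = GaussianModel(
            mean=np.zeros(1), covariance=np.eye(1), precision=np.eye(1),
            log_det=0.0, d=1, shrinkage_intensity=0.0,
        )
        assert math.isclose(
            log_density(model, np.zeros(1)), -0.5 * math.log(2 * math.pi)
        )

    def test_at_the_mean_quadratic_form_vanishes(self, rng):
        x = rng.standard_normal((4, 20))
        model = fit_shrinkage_gaussian(x)
        expected = -0.5 * (4 * math.log(2 * math.pi) + model.log_det)
        assert math.isclose(log_density(model, model.mean), expected, rel_tol=1e-12)

    def test_bivariate_identity_hand_value(self):
        model = GaussianModel(
            mean=np.zeros(2), covariance=np.eye(2), precision=np.eye(2),
            log_det=0.0, d=2, shrinkage_intensity=0.0,
        )
        assert math.isclose(
            log_density(model, np.array([1.0, 1.0])), -math.log(2 * math.pi) - 1.0
        )

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_shrinkage_gaussian(rng.standard_normal((3, 10)))
        with pytest.raises(ValueError):
            log_density(model, np.zeros(4))

    def test_vectorized_matches_single_sample(self, rng):
        x = rng.standard_normal((6, 15))
        model = fit_shrinkage_gaussian(x)
        batch = log_density_samples(model, x)
        singles = [log_density(model, x[:, j]) for j in range(15)]
        np.testing.assert_allclose(batch, singles, rtol=1e-12)

    def test_density_differences_reduce_to_quadratic_forms(self, rng):
        # the (2 pi) and log-det terms cancel exactly in any log ratio
        x = rng.standard_normal((5, 12))
        model = fit_shrinkage_gaussian(x)

        def quad(v):
            diff = v - model.mean
            return float(diff @ model.precision @ diff)

        for i, j in [(0, 1), (3, 7), (10, 11)]:
            lhs = log_density(model, x[:, i]) - log_density(model, x[:, j])
            rhs = -0.5 * (quad(x[:, i]) - quad(x[:, j]))
            assert math.isclose(lhs, rhs, rel_tol=1e-9, abs_tol=1e-12)

    def test_invariant_under_gene_permutation(self, rng):
        x = rng.standard_normal((7, 25))
        model = fit_shrinkage_gaussian(x)
        perm = rng.permutation(7)
        permuted = GaussianModel(
            mean=model.mean[perm],
            covariance=model.covariance[np.ix_(perm, perm)],
            precision=model.precision[np.ix_(perm, perm)],
            log_det=model.log_det,
            d=model.d,
            shrinkage_intensity=model.shrinkage_intensity,
        )
        v = rng.standard_normal(7)
        assert math.isclose(
            log_density(model, v), log_density(permuted, v[perm]), rel_tol=1e-10
        )


class TestProductKernel:
    def test_single_sample_self_kernel_only(self):
        x = np.array([[0.3], [1.2]])
        h = np.array([0.5, 2.0])
        expected = math.log(
            1.0 / (0.5 * math.sqrt(2 * math.pi)) * 1.0 / (2.0 * math.sqrt(2 * math.pi))
        )
        assert math.isclose(
            product_kernel_log_density(x, 0, h), expected, rel_tol=1e-12
        )

    def test_identical_samples_share_the_density(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0]])
        vals = product_kernel_log_density_samples(x, np.array([1.0, 1.0]))
        assert math.isclose(vals[0], vals[1], rel_tol=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        x = rng.standard_normal((2, 3))
        h = np.array([1.0, 1.0])
        vals = product_kernel_log_density_samples(x, h)
        n = 3
        for i in range(n):
            total = 0.0
            for k in range(n):
                prod = 1.0
                for g in range(2):
                    u = (x[g, i] - x[g, k]) / h[g]
                    prod *= math.exp(-0.5 * u * u) / (h[g] * math.sqrt(2 * math.pi))
                total += prod
            assert math.isclose(vals[i], math.log(total / n), rel_tol=1e-10)

    def test_silverman_default_used_when_bandwidths_omitted(self, rng):
        x = rng.standard_normal((4, 20))
        np.testing.assert_allclose(
            product_kernel_log_density_samples(x),
            product_kernel_log_density_samples(x, silverman_bandwidths(x)),
        )

    def test_nonpositive_bandwidth_rejected(self, rng):
        x = rng.standard_normal((2, 5))
        with pytest.raises(ValueError, match="positive"):
            product_kernel_log_density_samples(x, np.array([1.0, 0.0]))

    def test_constant_gene_gets_floored_bandwidth(self):
        x = np.vstack([np.zeros(6), np.arange(6.0)])
        h = silverman_bandwidths(x)
        assert h[0] > 0
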