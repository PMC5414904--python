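"""Synthetic survey worlds: random fields, latent surfaces, cluster
sampling and displacement."""

import numpy as np
import pytest

from surveygrid import (
    GridSpec,
    RasterLayer,
    displace_clusters,
    gen_covariate_fields,
    gen_latent_surface,
    sample_clusters,
    urban_mask_from_layer,
)
from surveygrid.synthetic import matern_field


class TestCovariateFields:
    def test_seed_reproducibility_bit_identical(self, grid50):
        a = gen_covariate_fields(grid50, 1, 5000.0, seed=7)
        b = gen_covariate_fields(grid50, 1, 5000.0, seed=7)
        np.testing.assert_array_equal(a.layers[0].values, b.layers[0].values)

    def test_standardization(self, stack50):
        for lyr in stack50.layers:
            assert abs(lyr.values.mean()) < 0.1
            assert abs(lyr.values.std() - 1.0) < 0.15

    def test_long_correlation_limit(self, grid50):
        # correlation length far beyond the grid extent -> near-constant field
        stack = gen_covariate_fields(grid50, 1, corr_length=50_000.0 * 100, seed=3)
        v = stack.layers[0].values
        r = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
        assert r > 0.95

    def test_bad_args(self, grid50):
        with pytest.raises(ValueError):
            gen_covariate_fields(grid50, 0, 5000.0, seed=1)
        with pytest.raises(ValueError):
            gen_covariate_fields(grid50, 1, -1.0, seed=1)

    def test_degenerate_1x1_grid(self):
        g = GridSpec(1, 1)
        stack = gen_covariate_fields(g, 2, 1000.0, seed=5)
        assert stack.layers[0].values.shape == (1, 1)

    def test_distance_fields_are_deterministic_given_seed(self, grid50):
        a = gen_covariate_fields(grid50, 1, 5000.0, seed=9, n_distance_fields=2)
        b = gen_covariate_fields(grid50, 1, 5000.0, seed=9, n_distance_fields=2)
        assert a.names == ["cov_01", "dist_01", "dist_02"]
        np.testing.assert_array_equal(a.layers[2].values, b.layers[2].values)


class TestLatentSurface:
    def test_zero_beta_logit_gives_half(self, stack50):
        truth = gen_latent_surface(stack50, [0, 0, 0, 0], 0.0, 10_000.0, link="logit", seed=1)
        np.testing.assert_allclose(truth.latent_surface.values, 0.5)

    def test_identity_constant(self, stack50):
        truth = gen_latent_surface(stack50, [0.3, 0, 0, 0], 0.0, 10_000.0, link="identity", seed=1)
        np.testing.assert_allclose(truth.latent_surface.values, 0.3)

    def test_identity_affine_in_covariates_when_no_spatial_term(self, stack50):
        beta = np.array([0.5, 0.03, -0.02, 0.01])
        truth = gen_latent_surface(stack50, beta, 0.0, 10_000.0, link="identity", seed=1)
        expected = beta[0] + sum(
            b * lyr.values for b, lyr in zip(beta[1:], stack50.layers)
        )
        assert expected.min() >= 0 and expected.max() <= 1  # clamping inactive
        np.testing.assert_allclose(truth.latent_surface.values, expected, atol=1e-14)

    def test_unknown_link_rejected(self, stack50):
        with pytest.raises(ValueError, match="link"):
            gen_latent_surface(stack50, [0, 0, 0, 0], 0.0, 1000.0, link="probit", seed=1)

    def test_matern_field_marginal_variance(self):
        # Monte-Carlo check of the spectral simulator's normalization
        grid = GridSpec(100, 100, origin_y=100_000.0, cell_size=1000.0)
        rng = np.random.default_rng(42)
        v = matern_field(grid, 1.0, 10_000.0, rng)
        assert abs(v.var() - 1.0) < 0.25

    def test_spatial_residual_variance_via_logit(self, grid50):
        stack = gen_covariate_fields(grid50, 1, 5000.0, seed=2)
        truth = gen_latent_surface(stack, [0.0, 0.4], 1.0, 10_000.0, link="logit", seed=11)
        from scipy.special import logit

        resid = logit(truth.latent_surface.values) - 0.4 * stack.layers[0].values
        assert abs(resid.var() - 1.0) < 0.25


class TestSampleClusters:
    def _truth_const(self, grid, p):
        layer = RasterLayer(grid, "true_proportion", np.full(grid.shape, float(p)))
        from surveygrid import SyntheticTruth

        return SyntheticTruth(
            beta_true=np.array([p]),
            spatial_variance=0.0,
            range_param=1000.0,
            nugget=0.0,
            link="identity",
            latent_surface=layer,
        )

    def _mask(self, grid, frac_urban=0.0):
        vals = np.zeros(grid.shape)
        n_urban = int(frac_urban * grid.n_rows * grid.n_cols)
        vals.flat[:n_urban] = 1.0
        return RasterLayer(grid, "urban_mask", vals)

    def test_certain_outcome(self, grid50):
        truth = self._truth_const(grid50, 1.0)
        cl = sample_clusters(truth, 50, self._mask(grid50), 25, seed=1)
        assert all(c.n_positive == c.n_respondents for c in cl)

    def test_pooled_mean_matches_truth(self, grid50):
        truth = self._truth_const(grid50, 0.4)
        cl = sample_clusters(truth, 400, self._mask(grid50), 25, seed=5)
        pooled = np.mean([c.proportion for c in cl])
        assert abs(pooled - 0.4) < 0.025  # ~5 binomial standard errors

    def test_reproducible(self, grid50):
        truth = self._truth_const(grid50, 0.3)
        a = sample_clusters(truth, 30, self._mask(grid50, 0.3), 10, seed=9)
        b = sample_clusters(truth, 30, self._mask(grid50, 0.3), 10, seed=9)
        assert [(c.id, c.true_xy, c.n_positive, c.stratum) for c in a] == [
            (c.id, c.true_xy, c.n_positive, c.stratum) for c in b
        ]

    def test_true_location_inside_grid_and_reported_initialized(self, grid50):
        truth = self._truth_const(grid50, 0.5)
        cl = sample_clusters(truth, 100, self._mask(grid50, 0.5), 10, seed=2)
        xmin, xmax, ymin, ymax = grid50.extent
        for c in cl:
            assert xmin <= c.true_xy[0] <= xmax and ymin <= c.true_xy[1] <= ymax
            assert c.reported_xy == c.true_xy

    def test_grid_mismatch_rejected(self, grid50):
        truth = self._truth_const(grid50, 0.5)
        other = GridSpec(10, 10)
        with pytest.raises(ValueError, match="grid"):
            sample_clusters(truth, 5, self._mask(other), 10, seed=1)


class TestDisplacement:
    @staticmethod
    def _make(n, stratum):
        from conftest import make_cluster

        return [make_cluster(0.0, 0.0, stratum=stratum, cid=f"c{i}") for i in range(n)]

    def test_urban_cap_and_near_cap_coverage(self):
        cl = displace_clusters(self._make(1000, "urban"), seed=4)
        d = np.array([c.displacement_m for c in cl])
        assert d.max() <= 2000.0
        assert d.max() > 1900.0  # P(miss) ~ 0.95^1000

    def test_rural_flagged_far_is_one_percent(self):
        cl = displace_clusters(self._make(1000, "rural"), seed=4)
        flagged = [c for c in cl if c.flagged_far]
        assert len(flagged) == 10
        for c in cl:
            cap = 10_000.0 if c.flagged_far else 5000.0
            assert c.displacement_m <= cap

    def test_empty_and_no_rural(self):
        assert displace_clusters([], seed=1) == []
        cl = displace_clusters(self._make(5, "urban"), seed=1)
        assert not any(c.flagged_far for c in cl)

    def test_mean_displacement_is_half_cap(self):
        # Uniform[0, L] radius -> mean L/2, sd L/sqrt(12)
        n = 4000
        cl = displace_clusters(self._make(n, "urban"), seed=8)
        d = np.array([c.displacement_m for c in cl])
        se = 2000.0 / np.sqrt(12.0) / np.sqrt(n)
        assert abs(d.mean() - 1000.0) < 3 * se

    def test_true_coordinates_preserved(self):
        cl = displace_clusters(self._make(20, "rural"), seed=2)
        assert all(c.true_xy == (0.0, 0.0) for c in cl)
        assert all(c.reported_xy != c.true_xy for c in cl)

    def test_double_displacement_rejected(self):
        cl = displace_clusters(self._make(3, "urban"), seed=1)
        with pytest.raises(ValueError, match="displaced"):
            displace_clusters(cl, seed=2)


def test_urban_mask_top_quartile(grid50, stack50):
    mask = urban_mask_from_layer(stack50.layers[0], quantile=0.75)
    frac = mask.values.mean()
    assert 0.2 < frac < 0.3
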