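"""Buffer extraction, VIF filtering and jackknife covariate selection."""

import numpy as np
import pytest
from conftest import make_cluster, make_design

from surveygrid import (
    CovariateStack,
    RasterLayer,
    buffer_mean,
    buffer_monte_carlo,
    build_design_matrix,
    compute_vif,
    jackknife_select,
    vif_filter,
)


@pytest.fixture
def ramp_stack(ramp_layer):
    const = RasterLayer(ramp_layer.grid, "const", np.full(ramp_layer.grid.shape, 3.2))
    return CovariateStack(ramp_layer.grid, [ramp_layer, const])


class TestBufferMean:
    def test_constant_layer(self, ramp_stack):
        cl = make_cluster(10_000.0, 10_000.0, "urban")
        vec = buffer_mean(ramp_stack, cl)
        assert vec[1] == pytest.approx(3.2)

    def test_ramp_buffer_mean_equals_center_value(self, ramp_stack):
        # disc symmetry: the mean of a linear ramp over a disc is its centre
        cl = make_cluster(10_000.0, 10_000.0, "urban")
        vec = buffer_mean(ramp_stack, cl)
        assert abs(vec[0] - 10.0) < 0.2  # one cell width = 0.2 ramp units

    def test_rural_buffer_uses_larger_disc(self, ramp_stack):
        grid = ramp_stack.grid
        x = y = 10_000.0
        cx, cy = grid.center_mesh()
        d2 = (cx - x) ** 2 + (cy - y) ** 2
        n_urban = int((d2 <= 2000.0**2).sum())
        n_rural = int((d2 <= 5000.0**2).sum())
        ratio = n_rural / n_urban
        assert abs(ratio - 6.25) / 6.25 < 0.1  # disc area ratio (5/2)^2
        # rural mean still matches the centre value over the larger disc
        rural = make_cluster(x, y, "rural")
        assert abs(buffer_mean(ramp_stack, rural)[0] - 10.0) < 0.2

    def test_layer_order_invariance(self, ramp_stack):
        cl = make_cluster(8000.0, 12_000.0, "rural")
        fwd = buffer_mean(ramp_stack, cl)
        rev = buffer_mean(CovariateStack(ramp_stack.grid, ramp_stack.layers[::-1]), cl)
        np.testing.assert_allclose(fwd, rev[::-1])

    def test_point_outside_grid_falls_back_to_nearest_cells(self, ramp_stack):
        cl = make_cluster(-4000.0, 10_000.0, "urban")
        vec = buffer_mean(ramp_stack, cl)
        assert np.isfinite(vec).all()
        assert vec[0] < 2.0  # near the x=0 edge of the ramp

    def test_all_missing_layer_flags_cluster(self, ramp_layer):
        grid = ramp_layer.grid
        empty = RasterLayer(grid, "empty", np.full(grid.shape, np.nan))
        stack = CovariateStack(grid, [empty])
        vec = buffer_mean(stack, make_cluster(10_000.0, 10_000.0))
        assert np.isnan(vec[0])


class TestBufferMonteCarlo:
    def test_constant_layer_all_draws_equal(self, ramp_stack):
        cl = make_cluster(10_000.0, 10_000.0, "urban")
        m = buffer_monte_carlo(ramp_stack, cl, n_draws=50, seed=1)
        assert m.shape == (50, 2)
        np.testing.assert_allclose(m[:, 1], 3.2)

    def test_column_mean_converges_to_buffer_mean(self, ramp_stack):
        cl = make_cluster(10_000.0, 10_000.0, "rural")
        m = buffer_monte_carlo(ramp_stack, cl, n_draws=2000, seed=2)
        target = buffer_mean(ramp_stack, cl)[0]
        se = m[:, 0].std() / np.sqrt(2000)
        assert abs(m[:, 0].mean() - target) < 2.5 * se + 0.01

    def test_seed_reproducibility(self, ramp_stack):
        cl = make_cluster(9000.0, 9000.0, "urban")
        a = buffer_monte_carlo(ramp_stack, cl, 100, seed=5)
        b = buffer_monte_carlo(ramp_stack, cl, 100, seed=5)
        np.testing.assert_array_equal(a, b)


class TestDesignMatrix:
    def test_shape_one_row_per_cluster(self, ramp_stack):
        clusters = [
            make_cluster(5000.0, 5000.0, "urban", cid="a"),
            make_cluster(10_000.0, 10_000.0, "rural", cid="b"),
            make_cluster(15_000.0, 15_000.0, "urban", cid="c"),
        ]
        d = build_design_matrix(ramp_stack, clusters)
        assert d.values.shape == (3, 2)
        assert d.cluster_ids == ["a", "b", "c"]

    def test_replicate_mode_repeats_ids(self, ramp_stack):
        clusters = [
            make_cluster(5000.0, 5000.0, cid="a"),
            make_cluster(10_000.0, 10_000.0, cid="b"),
            make_cluster(15_000.0, 15_000.0, cid="c"),
        ]
        d = build_design_matrix(
            ramp_stack, clusters, method="buffer_mc", n_draws=10, replicate_rows=True
        )
        assert d.values.shape == (30, 2)
        assert d.cluster_ids.count("a") == 10

    def test_columns_standardized(self, ramp_stack):
        rng = np.random.default_rng(4)
        clusters = [
            make_cluster(rng.uniform(2000, 18_000), rng.uniform(2000, 18_000), cid=f"c{i}")
            for i in range(20)
        ]
        d = build_design_matrix(ramp_stack, clusters)
        np.testing.assert_allclose(d.values.mean(axis=0), 0.0, atol=1e-9)
        # the constant column has zero variance and is left centred
        np.testing.assert_allclose(d.values[:, 0].std(), 1.0, atol=1e-9)

    def test_empty_cluster_list_rejected(self, ramp_stack):
        with pytest.raises(ValueError):
            build_design_matrix(ramp_stack, [])

    def test_csv_round_trip(self, ramp_stack, tmp_path):
        clusters = [
            make_cluster(5000.0, 5000.0, cid="a"),
            make_cluster(10_000.0, 10_000.0, cid="b"),
        ]
        d = build_design_matrix(ramp_stack, clusters)
        p = tmp_path / "design.csv"
        d.to_csv(p)
        from surveygrid import DesignMatrix

        back = DesignMatrix.from_csv(p)
        assert back.cluster_ids == d.cluster_ids
        assert back.covariate_names == d.covariate_names
        np.testing.assert_allclose(back.values, d.values, atol=1e-12)

    def test_selection_report_json(self, tmp_path):
        import json

        Q = _orthonormal_centered(40, 3)
        _, report = vif_filter(make_design(Q))
        p = tmp_path / "selection.json"
        report.to_json(p)
        data = json.loads(p.read_text())
        assert data["final_covariates"] == ["v0", "v1", "v2"]


def _orthonormal_centered(n, p, seed=0):
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(n, p))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    return Q


def _vif_oracle(X):
    """Explicit normal-equations VIF for every column."""
    n, p = X.shape
    out = []
    for j in range(p):
        yj = X[:, j]
        A = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        b = np.linalg.inv(A.T @ A) @ (A.T @ yj)
        r2 = 1 - ((yj - A @ b) ** 2).sum() / ((yj - yj.mean()) ** 2).sum()
        out.append(1.0 / (1.0 - r2))
    return np.array(out)


class TestVIF:
    def test_orthogonal_columns_vif_one(self):
        Q = _orthonormal_centered(40, 4)
        vifs = compute_vif(make_design(Q))
        np.testing.assert_allclose(list(vifs.values()), 1.0, atol=1e-10)

    def test_two_correlated_columns_closed_form(self):
        Q = _orthonormal_centered(60, 2)
        X = np.column_stack([Q[:, 0], 0.8 * Q[:, 0] + 0.6 * Q[:, 1]])
        vifs = compute_vif(make_design(X))
        # r = 0.8 exactly -> VIF = 1/(1-0.64) = 2.7778 for both columns
        assert vifs["v0"] == pytest.approx(1 / 0.36, rel=1e-9)
        assert vifs["v1"] == pytest.approx(1 / 0.36, rel=1e-9)

    def test_duplicated_column_is_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        vifs = compute_vif(make_design(np.column_stack([x, x])))
        assert vifs["v0"] == np.inf

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(120, 5))
        base[:, 3] = 0.6 * base[:, 0] + 0.8 * rng.normal(size=120)
        vifs = np.array(list(compute_vif(make_design(base)).values()))
        np.testing.assert_allclose(vifs, _vif_oracle(base), atol=1e-8)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(9)
        X = rng.normal(size=(150, 4))
        X[:, 1] += 0.9 * X[:, 0]
        A = np.column_stack([np.ones(150), X])
        sm_vifs = [variance_inflation_factor(A, j + 1) for j in range(4)]
        ours = list(compute_vif(make_design(X)).values())
        np.testing.assert_allclose(ours, sm_vifs, rtol=1e-8)


class TestVifFilter:
    def test_identity_when_all_below_threshold(self):
        Q = _orthonormal_centered(40, 3)
        filtered, report = vif_filter(make_design(Q), threshold=3.0)
        assert report.removed_by_vif == []
        assert filtered.covariate_names == ["v0", "v1", "v2"]

    def test_duplicate_column_removes_exactly_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        filtered, report = vif_filter(make_design(np.column_stack([x, x, z])))
        assert len(report.removed_by_vif) == 1
        assert report.removed_by_vif[0] in ("v0", "v1")
        assert max(report.vif_table.values()) < 3.0

    def test_matches_brute_force_minimal_removal(self):
        # x2 ~ x0 + x1: dropping any single column makes all VIF < 3
        Q = _orthonormal_centered(80, 3, seed=5)
        X = np.column_stack([Q[:, 0], Q[:, 1], Q[:, 0] + Q[:, 1] + 0.05 * Q[:, 2]])
        design = make_design(X)
        filtered, report = vif_filter(design, threshold=3.0)
        # brute force: smallest removal set over all column subsets
        from itertools import combinations

        best = None
        names = design.covariate_names
        for k in range(len(names) + 1):
            for rm in combinations(names, k):
                keep = [n for n in names if n not in rm]
                if not keep:
                    continue
                if len(keep) == 1:
                    ok = True
                else:
                    ok = max(compute_vif(design.subset(keep)).values()) < 3.0
                if ok:
                    best = rm
                    break
            if best is not None:
                break
        assert len(report.removed_by_vif) == len(best)
        assert max(report.vif_table.values()) < 3.0

    def test_final_max_vif_below_threshold_property(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            X = rng.normal(size=(100, 6))
            X[:, 4] = X[:, 0] + 0.3 * rng.normal(size=100)
            X[:, 5] = X[:, 1] - X[:, 2] + 0.2 * rng.normal(size=100)
            filtered, report = vif_filter(make_design(X), threshold=3.0)
            if len(filtered.covariate_names) > 1:
                assert max(compute_vif(filtered).values()) < 3.0


class TestJackknife:
    def _simulated(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        x_info = rng.normal(size=n)
        x_noise = rng.normal(size=n)
        y = 0.4 + 0.2 * x_info + 0.05 * rng.normal(size=n)
        return make_design(np.column_stack([x_info, x_noise]), names=["info", "noise"]), y

    def test_pure_noise_covariate_removed(self):
        removed = 0
        for seed in range(10):
            design, y = self._simulated(seed=seed)
            report = jackknife_select(design, y, n_repeats=10, seed=seed)
            if report.final_covariates == ["info"]:
                removed += 1
        assert removed >= 9

    def test_informative_covariates_kept(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 3))
        y = 0.5 + 0.3 * X[:, 0] + 0.3 * X[:, 1] + 0.3 * X[:, 2] + 0.05 * rng.normal(size=300)
        report = jackknife_select(make_design(X), y, n_repeats=10, seed=1)
        assert report.removed_by_jackknife == []
        assert len(report.final_covariates) == 3

    def test_single_covariate_unchanged(self):
        design = make_design(np.random.default_rng(0).normal(size=(50, 1)))
        y = np.linspace(0, 1, 50)
        report = jackknife_select(design, y, seed=0)
        assert report.final_covariates == ["v0"]

    def test_final_score_never_below_baseline(self):
        for seed in (1, 2, 3):
            design, y = self._simulated(seed=seed)
            report = jackknife_select(design, y, n_repeats=8, seed=seed)
            assert report.final_score >= report.baseline_score - 0.005
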