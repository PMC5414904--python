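"""Synthetic DHS-like survey worlds with known ground truth.

Everything downstream of real survey microdata is testable against these
generators: spatially autocorrelated covariate fields, a latent indicator
surface driven by a linear predictor plus a Matern spatial residual,
binomial cluster sampling, and the confidentiality displacement applied to
cluster coordinates (up to 2 km for urban clusters, 5 km for rural ones,
with 1% of rural clusters displaced up to 10 km).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.special import expit

from .core import (
    FAR_RURAL_DISPLACEMENT_M,
    RURAL_DISPLACEMENT_M,
    URBAN_DISPLACEMENT_M,
    ClusterRecord,
    CovariateStack,
    GridSpec,
    RasterLayer,
    SyntheticTruth,
)

__all__ = [
    "gen_covariate_fields",
    "matern_field",
    "gen_latent_surface",
    "sample_clusters",
    "displace_clusters",
    "urban_mask_from_layer",
    "write_truth_json",
    "read_truth_json",
]


def gen_covariate_fields(
    grid: GridSpec,
    n_fields: int,
    corr_length: float,
    seed: int,
    n_distance_fields: int = 0,
    points_per_distance_field: int = 5,
) -> CovariateStack:
    """Standardized stationary Gaussian random fields on ``grid``.

    Each stochastic field is white noise smoothed with an isotropic Gaussian
    kernel whose width is set so the autocorrelation is approximately
    ``exp(-(d / corr_length)**2)``, then standardized to sample mean 0 and
    standard deviation 1.  Optional "distance-to-random-points" layers mimic
    accessibility / distance-to-feature covariates (distance to the nearest
    of a few random cells, standardized).
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if corr_length <= 0:
        raise ValueError("corr_length must be positive")
    rng = np.random.default_rng(seed)
    sigma_px = corr_length / (2.0 * grid.cell_size)
    # beyond ~half the grid extent the smoothing filter cannot resolve the
    # field's low-frequency content; switch to exact simulation on anchor
    # points with smooth kriging interpolation
    use_exact = sigma_px > min(grid.n_rows, grid.n_cols) / 2.0
    layers = []
    for i in range(n_fields):
        if use_exact:
            f = _smooth_field_exact(grid, corr_length, rng)
        else:
            noise = rng.standard_normal(grid.shape)
            f = gaussian_filter(noise, sigma=sigma_px, mode="reflect")
        f = _standardize(f)
        layers.append(RasterLayer(grid, f"cov_{i + 1:02d}", f))
    for i in range(n_distance_fields):
        seeds = np.zeros(grid.shape, dtype=bool)
        k = min(points_per_distance_field, grid.n_rows * grid.n_cols)
        flat = rng.choice(grid.n_rows * grid.n_cols, size=k, replace=False)
        seeds.flat[flat] = True
        dist = distance_transform_edt(~seeds, sampling=grid.cell_size)
        layers.append(RasterLayer(grid, f"dist_{i + 1:02d}", _standardize(dist)))
    return CovariateStack(grid, layers)


def _smooth_field_exact(grid: GridSpec, corr_length: float, rng, n_anchor: int = 6) -> np.ndarray:
    """Gaussian-correlation field for lengths comparable to the grid extent.

    Simulates the field exactly (Cholesky) on a small anchor lattice and
    interpolates to all cell centres with the Gaussian-kernel conditional
    mean, which preserves the smooth low-frequency structure the moving-
    average filter loses at such lengths.
    """
    xmin, xmax, ymin, ymax = grid.extent
    ax = np.linspace(xmin, xmax, n_anchor)
    ay = np.linspace(ymin, ymax, n_anchor)
    AX, AY = np.meshgrid(ax, ay)
    anchors = np.column_stack([AX.ravel(), AY.ravel()])
    d2 = ((anchors[:, None, :] - anchors[None, :, :]) ** 2).sum(-1)
    C = np.exp(-d2 / corr_length**2) + 1e-8 * np.eye(len(anchors))
    z = np.linalg.cholesky(C) @ rng.standard_normal(len(anchors))
    X, Y = grid.center_mesh()
    cells = np.column_stack([X.ravel(), Y.ravel()])
    k = np.exp(
        -((cells[:, None, 0] - anchors[None, :, 0]) ** 2 + (cells[:, None, 1] - anchors[None, :, 1]) ** 2)
        / corr_length**2
    )
    return (k @ np.linalg.solve(C, z)).reshape(grid.shape)


def _standardize(f: np.ndarray) -> np.ndarray:
    sd = f.std()
    if sd == 0:  # degenerate (e.g. 1x1 grid): centre only
        return f - f.mean()
    return (f - f.mean()) / sd


def matern_field(
    grid: GridSpec, variance: float, range_m: float, rng: np.random.Generator
) -> np.ndarray:
    """One realization of a Matern nu=1 Gaussian field on the grid.

    Spectral simulation: white noise is filtered in the Fourier domain with
    the square root of the Matern nu=1 spectral density in two dimensions,
    S(w) ~ (kappa^2 + |w|^2)^-2 with kappa = sqrt(8)/range (the "practical
    range" convention where correlation drops to ~0.14 at ``range_m``).
    The grid is embedded in a doubled periodic domain to suppress wrap-around
    correlation, and the filter is normalized analytically so the marginal
    variance equals ``variance`` in expectation.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if range_m <= 0:
        raise ValueError("range_m must be positive")
    if variance == 0:
        return np.zeros(grid.shape)
    kappa = np.sqrt(8.0) / range_m
    ny, nx = 2 * grid.n_rows, 2 * grid.n_cols
    wy = 2 * np.pi * np.fft.fftfreq(ny, d=grid.cell_size)
    wx = 2 * np.pi * np.fft.fftfreq(nx, d=grid.cell_size)
    w2 = wy[:, None] ** 2 + wx[None, :] ** 2
    amp = (kappa**2 + w2) ** -1.0  # sqrt of (kappa^2+|w|^2)^-2
    noise = rng.standard_normal((ny, nx))
    z = np.fft.ifft2(amp * np.fft.fft2(noise)).real
    # Var(z) = mean(amp^2)/1 per pixel (orthogonality of Fourier modes)
    var_now = (amp**2).mean()
    z *= np.sqrt(variance / var_now)
    return z[: grid.n_rows, : grid.n_cols]


def gen_latent_surface(
    stack: CovariateStack,
    beta: np.ndarray,
    spatial_variance: float,
    range_param: float,
    link: str = "logit",
    seed: int = 0,
    nugget: float = 0.0,
) -> SyntheticTruth:
    """Latent proportion surface p(s) = link^-1(X(s)'beta + v(s)).

    ``beta`` holds the intercept first, then one coefficient per stack
    layer.  ``v`` is a Matern nu=1 field with the given marginal variance
    and practical range.  The identity link clamps to [0, 1]; the logit link
    needs no clamping.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.size != len(stack) + 1:
        raise ValueError(
            f"beta has {beta.size} entries; expected {len(stack) + 1} "
            "(intercept + one per layer)"
        )
    if link not in ("logit", "identity"):
        raise ValueError(f"unknown link {link!r}")
    if spatial_variance < 0:
        raise ValueError("spatial_variance must be non-negative")
    rng = np.random.default_rng(seed)
    lp = np.full(stack.grid.shape, beta[0])
    for coef, lyr in zip(beta[1:], stack.layers):
        lp = lp + coef * lyr.values
    v = matern_field(stack.grid, spatial_variance, range_param, rng)
    eta = lp + v
    if link == "logit":
        p = expit(eta)
    else:
        p = np.clip(eta, 0.0, 1.0)
    surface = RasterLayer(stack.grid, "true_proportion", p)
    return SyntheticTruth(
        beta_true=beta,
        spatial_variance=spatial_variance,
        range_param=range_param,
        nugget=nugget,
        link=link,
        latent_surface=surface,
        covariate_names=stack.names,
        seed=seed,
    )


def urban_mask_from_layer(layer: RasterLayer, quantile: float = 0.75) -> RasterLayer:
    """0/1 urban mask: cells in the top quantile of an urbanization proxy."""
    vals = layer.values
    finite = vals[np.isfinite(vals)]
    thr = np.quantile(finite, quantile)
    mask = np.where(np.isfinite(vals), (vals >= thr).astype(float), np.nan)
    return RasterLayer(layer.grid, "urban_mask", mask)


def sample_clusters(
    truth: SyntheticTruth,
    n_clusters: int,
    urban_mask: RasterLayer,
    respondents_per_cluster: int,
    seed: int,
    indicator: str = "indicator",
) -> list[ClusterRecord]:
    """Draw survey clusters uniformly over the non-missing cells.

    Each cluster gets a uniform true location inside its cell, the stratum
    of that cell from ``urban_mask``, and a Binomial(m, p) positive count at
    the cell's true proportion.  Reported coordinates start equal to the
    true ones; displacement is a separate step.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if respondents_per_cluster < 1:
        raise ValueError("respondents_per_cluster must be >= 1")
    grid = truth.latent_surface.grid
    if not urban_mask.grid.same_geometry(grid):
        raise ValueError("urban_mask grid does not match the truth surface grid")
    rng = np.random.default_rng(seed)
    p = truth.latent_surface.values
    valid = np.flatnonzero(np.isfinite(p.ravel()))
    if valid.size == 0:
        raise ValueError("truth surface has no non-missing cells")
    picks = rng.choice(valid, size=n_clusters, replace=True)
    rows, cols = np.unravel_index(picks, grid.shape)
    u = rng.uniform(size=(n_clusters, 2))
    xs = grid.origin_x + (cols + u[:, 0]) * grid.cell_size
    ys = grid.origin_y - (rows + u[:, 1]) * grid.cell_size
    counts = rng.binomial(respondents_per_cluster, p[rows, cols])
    urban = urban_mask.values[rows, cols] > 0.5
    records = []
    for i in range(n_clusters):
        xy = (float(xs[i]), float(ys[i]))
        records.append(
            ClusterRecord(
                id=f"c{i + 1:05d}",
                true_xy=xy,
                reported_xy=xy,
                stratum="urban" if urban[i] else "rural",
                n_respondents=respondents_per_cluster,
                n_positive=int(counts[i]),
                indicator=indicator,
            )
        )
    return records


def displace_clusters(clusters: list[ClusterRecord], seed: int) -> list[ClusterRecord]:
    """Apply DHS-style random displacement to reported coordinates.

    Each cluster is moved by a uniform angle and a Uniform[0, L] radius with
    L = 2 km (urban) or 5 km (rural); a simple random 1% of rural clusters
    (count rounded to the nearest integer) is flagged and allowed L = 10 km.
    True coordinates are preserved for evaluation.
    """
    if not clusters:
        return []
    for cl in clusters:
        if cl.reported_xy != cl.true_xy:
            raise ValueError(f"cluster {cl.id} already displaced")
    rng = np.random.default_rng(seed)
    rural_idx = [i for i, cl in enumerate(clusters) if cl.stratum == "rural"]
    n_far = int(np.floor(0.01 * len(rural_idx) + 0.5))
    far = set(rng.choice(rural_idx, size=n_far, replace=False).tolist()) if n_far else set()
    out = []
    for i, cl in enumerate(clusters):
        flagged = i in far
        if cl.stratum == "urban":
            cap = URBAN_DISPLACEMENT_M
        elif flagged:
            cap = FAR_RURAL_DISPLACEMENT_M
        else:
            cap = RURAL_DISPLACEMENT_M
        theta = rng.uniform(0.0, 2 * np.pi)
        r = rng.uniform(0.0, cap)
        xy = (cl.true_xy[0] + r * np.cos(theta), cl.true_xy[1] + r * np.sin(theta))
        out.append(cl.with_reported(xy, flagged_far=flagged))
    return out


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
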