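"""Displacement-aware covariate extraction and covariate selection.

Because reported cluster coordinates are randomly displaced, covariate
values are not read at the point itself but averaged over a buffer whose
radius matches the displacement cap of the stratum: 2 km around urban
clusters and 5 km around rural ones.  Linear models use the buffer mean;
nonlinear models can instead use Monte-Carlo draws inside the same buffer.

Covariate selection is two-stage: an iterative variance-inflation-factor
(VIF) filter removes multicollinear columns until every VIF is below a
threshold (default 3), then a jackknife sensitivity analysis greedily drops
covariates whose removal improves held-out explained variance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ClusterRecord, CovariateStack

__all__ = [
    "DesignMatrix",
    "SelectionReport",
    "buffer_mean",
    "buffer_monte_carlo",
    "build_design_matrix",
    "compute_vif",
    "vif_filter",
    "jackknife_select",
]

logger = logging.getLogger(__name__)

BUFFER_RADII_M = {"urban": 2000.0, "rural": 5000.0}


@dataclass
class DesignMatrix:
    """Cluster-by-covariate matrix from buffer extraction.

    Columns are z-scored; the original means and standard deviations are
    kept so fitted coefficients can be applied to raw grid values later.
    """

    cluster_ids: list[str]
    covariate_names: list[str]
    values: np.ndarray
    extraction_method: str = "buffer_mean"
    buffer_radii: dict = field(default_factory=lambda: dict(BUFFER_RADII_M))
    mc_draws: int | None = None
    col_means: np.ndarray | None = None
    col_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cluster_ids), len(self.covariate_names)):
            raise ValueError("design matrix shape does not match ids/names")
        if not np.isfinite(self.values).all():
            raise ValueError("design matrix contains missing values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def standardized(self) -> bool:
        return self.col_means is not None

    def standardize_new(self, raw: np.ndarray) -> np.ndarray:
        """Apply the stored z-scoring to raw covariate values."""
        raw = np.asarray(raw, dtype=float)
        if raw.shape[-1] != len(self.covariate_names):
            raise ValueError("column count mismatch")
        if not self.standardized:
            return raw
        return (raw - self.col_means) / self.col_sds

    def subset(self, names: list[str]) -> "DesignMatrix":
        idx = [self.covariate_names.index(n) for n in names]
        return DesignMatrix(
            cluster_ids=list(self.cluster_ids),
            covariate_names=list(names),
            values=self.values[:, idx],
            extraction_method=self.extraction_method,
            buffer_radii=dict(self.buffer_radii),
            mc_draws=self.mc_draws,
            col_means=None if self.col_means is None else self.col_means[idx],
            col_sds=None if self.col_sds is None else self.col_sds[idx],
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.covariate_names)
        df.insert(0, "cluster_id", self.cluster_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "DesignMatrix":
        df = pd.read_csv(path)
        ids = df.iloc[:, 0].astype(str).tolist()
        names = list(df.columns[1:])
        return cls(cluster_ids=ids, covariate_names=names, values=df.iloc[:, 1:].to_numpy(), **kwargs)


@dataclass
class SelectionReport:
    """Outcome of VIF filtering and/or jackknife covariate selection."""

    vif_table: dict[str, float] = field(default_factory=dict)
    removed_by_vif: list[str] = field(default_factory=list)
    jackknife_scores: dict[str, float] = field(default_factory=dict)
    removed_by_jackknife: list[str] = field(default_factory=list)
    final_covariates: list[str] = field(default_factory=list)
    baseline_score: float | None = None
    final_score: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "vif_table": self.vif_table,
            "removed_by_vif": self.removed_by_vif,
            "jackknife_scores": self.jackknife_scores,
            "removed_by_jackknife": self.removed_by_jackknife,
            "final_covariates": self.final_covariates,
            "baseline_score": self.baseline_score,
            "final_score": self.final_score,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Buffer extraction


def _buffer_radius(cluster: ClusterRecord, radii: dict | None = None) -> float:
    radii = radii or BUFFER_RADII_M
    return radii[cluster.stratum]


def _window(grid, x, y, radius):
    """Row/col slice of cells whose centres could fall within radius."""
    r0, c0 = grid.cell_of(x, y)
    pad = int(np.ceil(radius / grid.cell_size)) + 1
    r_lo, r_hi = max(0, r0 - pad), min(grid.n_rows, r0 + pad + 1)
    c_lo, c_hi = max(0, c0 - pad), min(grid.n_cols, c0 + pad + 1)
    return slice(r_lo, r_hi), slice(c_lo, c_hi)


def buffer_mean(
    stack: CovariateStack, cluster: ClusterRecord, radii: dict | None = None
) -> np.ndarray:
    """Mean of each layer over cells whose centres lie within the stratum
    buffer of the reported location.

    Falls back to the nearest non-missing cell when the buffer captures no
    cell centre (e.g. a point just off the grid edge); returns NaN for a
    layer with no usable cells at all, which flags the cluster for removal.
    """
    grid = stack.grid
    x, y = cluster.reported_xy
    radius = _buffer_radius(cluster, radii)
    # clamp points outside the grid onto its edge (nearest-cell fallback)
    xmin, xmax, ymin, ymax = grid.extent
    xq = min(max(x, xmin), xmax)
    yq = min(max(y, ymin), ymax)
    rs, cs = _window(grid, xq, yq, radius)
    sub_rows = np.arange(rs.start, rs.stop)
    sub_cols = np.arange(cs.start, cs.stop)
    cx = grid.origin_x + (sub_cols + 0.5) * grid.cell_size
    cy = grid.origin_y - (sub_rows + 0.5) * grid.cell_size
    d2 = (cy[:, None] - y) ** 2 + (cx[None, :] - x) ** 2
    in_buf = d2 <= radius**2
    out = np.empty(len(stack))
    for j, lyr in enumerate(stack.layers):
        sub = lyr.values[rs, cs]
        vals = sub[in_buf & np.isfinite(sub)]
        if vals.size:
            out[j] = vals.mean()
        else:
            out[j] = _nearest_valid(lyr, x, y)
    return out


def _nearest_valid(layer, x, y) -> float:
    ok = layer.mask
    if not ok.any():
        return np.nan
    rows, cols = np.nonzero(ok)
    cx, cy = layer.grid.cell_center(rows, cols)
    d2 = (cx - x) ** 2 + (cy - y) ** 2
    return float(layer.values[rows[np.argmin(d2)], cols[np.argmin(d2)]])


def buffer_monte_carlo(
    stack: CovariateStack,
    cluster: ClusterRecord,
    n_draws: int,
    seed: int,
    radii: dict | None = None,
) -> np.ndarray:
    """Covariates at uniform random points in the stratum buffer disc.

    Returns an ``(n_draws, n_layers)`` matrix of nearest-cell lookups, the
    sampling counterpart of :func:`buffer_mean` for nonlinear models.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    grid = stack.grid
    rng = np.random.default_rng(seed)
    x, y = cluster.reported_xy
    radius = _buffer_radius(cluster, radii)
    r = radius * np.sqrt(rng.uniform(size=n_draws))
    theta = rng.uniform(0.0, 2 * np.pi, size=n_draws)
    px = x + r * np.cos(theta)
    py = y + r * np.sin(theta)
    rows, cols = grid.cell_of(px, py)
    rows = np.clip(rows, 0, grid.n_rows - 1)
    cols = np.clip(cols, 0, grid.n_cols - 1)
    out = np.empty((n_draws, len(stack)))
    for j, lyr in enumerate(stack.layers):
        v = lyr.values[rows, cols]
        if not np.isfinite(v).all():  # patch missing lookups with the buffer mean
            fill = buffer_mean(stack.subset([lyr.name]), cluster, radii)[0]
            v = np.where(np.isfinite(v), v, fill)
        out[:, j] = v
    return out


def build_design_matrix(
    stack: CovariateStack,
    clusters: list[ClusterRecord],
    method: str = "buffer_mean",
    n_draws: int = 100,
    replicate_rows: bool = False,
    seed: int = 0,
    standardize: bool = True,
    radii: dict | None = None,
) -> DesignMatrix:
    """Assemble the cluster x covariate design matrix.

    ``buffer_mean`` gives one row per cluster.  ``buffer_mc`` averages the
    Monte-Carlo draws into one row per cluster, or keeps all draws as
    replicate rows (``replicate_rows=True``, for the ANN path where each
    replicate repeats the cluster response).  Clusters with any unusable
    layer are dropped and logged.
    """
    if not clusters:
        raise ValueError("no clusters supplied")
    if method not in ("buffer_mean", "buffer_mc"):
        raise ValueError(f"unknown extraction method {method!r}")
    rows: list[np.ndarray] = []
    ids: list[str] = []
    dropped: list[str] = []
    rng = np.random.default_rng(seed)
    for cl in clusters:
        if method == "buffer_mean":
            vec = buffer_mean(stack, cl, radii)
            block = vec[None, :]
        else:
            block = buffer_monte_carlo(stack, cl, n_draws, int(rng.integers(2**31)), radii)
            if not replicate_rows:
                block = block.mean(axis=0, keepdims=True)
        if not np.isfinite(block).all():
            dropped.append(cl.id)
            continue
        rows.append(block)
        ids.extend([cl.id] * block.shape[0])
    if dropped:
        logger.warning("dropped %d clusters with unusable extraction: %s", len(dropped), dropped)
    if not rows:
        raise ValueError("no usable clusters after extraction")
    values = np.vstack(rows)
    col_means = col_sds = None
    if standardize:
        col_means = values.mean(axis=0)
        col_sds = values.std(axis=0)
        # numerically constant columns are centred but not scaled
        degenerate = col_sds <= 1e-10 * (np.abs(col_means) + 1.0)
        col_sds = np.where(degenerate, 1.0, col_sds)
        values = (values - col_means) / col_sds
    return DesignMatrix(
        cluster_ids=ids,
        covariate_names=list(stack.names),
        values=values,
        extraction_method=method,
        buffer_radii=dict(radii or BUFFER_RADII_M),
        mc_draws=n_draws if method == "buffer_mc" else None,
        col_means=col_means,
        col_sds=col_sds,
    )


# ---------------------------------------------------------------------------
# Multicollinearity filtering

_VIF_INF = float("inf")


def compute_vif(design: DesignMatrix) -> dict[str, float]:
    """Variance inflation factor of every column.

    ``VIF_j = 1 / (1 - R2_j)`` where ``R2_j`` is from the least-squares
    regression of column j on all other columns plus an intercept.  Exactly
    collinear columns get an infinite sentinel.
    """
    X = design.values
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more rows than covariates to compute VIF")
    out: dict[str, float] = {}
    for j, name in enumerate(design.covariate_names):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        sst = ((yj - yj.mean()) ** 2).sum()
        if sst == 0:
            out[name] = _VIF_INF
            continue
        r2 = 1.0 - (resid**2).sum() / sst
        out[name] = _VIF_INF if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(
    design: DesignMatrix, threshold: float = 3.0
) -> tuple[DesignMatrix, SelectionReport]:
    """Iteratively drop the highest-VIF covariate until all are below
    ``threshold`` (ties broken by column order); a single covariate always
    passes."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    current = design
    removed: list[str] = []
    while len(current.covariate_names) > 1:
        vifs = compute_vif(current)
        worst = max(vifs, key=lambda k: (vifs[k], -current.covariate_names.index(k)))
        if vifs[worst] < threshold:
            break
        # ties (incl. multiple +inf) resolved by earliest column order
        cands = [n for n in current.covariate_names if vifs[n] == vifs[worst]]
        worst = cands[0]
        removed.append(worst)
        current = current.subset([n for n in current.covariate_names if n != worst])
    final_vifs = (
        compute_vif(current)
        if len(current.covariate_names) > 1
        else {current.covariate_names[0]: 1.0}
    )
    report = SelectionReport(
        vif_table=final_vifs,
        removed_by_vif=removed,
        final_covariates=list(current.covariate_names),
    )
    return current, report


# ---------------------------------------------------------------------------
# Jackknife covariate sensitivity


def _linear_exp_var(X: np.ndarray, y: np.ndarray, splits) -> float:
    """Mean held-out explained variance of an OLS fit over fixed splits."""
    scores = []
    for train, test in splits:
        A = np.column_stack([np.ones(len(train)), X[train]])
        coef, *_ = np.linalg.lstsq(A, y[train], rcond=None)
        pred = np.column_stack([np.ones(len(test)), X[test]]) @ coef
        mse = ((y[test] - pred) ** 2).mean()
        var = y[test].var()
        scores.append(1.0 - mse / var if var > 0 else 0.0)
    return float(np.mean(scores))


def jackknife_select(
    design: DesignMatrix,
    responses: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
    tolerance: float = 0.005,
    score_fn=None,
) -> SelectionReport:
    """Greedy backward covariate elimination by held-out explained variance.

    The baseline score is the mean validation pseudo-R2 over ``n_repeats``
    random 70/30 splits; each covariate is then left out in turn on the same
    splits.  The best-scoring deletion is accepted whenever its score stays
    within ``tolerance`` of the full-set baseline — uninformative covariates
    cost nothing to delete and are pruned, while deleting an informative one
    drops the score past the tolerance and stops the search.  The returned
    set therefore never scores below the baseline minus the tolerance.
    ``score_fn(X, y, splits)`` defaults to an ordinary least-squares scorer.
    """
    y = np.asarray(responses, dtype=float)
    if y.size != design.n_rows:
        raise ValueError("responses length does not match design rows")
    names = list(design.covariate_names)
    if len(names) < 2:
        return SelectionReport(final_covariates=names, jackknife_scores={})
    score_fn = score_fn or _linear_exp_var
    rng = np.random.default_rng(seed)
    n = design.n_rows
    n_train = int(round(0.7 * n))
    splits = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        splits.append((perm[:n_train], perm[n_train:]))

    current = names
    removed: list[str] = []
    scores_log: dict[str, float] = {}
    idx_of = {n_: i for i, n_ in enumerate(design.covariate_names)}
    baseline = score_fn(design.values[:, [idx_of[n_] for n_ in current]], y, splits)
    first_baseline = baseline
    while len(current) > 1:
        best_name, best_score = None, -np.inf
        for name in current:
            keep = [idx_of[n_] for n_ in current if n_ != name]
            s = score_fn(design.values[:, keep], y, splits)
            scores_log[name] = s
            if s > best_score:
                best_name, best_score = name, s
        if best_score < first_baseline - tolerance:
            break
        removed.append(best_name)
        current = [n_ for n_ in current if n_ != best_name]
        baseline = best_score
    return SelectionReport(
        jackknife_scores=scores_log,
        removed_by_jackknife=removed,
        final_covariates=current,
        baseline_score=first_baseline,
        final_score=baseline,
    )
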