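"""Shared domain types for the survey-interpolation pipeline.

All coordinates are planar metres.  Grids are row-major with row 0 at the
top: pixel (r, c) covers the half-open square
``[origin_x + c*cell, origin_x + (c+1)*cell) x (origin_y - (r+1)*cell,
origin_y - r*cell]`` and is sampled at its centre.  Missing raster values
are NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "RasterLayer",
    "CovariateStack",
    "ClusterRecord",
    "SyntheticTruth",
    "URBAN_DISPLACEMENT_M",
    "RURAL_DISPLACEMENT_M",
    "FAR_RURAL_DISPLACEMENT_M",
]

# DHS confidentiality displacement caps (metres).
URBAN_DISPLACEMENT_M = 2000.0
RURAL_DISPLACEMENT_M = 5000.0
FAR_RURAL_DISPLACEMENT_M = 10000.0


@dataclass(frozen=True)
class GridSpec:
    """A regular planar grid, anchored at its top-left corner."""

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1000.0
    crs_tag: str = "local-metric"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the full grid."""
        return (
            self.origin_x,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_y,
        )

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray] | tuple[float, float]:
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        if np.isscalar(row) or (np.ndim(row) == 0 and np.ndim(col) == 0):
            return float(x), float(y)
        return x, y

    def cell_of(self, x, y):
        """Row/col of the pixel containing point (x, y); no bounds check."""
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y, float)) / self.cell_size).astype(int)
        # points exactly on the bottom/right edge fall in the last pixel
        row = np.where(row == self.n_rows, self.n_rows - 1, row)
        col = np.where(col == self.n_cols, self.n_cols - 1, col)
        if np.ndim(x) == 0 and np.ndim(y) == 0:
            return int(row), int(col)
        return row, col

    def contains(self, x, y):
        xmin, xmax, ymin, ymax = self.extent
        return (np.asarray(x) >= xmin) & (np.asarray(x) <= xmax) & (
            np.asarray(y) >= ymin
        ) & (np.asarray(y) <= ymax)

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of all cell-centre coordinates, shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.origin_x, other.origin_x, abs_tol=1e-6)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=1e-6)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12)
        )


@dataclass
class RasterLayer:
    """One named single-band raster; NaN marks missing cells."""

    grid: GridSpec
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("layer name must be non-empty")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"does not match grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array of valid (non-missing) cells."""
        return np.isfinite(self.values)

    def copy(self, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.grid, name or self.name, self.values.copy())


@dataclass
class CovariateStack:
    """Ordered collection of raster layers sharing a single grid."""

    grid: GridSpec
    layers: list[RasterLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [lyr.name for lyr in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for lyr in self.layers:
            if not lyr.grid.same_geometry(self.grid):
                raise ValueError(f"layer {lyr.name!r} is not on the stack grid")

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> RasterLayer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "CovariateStack":
        return CovariateStack(self.grid, [self[n] for n in names])

    def as_array(self) -> np.ndarray:
        """Stacked values, shape (n_layers, n_rows, n_cols)."""
        return np.stack([lyr.values for lyr in self.layers])

    def valid_mask(self) -> np.ndarray:
        """Cells where every layer is non-missing."""
        m = np.ones(self.grid.shape, dtype=bool)
        for lyr in self.layers:
            m &= lyr.mask
        return m


@dataclass
class ClusterRecord:
    """One survey cluster: a geolocated binomial observation.

    ``true_xy`` is the undisclosed sampling location; ``reported_xy`` is the
    location after confidentiality displacement (equal to ``true_xy`` until
    displacement is applied).  ``flagged_far`` marks membership of the 1%
    rural subset allowed the larger 10 km displacement.
    """

    id: str
    true_xy: tuple[float, float]
    reported_xy: tuple[float, float]
    stratum: str
    n_respondents: int
    n_positive: int
    indicator: str = "indicator"
    flagged_far: bool = False

    def __post_init__(self) -> None:
        if self.stratum not in ("urban", "rural"):
            raise ValueError(f"cluster {self.id}: stratum must be 'urban' or 'rural'")
        if self.n_respondents <= 0:
            raise ValueError(f"cluster {self.id}: n_respondents must be positive")
        if not 0 <= self.n_positive <= self.n_respondents:
            raise ValueError(
                f"cluster {self.id}: n_positive={self.n_positive} outside "
                f"[0, {self.n_respondents}]"
            )
        if self.flagged_far and self.stratum != "rural":
            raise ValueError(f"cluster {self.id}: only rural clusters may be flagged_far")

    @property
    def proportion(self) -> float:
        return self.n_positive / self.n_respondents

    @property
    def displacement_cap_m(self) -> float:
        if self.stratum == "urban":
            return URBAN_DISPLACEMENT_M
        return FAR_RURAL_DISPLACEMENT_M if self.flagged_far else RURAL_DISPLACEMENT_M

    @property
    def displacement_m(self) -> float:
        dx = self.reported_xy[0] - self.true_xy[0]
        dy = self.reported_xy[1] - self.true_xy[1]
        return math.hypot(dx, dy)

    def validate_displacement(self) -> None:
        if self.displacement_m > self.displacement_cap_m + 1e-9:
            raise ValueError(
                f"cluster {self.id}: displacement {self.displacement_m:.1f} m "
                f"exceeds the {self.displacement_cap_m:.0f} m cap"
            )

    def with_reported(self, xy: tuple[float, float], flagged_far: bool | None = None) -> "ClusterRecord":
        return replace(
            self,
            reported_xy=xy,
            flagged_far=self.flagged_far if flagged_far is None else flagged_far,
        )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated indicator surface.

    The latent proportion is ``p(s) = g^{-1}(beta_0 + sum_i beta_i cov_i(s)
    + v(s))`` with ``v`` a Matern nu=1 Gaussian field of marginal variance
    ``spatial_variance`` and the stated practical range, and ``g`` the link.
    """

    beta_true: np.ndarray
    spatial_variance: float
    range_param: float
    nugget: float
    link: str
    latent_surface: RasterLayer
    covariate_names: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.spatial_variance < 0 or self.nugget < 0:
            raise ValueError("variances must be non-negative")
        if self.range_param <= 0:
            raise ValueError("range_param must be positive")
        if self.link not in ("logit", "identity"):
            raise ValueError(f"unknown link {self.link!r}")
        vals = self.latent_surface.values
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("latent surface must hold proportions in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "beta_true": self.beta_true.tolist(),
            "spatial_variance": self.spatial_variance,
            "range_param": self.range_param,
            "nugget": self.nugget,
            "link": self.link,
            "covariate_names": list(self.covariate_names),
            "seed": self.seed,
        }
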