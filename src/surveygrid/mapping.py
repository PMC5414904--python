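"""Gridded prediction surfaces with uncertainty and map-level summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CovariateStack, RasterLayer
from .models import (
    AnnModel,
    LinearModel,
    MeanModel,
    SpatialGPModel,
    ann_predict,
    gp_predict,
)

__all__ = [
    "PredictionSurface",
    "predict_surface",
    "summarize_uncertainty",
    "aggregate_to_units",
    "INTERDECILE_FACTOR",
]

# q90 - q10 of a Gaussian, in standard deviations
INTERDECILE_FACTOR = 2.5631031310892007


@dataclass
class PredictionSurface:
    """Mean prediction raster paired with its uncertainty raster."""

    mean: RasterLayer
    sd: RasterLayer
    model_id: str = "model"
    indicator: str = ""
    uncertainty_kind: str = "sd"  # 'sd' or 'interdecile'

    def __post_init__(self) -> None:
        if not self.mean.grid.same_geometry(self.sd.grid):
            raise ValueError("mean and sd layers must share one grid")
        m = self.mean.values[np.isfinite(self.mean.values)]
        if m.size and (m.min() < -1e-9 or m.max() > 1 + 1e-9):
            raise ValueError("mean surface must hold proportions in [0, 1]")
        s = self.sd.values[np.isfinite(self.sd.values)]
        if s.size and s.min() < -1e-9:
            raise ValueError("uncertainty surface must be non-negative")


def predict_surface(
    model,
    stack: CovariateStack,
    model_id: str = "model",
    indicator: str = "",
    uncertainty: str = "sd",
    chunk_size: int = 4096,
) -> PredictionSurface:
    """Evaluate a fitted model at every non-missing cell centre.

    ``model`` may be a :class:`SpatialGPModel`, a list of
    :class:`AnnModel` (ensemble), a single :class:`AnnModel`, a
    :class:`LinearModel` or a :class:`MeanModel`.  Cells where any required
    covariate is missing are missing in the output.  ``uncertainty`` is
    'sd' or 'interdecile' (2.5631 x sd of the Gaussian predictive law).
    """
    if uncertainty not in ("sd", "interdecile"):
        raise ValueError(f"unknown uncertainty kind {uncertainty!r}")
    names = _required_covariates(model)
    missing = [n for n in names if n not in stack.names]
    if missing:
        raise KeyError(f"stack is missing required layer(s): {missing}")
    sub = stack.subset(names) if names else stack
    grid = stack.grid
    valid = sub.valid_mask() if names else np.ones(grid.shape, bool)
    rows, cols = np.nonzero(valid)
    cx, cy = grid.cell_center(rows, cols)
    coords = np.column_stack([cx, cy])
    X_raw = np.column_stack([sub[n].values[rows, cols] for n in names]) if names else np.empty((len(rows), 0))

    mean_flat = np.empty(len(rows))
    sd_flat = np.empty(len(rows))
    for start in range(0, len(rows), chunk_size):
        sl = slice(start, start + chunk_size)
        m, s = _predict_chunk(model, X_raw[sl], coords[sl])
        mean_flat[sl], sd_flat[sl] = m, s

    mean = np.full(grid.shape, np.nan)
    sd = np.full(grid.shape, np.nan)
    mean[rows, cols] = np.clip(mean_flat, 0.0, 1.0)
    sd[rows, cols] = sd_flat * (INTERDECILE_FACTOR if uncertainty == "interdecile" else 1.0)
    return PredictionSurface(
        mean=RasterLayer(grid, f"{model_id}_mean", mean),
        sd=RasterLayer(grid, f"{model_id}_sd", sd),
        model_id=model_id,
        indicator=indicator,
        uncertainty_kind=uncertainty,
    )


def _required_covariates(model) -> list[str]:
    if isinstance(model, list):
        return list(model[0].covariate_names)
    return list(getattr(model, "covariate_names", []))


def _predict_chunk(model, X_raw, coords):
    if isinstance(model, SpatialGPModel):
        return gp_predict(model, X_raw, coords, standardized=False)
    if isinstance(model, list):
        return ann_predict(model, X_raw, standardized=False)
    if isinstance(model, AnnModel):
        return ann_predict([model], X_raw, standardized=False)
    if isinstance(model, LinearModel):
        return model.predict(X_raw, standardized=False), np.zeros(len(X_raw))
    if isinstance(model, MeanModel):
        return model.predict(X_raw), np.zeros(len(X_raw))
    raise TypeError(f"cannot predict with model of type {type(model).__name__}")


def summarize_uncertainty(surface: PredictionSurface, thresholds) -> pd.DataFrame:
    """Fraction of non-missing pixels with uncertainty strictly below each
    threshold; fractions are non-decreasing in the threshold."""
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    sd = surface.sd.values
    ok = np.isfinite(sd)
    n = int(ok.sum())
    fracs = [float((sd[ok] < t).sum()) / n if n else np.nan for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "fraction_below": fracs})


def aggregate_to_units(
    surface: PredictionSurface,
    zones: RasterLayer,
    weights: RasterLayer | None = None,
) -> pd.DataFrame:
    """Per-zone (optionally weighted) mean of the prediction and
    root-mean-square of the uncertainty; zone label 0 / missing excluded."""
    if not zones.grid.same_geometry(surface.mean.grid):
        raise ValueError("zones must be on the surface grid")
    if weights is not None and not weights.grid.same_geometry(surface.mean.grid):
        raise ValueError("weights must be on the surface grid")
    z = zones.values
    m = surface.mean.values
    s = surface.sd.values
    w = weights.values if weights is not None else np.ones_like(m)
    ok = np.isfinite(z) & (z != 0) & np.isfinite(m) & np.isfinite(s) & np.isfinite(w)
    rows = []
    for label in np.unique(z[ok]):
        sel = ok & (z == label)
        wt = w[sel]
        tw = wt.sum()
        if tw <= 0:
            continue
        rows.append(
            {
                "zone": int(label),
                "n_cells": int(sel.sum()),
                "mean": float((wt * m[sel]).sum() / tw),
                "sd_rms": float(np.sqrt((wt * s[sel] ** 2).sum() / tw)),
            }
        )
    return pd.DataFrame(rows, columns=["zone", "n_cells", "mean", "sd_rms"])
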