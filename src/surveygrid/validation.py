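"""Validation protocol: data splits, metric suite and model comparison.

Metrics follow the mean-squared-error-centric convention for comparing
interpolators of cluster proportions:

* ``exp_var = 1 - MSE / var(obs)`` — the pseudo-R2, with ``var(obs)`` the
  population (divide-by-n) variance of the observed values, so the trivial
  mean model scores exactly 0 on its own training set and its in-sample MSE
  equals ``var(obs)``.
* ``bias = (mean(pred) - mean(obs)) / sd(obs)`` — a sign-preserving summary
  of systematic over/under-prediction in units of the observed spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SplitSpec",
    "split_data",
    "ValidationReport",
    "compute_metrics",
    "explained_variance",
    "aggregate_reports",
    "compare_models",
    "select_best",
]

_SCHEMES = {
    "train_test_70_30": (0.7, 0.0, 0.3),
    "train_valid_test_60_20_20": (0.6, 0.2, 0.2),
}


@dataclass(frozen=True)
class SplitSpec:
    scheme: str = "train_test_70_30"
    n_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown split scheme {self.scheme!r}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def split_data(n: int, spec: SplitSpec) -> list[dict[str, np.ndarray]]:
    """Reproducible random partitions of ``range(n)``, one dict per repeat.

    Each dict has 'train' and 'test' index arrays, plus 'valid' for the
    three-way scheme.  Partitions are disjoint and exhaustive.
    """
    f_train, f_valid, _ = _SCHEMES[spec.scheme]
    n_train = int(round(f_train * n))
    n_valid = int(round(f_valid * n))
    if n_train == 0 or n_train + n_valid >= n:
        raise ValueError(f"{n} records are too few for scheme {spec.scheme!r}")
    out = []
    for rep in range(spec.n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, rep)))
        perm = rng.permutation(n)
        parts = {"train": np.sort(perm[:n_train])}
        if n_valid:
            parts["valid"] = np.sort(perm[n_train : n_train + n_valid])
        parts["test"] = np.sort(perm[n_train + n_valid :])
        out.append(parts)
    return out


@dataclass
class ValidationReport:
    """Metric suite for one model on one evaluation set.

    ``exp_var`` and ``bias`` are NaN sentinels when the observed values
    have zero variance.
    """

    model_id: str
    mse: float
    rmse: float
    mae: float
    exp_var: float
    bias: float
    mse_mean: float
    n_eval: int
    label: str = ""
    indicator: str = ""

    def as_row(self) -> dict:
        return {
            "label": self.label,
            "indicator": self.indicator,
            "model": self.model_id,
            "MSE": self.mse,
            "RMSE": self.rmse,
            "MAE": self.mae,
            "exp. var.": self.exp_var,
            "MSE (mean)": self.mse_mean,
        }


def explained_variance(mse: float, var_obs: float) -> float:
    """Pseudo-R2: ``1 - MSE / var(obs)``; NaN when var(obs) is zero."""
    if var_obs == 0:
        return math.nan
    return 1.0 - mse / var_obs


def compute_metrics(
    obs: np.ndarray,
    pred: np.ndarray,
    model_id: str = "model",
    label: str = "",
    indicator: str = "",
) -> ValidationReport:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: obs {obs.shape} vs pred {pred.shape}")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    err = pred - obs
    mse = float((err**2).mean())
    var_obs = float(obs.var())  # population variance
    sd_obs = math.sqrt(var_obs)
    bias = (float(pred.mean() - obs.mean()) / sd_obs) if sd_obs > 0 else math.nan
    return ValidationReport(
        model_id=model_id,
        mse=mse,
        rmse=math.sqrt(mse),
        mae=float(np.abs(err).mean()),
        exp_var=explained_variance(mse, var_obs),
        bias=bias,
        mse_mean=var_obs,
        n_eval=obs.size,
        label=label,
        indicator=indicator,
    )


def aggregate_reports(reports: list[ValidationReport]) -> ValidationReport:
    """Combine per-repeat reports for one model into a single summary.

    MSE, MAE, var(obs) and bias are averaged across repeats; RMSE and the
    pseudo-R2 are then recomputed from the averaged MSE and variance so the
    internal identities (rmse^2 = mse; exp_var = 1 - mse/var) still hold.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    ids = {r.model_id for r in reports}
    if len(ids) != 1:
        raise ValueError("reports aggregate over repeats of a single model")
    mse = float(np.mean([r.mse for r in reports]))
    mae = float(np.mean([r.mae for r in reports]))
    var = float(np.mean([r.mse_mean for r in reports]))
    bias = float(np.mean([r.bias for r in reports]))
    return ValidationReport(
        model_id=reports[0].model_id,
        mse=mse,
        rmse=math.sqrt(mse),
        mae=mae,
        exp_var=explained_variance(mse, var),
        bias=bias,
        mse_mean=var,
        n_eval=int(np.sum([r.n_eval for r in reports])),
        label=reports[0].label,
        indicator=reports[0].indicator,
    )


def compare_models(reports: list[ValidationReport]) -> pd.DataFrame:
    """Comparison table with one row per model (MSE, RMSE, MAE, exp. var.,
    MSE (mean)), sorted best-first by the selection rule."""
    if not reports:
        raise ValueError("no reports to compare")
    rows = [r.as_row() for r in sorted(reports, key=_rank_key)]
    return pd.DataFrame(rows)


def _rank_key(r: ValidationReport):
    ev = -r.exp_var if math.isfinite(r.exp_var) else math.inf
    return (ev, r.rmse, r.mae)


def select_best(reports: list[ValidationReport]) -> str:
    """Highest explained variance wins; ties broken by lower RMSE, then
    lower MAE; deterministic."""
    if not reports:
        raise ValueError("no reports to select from")
    return min(reports, key=_rank_key).model_id
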