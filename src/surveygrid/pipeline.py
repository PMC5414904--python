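"""End-to-end orchestration: simulate -> extract -> select -> fit ->
validate -> predict -> report, under a single config and master seed.

Every stage validates its inputs against the domain-type invariants before
running, and derives its own RNG seed as a pure function of the master seed
and the stage name, so reruns with one config are bit-reproducible and
changing one stage's seed leaves earlier stages untouched.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import ClusterRecord, CovariateStack, GridSpec
from .covariates import DesignMatrix, build_design_matrix, jackknife_select, vif_filter
from .mapping import predict_surface, summarize_uncertainty
from .models import (
    AnnSearchSpace,
    GPConfig,
    fit_ann_ensemble,
    fit_gp,
    fit_linear,
    fit_mean_baseline,
)
from .rasters import read_clusters, read_raster, write_clusters, write_raster, write_stack
from .synthetic import (
    displace_clusters,
    gen_covariate_fields,
    gen_latent_surface,
    sample_clusters,
    urban_mask_from_layer,
    write_truth_json,
)
from .validation import SplitSpec, aggregate_reports, compare_models, compute_metrics, select_best, split_data

__all__ = ["RunConfig", "stage_seed", "simulate_demo", "run_pipeline"]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed, a pure function of (master, stage)."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2**31)


@dataclass
class SimulateConfig:
    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 1000.0
    n_fields: int = 4
    n_distance_fields: int = 1
    corr_length: float = 8000.0
    beta: list[float] = field(default_factory=lambda: [-0.3, 0.8, -0.5, 0.4, 0.0, 0.3])
    spatial_variance: float = 0.3
    range_param: float = 15000.0
    link: str = "logit"
    n_clusters: int = 400
    respondents_per_cluster: int = 25
    urban_quantile: float = 0.75


@dataclass
class RunConfig:
    """Pipeline configuration; every entry has a sensible default, so the
    bundled synthetic demo runs with nothing but a seed."""

    out_dir: str = "runs/demo"
    seed: int = 0
    indicator: str = "indicator"
    raster_paths: list[str] = field(default_factory=list)
    clusters_path: str | None = None
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    extraction_method: str = "buffer_mean"  # or 'buffer_mc'
    mc_draws: int = 100
    vif_threshold: float = 3.0
    jackknife: bool = True
    jackknife_repeats: int = 10
    jackknife_tolerance: float = 0.005
    split_scheme: str = "train_test_70_30"
    split_repeats: int = 10
    big_dataset_threshold: int = 2000  # above this, switch to 60/20/20
    models: list[str] = field(default_factory=lambda: ["mean", "linear", "gp", "ann"])
    gp_n_starts: int = 3
    ann_hidden_sizes: list[int] = field(default_factory=lambda: [4, 8])
    ann_learning_rates: list[float] = field(default_factory=lambda: [0.2])
    ann_momentum: float = 0.9
    ann_epochs: int = 600
    ann_tuning_repeats: int = 5
    ann_restarts: int = 2
    ann_ensemble: int = 3
    raster_format: str = "tif"
    uncertainty_kind: str = "sd"
    uncertainty_thresholds: list[float] = field(default_factory=lambda: [0.05, 0.1, 0.2])
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = data.pop("simulate", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(sim, dict):
            cfg.simulate = SimulateConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def apply_overrides(self, overrides: dict[str, str]) -> None:
        """Dotted key=value overrides, e.g. ``simulate.n_clusters=100``."""
        for key, raw in overrides.items():
            target = self
            parts = key.split(".")
            for part in parts[:-1]:
                if not hasattr(target, part):
                    raise ValueError(f"unknown config key {key!r}")
                target = getattr(target, part)
            if not hasattr(target, parts[-1]):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(target, parts[-1])
            setattr(target, parts[-1], _coerce(raw, current))


def _coerce(raw: str, like):
    if isinstance(like, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(like, int):
        return int(raw)
    if isinstance(like, float):
        return float(raw)
    if isinstance(like, list):
        return yaml.safe_load(raw)
    return raw


# ---------------------------------------------------------------------------
# Stages


def simulate_demo(config: RunConfig, directory: str | Path | None = None) -> Path:
    """Write a complete synthetic country: covariate stack, urban mask,
    truth parameters and a displaced cluster table."""
    sim = config.simulate
    directory = Path(directory or Path(config.out_dir) / "data")
    directory.mkdir(parents=True, exist_ok=True)
    grid = GridSpec(sim.n_rows, sim.n_cols, cell_size=sim.cell_size)
    stack = gen_covariate_fields(
        grid,
        sim.n_fields,
        sim.corr_length,
        seed=stage_seed(config.seed, "simulate.fields"),
        n_distance_fields=sim.n_distance_fields,
    )
    truth = gen_latent_surface(
        stack,
        np.asarray(sim.beta, dtype=float),
        sim.spatial_variance,
        sim.range_param,
        link=sim.link,
        seed=stage_seed(config.seed, "simulate.surface"),
    )
    urban = urban_mask_from_layer(stack.layers[0], quantile=sim.urban_quantile)
    clusters = sample_clusters(
        truth,
        sim.n_clusters,
        urban,
        sim.respondents_per_cluster,
        seed=stage_seed(config.seed, "simulate.clusters"),
        indicator=config.indicator,
    )
    clusters = displace_clusters(clusters, seed=stage_seed(config.seed, "simulate.displace"))
    fmt = "asc"
    write_stack(stack, directory, fmt=fmt)
    write_raster(urban, directory / f"urban_mask.{fmt}")
    write_raster(truth.latent_surface, directory / f"true_proportion.{fmt}")
    write_truth_json(truth, directory / "truth.json")
    write_clusters(clusters, directory / "clusters.csv", directory / "clusters_true.csv")
    return directory


def _load_inputs(config: RunConfig, data_dir: Path | None):
    if config.raster_paths:
        layers = [read_raster(p) for p in config.raster_paths]
        stack = CovariateStack(layers[0].grid, layers)
        clusters = read_clusters(config.clusters_path)
    else:
        if data_dir is None:
            raise ValueError("no input rasters configured and no simulated data")
        paths = sorted(
            p
            for p in data_dir.glob("*.asc")
            if p.stem not in ("urban_mask", "true_proportion")
        )
        layers = [read_raster(p) for p in paths]
        stack = CovariateStack(layers[0].grid, layers)
        clusters = read_clusters(data_dir / "clusters.csv", data_dir / "clusters_true.csv")
    if not clusters:
        raise ValueError("cluster table is empty")
    for cl in clusters:
        cl.validate_displacement()
    return stack, clusters


def _extract(config: RunConfig, stack, clusters) -> tuple[DesignMatrix, np.ndarray, np.ndarray]:
    design = build_design_matrix(
        stack,
        clusters,
        method=config.extraction_method,
        n_draws=config.mc_draws,
        seed=stage_seed(config.seed, "extract"),
    )
    by_id = {c.id: c for c in clusters}
    y = np.array([by_id[i].proportion for i in design.cluster_ids])
    coords = np.array([by_id[i].reported_xy for i in design.cluster_ids])
    return design, y, coords


def _select(config: RunConfig, design: DesignMatrix, y: np.ndarray):
    filtered, vif_report = vif_filter(design, threshold=config.vif_threshold)
    if config.jackknife and len(filtered.covariate_names) >= 2:
        jk = jackknife_select(
            filtered,
            y,
            n_repeats=config.jackknife_repeats,
            seed=stage_seed(config.seed, "select.jackknife"),
            tolerance=config.jackknife_tolerance,
        )
        vif_report.jackknife_scores = jk.jackknife_scores
        vif_report.removed_by_jackknife = jk.removed_by_jackknife
        vif_report.final_covariates = jk.final_covariates
        vif_report.baseline_score = jk.baseline_score
        vif_report.final_score = jk.final_score
        filtered = filtered.subset(jk.final_covariates)
    return filtered, vif_report


def _fit_one(config: RunConfig, name: str, design: DesignMatrix, y, coords, seed: int):
    if name == "mean":
        return fit_mean_baseline(y)
    if name == "linear":
        return fit_linear(design, y)
    if name == "gp":
        return fit_gp(design, coords, y, GPConfig(n_starts=config.gp_n_starts))
    if name == "ann":
        space = AnnSearchSpace(
            hidden_sizes=tuple(config.ann_hidden_sizes),
            learning_rates=tuple(config.ann_learning_rates),
            momentum=config.ann_momentum,
            epochs=config.ann_epochs,
            n_repeats=config.ann_tuning_repeats,
        )
        return fit_ann_ensemble(design, y, n_members=config.ann_ensemble, search_space=space, seed=seed)
    raise ValueError(f"unknown model {name!r}")


def _predict_rows(model, design: DesignMatrix, coords, idx):
    from .models import AnnModel, LinearModel, MeanModel, SpatialGPModel, ann_predict, gp_predict

    X = design.values[idx]
    if isinstance(model, SpatialGPModel):
        return gp_predict(model, X, coords[idx])[0]
    if isinstance(model, list) or isinstance(model, AnnModel):
        models = model if isinstance(model, list) else [model]
        return ann_predict(models, X)[0]
    if isinstance(model, (LinearModel, MeanModel)):
        return model.predict(X)
    raise TypeError(type(model).__name__)


def _validate(config: RunConfig, design: DesignMatrix, y, coords):
    n = design.n_rows
    scheme = config.split_scheme
    if n > config.big_dataset_threshold:
        scheme = "train_valid_test_60_20_20"
    spec = SplitSpec(scheme=scheme, n_repeats=config.split_repeats, seed=stage_seed(config.seed, "validate"))
    partitions = split_data(n, spec)
    reports = []
    for name in config.models:
        per_repeat = []
        for rep, parts in enumerate(partitions):
            tr, te = parts["train"], parts["test"]
            sub = DesignMatrix(
                cluster_ids=[design.cluster_ids[i] for i in tr],
                covariate_names=design.covariate_names,
                values=design.values[tr],
                extraction_method=design.extraction_method,
                col_means=design.col_means,
                col_sds=design.col_sds,
            )
            model = _fit_one(
                config, name, sub, y[tr], coords[tr], seed=stage_seed(config.seed, f"fit.{name}.{rep}")
            )
            pred = _predict_rows(model, design, coords, te)
            per_repeat.append(compute_metrics(y[te], pred, model_id=name, indicator=config.indicator))
        reports.append(aggregate_reports(per_repeat))
    return reports


_STAGE_ORDER = ["simulate", "extract", "select", "fit", "validate", "predict", "report"]


def run_pipeline(config: RunConfig, until: str = "report") -> Path:
    """Execute the stages in order up to ``until`` (default: all of them)
    and write each stage's artifacts into the run directory."""
    if until not in _STAGE_ORDER:
        raise ValueError(f"unknown stage {until!r}")
    stop = _STAGE_ORDER.index(until)
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.models:
        raise ValueError("model list must be non-empty")

    logger.info("stage=simulate")
    data_dir = None
    if not config.raster_paths:
        data_dir = simulate_demo(config)
    if stop < _STAGE_ORDER.index("extract"):
        return out
    stack, clusters = _load_inputs(config, data_dir)

    logger.info("stage=extract n_clusters=%d n_layers=%d", len(clusters), len(stack))
    design, y, coords = _extract(config, stack, clusters)
    design.to_csv(out / "design_matrix.csv")
    if stop < _STAGE_ORDER.index("select"):
        return out

    logger.info("stage=select")
    design_sel, selection = _select(config, design, y)
    selection.to_json(out / "selection.json")
    if stop < _STAGE_ORDER.index("fit"):
        return out

    logger.info("stage=validate scheme=%s repeats=%d", config.split_scheme, config.split_repeats)
    reports = _validate(config, design_sel, y, coords)
    table = compare_models(reports)
    table.to_csv(out / "comparison.csv", index=False)
    table.to_json(out / "comparison.json", orient="records", indent=2)
    best = select_best(reports)
    logger.info("stage=validate best_model=%s", best)

    logger.info("stage=fit model=%s (final, all clusters)", best)
    final_model = _fit_one(
        config, best, design_sel, y, coords, seed=stage_seed(config.seed, f"fit.{best}.final")
    )
    _write_model_summary(final_model, best, out / "model.json")
    if stop < _STAGE_ORDER.index("predict"):
        return out

    logger.info("stage=predict")
    surface = predict_surface(
        final_model,
        stack.subset(design_sel.covariate_names),
        model_id=best,
        indicator=config.indicator,
        uncertainty=config.uncertainty_kind,
    )
    fmt = config.raster_format
    write_raster(surface.mean, out / f"{config.indicator}_mean.{fmt}")
    write_raster(surface.sd, out / f"{config.indicator}_sd.{fmt}")
    if stop < _STAGE_ORDER.index("report"):
        return out

    logger.info("stage=report")
    summarize_uncertainty(surface, config.uncertainty_thresholds).to_csv(
        out / "uncertainty_summary.csv", index=False
    )
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in (
                "simulate.fields",
                "simulate.surface",
                "simulate.clusters",
                "simulate.displace",
                "extract",
                "select.jackknife",
                "validate",
            )
        },
        "best_model": best,
        "final_covariates": design_sel.covariate_names,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _write_model_summary(model, name: str, path: Path) -> None:
    from .models import LinearModel, MeanModel, SpatialGPModel

    payload: dict = {"model": name, "format_version": 1}
    if isinstance(model, SpatialGPModel):
        payload.update(
            beta=model.beta.tolist(),
            sigma_v2=model.sigma_v2,
            range_m=model.range_m,
            sigma_e2=model.sigma_e2,
            covariates=model.covariate_names,
        )
    elif isinstance(model, LinearModel):
        payload.update(beta=model.beta.tolist(), covariates=model.covariate_names)
    elif isinstance(model, MeanModel):
        payload.update(mean=model.mean)
    elif isinstance(model, list):
        payload.update(
            ensemble=len(model),
            layer_sizes=list(model[0].layer_sizes),
            covariates=model[0].covariate_names,
        )
    path.write_text(json.dumps(payload, indent=2))
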