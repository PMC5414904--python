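"""Raster harmonization and file I/O.

Supports two on-disk dialects: ESRI ASCII grid (plain text, full decimal
precision) and single-band GeoTIFF (float32, georeferenced through the
standard ModelPixelScale / ModelTiepoint tags, written and read with
tifffile).  Cluster tables round-trip as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ClusterRecord, CovariateStack, GridSpec, RasterLayer

__all__ = [
    "resample_to_grid",
    "read_raster",
    "write_raster",
    "read_clusters",
    "write_clusters",
    "read_stack",
    "write_stack",
]

_NODATA = -9999.0

# ---------------------------------------------------------------------------
# Resampling


def resample_to_grid(layer: RasterLayer, target: GridSpec, method: str = "nearest") -> RasterLayer:
    """Harmonize ``layer`` onto ``target``.

    ``nearest`` and ``bilinear`` sample at target cell centres (bilinear
    skips missing neighbours, renormalizing the weights); ``mean_aggregate``
    averages all source cells whose centres fall inside a target cell.
    Missing values propagate as NaN.
    """
    src = layer.grid
    sx0, sx1, sy0, sy1 = src.extent
    tx0, tx1, ty0, ty1 = target.extent
    if sx1 <= tx0 or tx1 <= sx0 or sy1 <= ty0 or ty1 <= sy0:
        raise ValueError("source and target grids have disjoint extents")
    if method == "nearest":
        out = _resample_nearest(layer, target)
    elif method == "bilinear":
        out = _resample_bilinear(layer, target)
    elif method == "mean_aggregate":
        out = _resample_mean(layer, target)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return RasterLayer(target, layer.name, out)


def _resample_nearest(layer: RasterLayer, target: GridSpec) -> np.ndarray:
    src = layer.grid
    tx, ty = target.center_mesh()
    inside = src.contains(tx, ty)
    rows, cols = src.cell_of(tx, ty)
    rows = np.clip(rows, 0, src.n_rows - 1)
    cols = np.clip(cols, 0, src.n_cols - 1)
    out = layer.values[rows, cols]
    out[~inside] = np.nan
    return out


def _resample_bilinear(layer: RasterLayer, target: GridSpec) -> np.ndarray:
    src = layer.grid
    tx, ty = target.center_mesh()
    # fractional index relative to source cell centres
    fc = (tx - src.origin_x) / src.cell_size - 0.5
    fr = (src.origin_y - ty) / src.cell_size - 0.5
    c0 = np.floor(fc).astype(int)
    r0 = np.floor(fr).astype(int)
    wc = fc - c0
    wr = fr - r0
    total = np.zeros(target.shape)
    weight = np.zeros(target.shape)
    for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
        rr = np.clip(r0 + dr, 0, src.n_rows - 1)
        cc = np.clip(c0 + dc, 0, src.n_cols - 1)
        w = ((1 - wr) if dr == 0 else wr) * ((1 - wc) if dc == 0 else wc)
        v = layer.values[rr, cc]
        ok = np.isfinite(v)
        total += np.where(ok, w * np.nan_to_num(v), 0.0)
        weight += np.where(ok, w, 0.0)
    inside = src.contains(tx, ty)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(weight > 0, total / weight, np.nan)
    out[~inside] = np.nan
    return out


def _resample_mean(layer: RasterLayer, target: GridSpec) -> np.ndarray:
    src = layer.grid
    sx, sy = src.center_mesh()
    inside = target.contains(sx, sy)
    rows, cols = target.cell_of(sx, sy)
    v = layer.values
    ok = inside & np.isfinite(v)
    total = np.zeros(target.shape)
    count = np.zeros(target.shape)
    np.add.at(total, (rows[ok], cols[ok]), v[ok])
    np.add.at(count, (rows[ok], cols[ok]), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(count > 0, total / count, np.nan)


# ---------------------------------------------------------------------------
# Raster file I/O


def write_raster(layer: RasterLayer, path: str | Path) -> None:
    """Write a layer as ESRI ASCII grid (.asc/.txt) or GeoTIFF (.tif)."""
    path = Path(path)
    if path.suffix.lower() in (".asc", ".txt", ".grd"):
        _write_ascii(layer, path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        _write_gtiff(layer, path)
    else:
        raise ValueError(f"unsupported raster extension {path.suffix!r}")


def read_raster(path: str | Path, name: str | None = None) -> RasterLayer:
    path = Path(path)
    if path.suffix.lower() in (".asc", ".txt", ".grd"):
        return _read_ascii(path, name)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_gtiff(path, name)
    raise ValueError(f"unsupported raster extension {path.suffix!r}")


def _write_ascii(layer: RasterLayer, path: Path) -> None:
    g = layer.grid
    vals = np.where(np.isfinite(layer.values), layer.values, _NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin_x!r}\n")
        fh.write(f"yllcorner {g.origin_y - g.n_rows * g.cell_size!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_ascii(path: Path, name: str | None) -> RasterLayer:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in keys and len(parts) == 2:
                try:
                    header[parts[0].lower()] = float(parts[1])
                except ValueError as exc:
                    raise ValueError(f"malformed header field {parts[0]!r} in {path}") from exc
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise ValueError(f"malformed data row in {path}: {line.strip()!r}") from exc
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"missing header field {req!r} in {path}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    vals = np.array(rows, dtype=float)
    if vals.shape != (n_rows, n_cols):
        raise ValueError(
            f"data block shape {vals.shape} does not match header "
            f"({n_rows}, {n_cols}) in {path}"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals[vals == nodata] = np.nan
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
    )
    return RasterLayer(grid, name or path.stem, vals)


_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


def _write_gtiff(layer: RasterLayer, path: Path) -> None:
    g = layer.grid
    meta = json.dumps({"name": layer.name, "crs_tag": g.crs_tag})
    tifffile.imwrite(
        path,
        layer.values.astype(np.float32),
        description=meta,
        extratags=[
            (_TAG_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_x, g.origin_y, 0.0)),
        ],
    )


def _read_gtiff(path: Path, name: str | None) -> RasterLayer:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        vals = page.asarray().astype(float)
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags:
            raise ValueError(f"missing ModelPixelScale tag in {path}")
        if _TAG_TIEPOINT not in tags:
            raise ValueError(f"missing ModelTiepoint tag in {path}")
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        desc = tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    if vals.ndim != 2:
        raise ValueError(f"expected a single-band raster in {path}")
    grid = GridSpec(
        n_rows=vals.shape[0],
        n_cols=vals.shape[1],
        origin_x=tie[3] - tie[0] * scale[0],
        origin_y=tie[4] + tie[1] * scale[1],
        cell_size=float(scale[0]),
        crs_tag=meta.get("crs_tag", "local-metric"),
    )
    return RasterLayer(grid, name or meta.get("name", path.stem), vals)


def write_stack(stack: CovariateStack, directory: str | Path, fmt: str = "asc") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for lyr in stack.layers:
        p = directory / f"{lyr.name}.{fmt}"
        write_raster(lyr, p)
        paths.append(p)
    return paths


def read_stack(paths: list[str | Path]) -> CovariateStack:
    layers = [read_raster(p) for p in paths]
    return CovariateStack(layers[0].grid, layers)


# ---------------------------------------------------------------------------
# Cluster table I/O

_CLUSTER_COLUMNS = [
    "id",
    "x",
    "y",
    "stratum",
    "flagged_far",
    "n_respondents",
    "n_positive",
    "indicator",
]


def write_clusters(
    clusters: list[ClusterRecord],
    path: str | Path,
    true_coords_path: str | Path | None = None,
) -> None:
    """Write the cluster table (reported coordinates) as CSV.

    ``true_coords_path`` optionally writes an evaluation-only companion file
    with the undisplaced coordinates.
    """
    df = pd.DataFrame(
        {
            "id": [c.id for c in clusters],
            "x": [c.reported_xy[0] for c in clusters],
            "y": [c.reported_xy[1] for c in clusters],
            "stratum": [c.stratum for c in clusters],
            "flagged_far": [int(c.flagged_far) for c in clusters],
            "n_respondents": [c.n_respondents for c in clusters],
            "n_positive": [c.n_positive for c in clusters],
            "indicator": [c.indicator for c in clusters],
        }
    )
    df.to_csv(path, index=False)
    if true_coords_path is not None:
        pd.DataFrame(
            {
                "id": [c.id for c in clusters],
                "true_x": [c.true_xy[0] for c in clusters],
                "true_y": [c.true_xy[1] for c in clusters],
            }
        ).to_csv(true_coords_path, index=False)


def read_clusters(
    path: str | Path, true_coords_path: str | Path | None = None
) -> list[ClusterRecord]:
    """Read a cluster CSV; the observed proportion is always recomputed
    from the counts, never trusted from the file."""
    df = pd.read_csv(path)
    for col in _CLUSTER_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cluster table {path} is missing column {col!r}")
    true_xy = None
    if true_coords_path is not None:
        tdf = pd.read_csv(true_coords_path).set_index("id")
        true_xy = {i: (r["true_x"], r["true_y"]) for i, r in tdf.iterrows()}
    records = []
    for i, row in df.iterrows():
        if row["n_positive"] > row["n_respondents"]:
            raise ValueError(
                f"row {i + 2} of {path}: n_positive={row['n_positive']} exceeds "
                f"n_respondents={row['n_respondents']}"
            )
        reported = (float(row["x"]), float(row["y"]))
        tx = true_xy.get(row["id"], reported) if true_xy else reported
        records.append(
            ClusterRecord(
                id=str(row["id"]),
                true_xy=tx,
                reported_xy=reported,
                stratum=str(row["stratum"]),
                flagged_far=bool(row["flagged_far"]),
                n_respondents=int(row["n_respondents"]),
                n_positive=int(row["n_positive"]),
                indicator=str(row["indicator"]),
            )
        )
    return records
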