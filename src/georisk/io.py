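"""Readers/writers for the pipeline's file formats.

Rasters travel as ESRI ASCII grids (``.asc``) — plain text, one header of
ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value followed by the
row-major array — so every artifact of a run remains diff-able text.
Points travel as CSV (columns x, y[, label][, partition]) or GeoJSON
point collections; tables and reports as CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .grid import CasePoints, CriterionRaster, StudyArea

__all__ = [
    "read_raster",
    "write_raster",
    "read_points",
    "write_points",
    "write_json",
    "read_json",
]

_NODATA = -9999.0


def write_raster(raster: CriterionRaster, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid; NaN cells become NODATA."""
    path = Path(path)
    area = raster.area
    vals = np.where(np.isfinite(raster.values), raster.values, _NODATA)
    header = (
        f"ncols {area.ncols}\n"
        f"nrows {area.nrows}\n"
        f"xllcorner {area.x_min!r}\n"
        f"yllcorner {area.y_min!r}\n"
        f"cellsize {area.cell_size!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")
    return path


def read_raster(path: str | Path, name: str | None = None) -> CriterionRaster:
    """Read an ESRI ASCII grid; NODATA cells become NaN (and mask=False)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline()
            try:
                key, val = line.split()
                header[key.lower()] = float(val)
            except ValueError as exc:
                raise SchemaError(f"{path}: malformed ASCII-grid header "
                                  f"line {line!r}") from exc
        data = np.loadtxt(fh)
    try:
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        cell = header["cellsize"]
        x_min = header["xllcorner"]
        y_max = header["yllcorner"] + nrows * cell
        nodata = header.get("nodata_value", _NODATA)
    except KeyError as exc:
        raise SchemaError(f"{path}: missing header field {exc}") from exc
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape != (nrows, ncols):
        raise SchemaError(f"{path}: data shape {data.shape} does not match "
                          f"header ({nrows}, {ncols})")
    values = np.where(data == nodata, np.nan, data)
    mask = np.isfinite(values)
    if not mask.any():
        raise SchemaError(f"{path}: raster has no valid cells")
    area = StudyArea(x_min, y_max, cell, mask)
    return CriterionRaster(area, values, name or path.stem)


def write_points(points: CasePoints, path: str | Path,
                 fmt: str | None = None) -> Path:
    """Write a point set as CSV or GeoJSON (by extension if fmt omitted)."""
    path = Path(path)
    fmt = fmt or ("geojson" if path.suffix.lower() in (".geojson", ".json")
                  else "csv")
    has_part = points.partition is not None
    if fmt == "csv":
        df = pd.DataFrame({"x": points.x, "y": points.y, "label": points.label})
        if has_part:
            df["partition"] = points.partition
        df.to_csv(path, index=False, float_format="%.9f")
    elif fmt == "geojson":
        feats = []
        for i in range(len(points)):
            props = {"label": int(points.label[i])}
            if has_part:
                props["partition"] = str(points.partition[i])
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [float(points.x[i]),
                                             float(points.y[i])]},
                "properties": props,
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    else:
        raise SchemaError(f"unknown point format {fmt!r}")
    return path


def read_points(path: str | Path, fmt: str | None = None) -> CasePoints:
    """Read a point set; malformed rows are reported with line numbers."""
    path = Path(path)
    fmt = fmt or ("geojson" if path.suffix.lower() in (".geojson", ".json")
                  else "csv")
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise SchemaError(f"{path}: empty input file") from exc
        missing = {"x", "y"} - set(df.columns)
        if missing:
            raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
        bad_lines = []
        for col in ("x", "y"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()] + 2  # 1-based + header
            bad_lines.extend(bad.tolist())
            df[col] = coerced
        nan_rows = df.index[df[["x", "y"]].isna().any(axis=1)] + 2
        bad_lines.extend(i for i in nan_rows if i not in bad_lines)
        if bad_lines:
            raise SchemaError(
                f"{path}: non-numeric or missing coordinates at line(s) "
                f"{sorted(set(bad_lines))}")
        label = df["label"].to_numpy(dtype=int) if "label" in df \
            else np.ones(len(df), dtype=int)
        part = df["partition"].to_numpy(dtype=object) if "partition" in df else None
        return CasePoints(df["x"].to_numpy(), df["y"].to_numpy(), label, part)
    if fmt == "geojson":
        with open(path) as fh:
            gj = json.load(fh)
        feats = gj.get("features", [])
        if not feats:
            raise SchemaError(f"{path}: empty GeoJSON feature collection")
        xs, ys, labels, parts = [], [], [], []
        for i, f in enumerate(feats):
            geom = f.get("geometry") or {}
            if geom.get("type") != "Point":
                raise SchemaError(f"{path}: feature {i} is not a Point")
            x, y = geom["coordinates"][:2]
            xs.append(float(x))
            ys.append(float(y))
            props = f.get("properties") or {}
            labels.append(int(props.get("label", 1)))
            parts.append(props.get("partition"))
        part = np.array(parts, dtype=object) if all(p is not None for p in parts) \
            else None
        return CasePoints(np.array(xs), np.array(ys), np.array(labels), part)
    raise SchemaError(f"unknown point format {fmt!r}")


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
    return path


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
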