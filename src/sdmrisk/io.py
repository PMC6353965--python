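"""Plain-text I/O adapters: ESRI ASCII rasters, CSV tables, GeoJSON, manifests.

Rasters are exchanged as single-band ESRI ASCII grids (``.asc``), a
widely-supported text raster format: a six-line header (ncols, nrows,
xllcorner, yllcorner, cellsize, NODATA_value) followed by rows of values,
first row northernmost — matching the in-memory convention of
:class:`sdmrisk.grids.GridSpec`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import EnvStack, GridSpec

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_stack",
    "read_stack",
    "read_occurrences",
    "write_occurrences",
    "write_geojson",
    "write_manifest",
    "file_sha256",
]

NODATA = -9999.0


def write_ascii_grid(path, grid: GridSpec, values: np.ndarray, fmt: str = "%.10g") -> None:
    """Write one raster layer as an ESRI ASCII grid (NaN -> NODATA)."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"array shape {values.shape} != grid shape {grid.shape}")
    out = np.where(np.isnan(values), NODATA, values)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon!r}\n"
        f"yllcorner {grid.south!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path, crs_id: str = "EPSG:4326") -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; NODATA becomes NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
        crs_id=crs_id,
    )
    values = values.reshape(grid.shape)
    nodata = header.get("nodata_value", NODATA)
    values[values == nodata] = np.nan
    return grid, values


def write_stack(directory, stack: EnvStack) -> None:
    """Write a stack as one ``.asc`` per layer plus ``stack.json`` metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.layers.items():
        write_ascii_grid(directory / f"{name}.asc", stack.grid, arr)
    meta = {
        "crs_id": stack.grid.crs_id,
        "layers": stack.layer_names,
        "static_flags": stack.static_flags,
        "train_bounds": {k: list(v) for k, v in stack.train_bounds.items()},
        "clamped": stack.clamped,
    }
    (directory / "stack.json").write_text(json.dumps(meta, indent=1))


def read_stack(directory) -> EnvStack:
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    layers: dict[str, np.ndarray] = {}
    grid = None
    for name in meta["layers"]:
        g, arr = read_ascii_grid(directory / f"{name}.asc", crs_id=meta.get("crs_id", "EPSG:4326"))
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError(f"layer {name!r} grid mismatch:\n{g!r}\nvs\n{grid!r}")
        layers[name] = arr
    return EnvStack(
        grid=grid,
        layers=layers,
        static_flags=dict(meta.get("static_flags", {})),
        train_bounds={k: tuple(v) for k, v in meta.get("train_bounds", {}).items()},
        clamped=bool(meta.get("clamped", False)),
    )


OCC_COLUMNS = ["species", "lon", "lat", "year", "source"]


def read_occurrences(path) -> tuple[pd.DataFrame, int]:
    """Read an occurrence CSV (species,lon,lat,year,source).

    Malformed rows (unparseable lon/lat/year) are skipped with a warning;
    returns ``(frame, n_skipped)``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in OCC_COLUMNS[:4] if c not in raw.columns]
    if missing:
        raise ValueError(f"occurrence file {path} missing columns: {missing}")
    if "source" not in raw.columns:
        raw["source"] = ""
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    lat = pd.to_numeric(raw["lat"], errors="coerce")
    year = pd.to_numeric(raw["year"], errors="coerce")
    bad = lon.isna() | lat.isna() | year.isna()
    n_skipped = int(bad.sum())
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} malformed occurrence rows")
    out = pd.DataFrame(
        {
            "species": raw.loc[~bad, "species"].astype(str),
            "lon": lon[~bad].astype(float),
            "lat": lat[~bad].astype(float),
            "year": year[~bad].astype(int),
            "source": raw.loc[~bad, "source"].astype(str),
        }
    ).reset_index(drop=True)
    return out, n_skipped


def write_occurrences(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, columns=[c for c in OCC_COLUMNS if c in frame.columns])


def write_geojson(path, geometry, properties: dict | None = None) -> None:
    """Write a shapely geometry as a single-feature GeoJSON file."""
    from shapely.geometry import mapping

    feature = {
        "type": "Feature",
        "properties": properties or {},
        "geometry": mapping(geometry),
    }
    obj = {"type": "FeatureCollection", "features": [feature]}
    Path(path).write_text(json.dumps(obj))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True, default=_json_default))
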