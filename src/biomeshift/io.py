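"""Plain-text writers for the pipeline's artifacts.

Rasters go out as ESRI ASCII grids (.asc, single band, GDAL/QGIS
readable), points as CSV and GeoJSON, tables as CSV and summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic import CovariateStack, GridSpec, ObservationTable

NODATA = -9999.0


def write_ascii_grid(path, array: np.ndarray, grid: GridSpec, nodata: float = NODATA) -> Path:
    """Write one band as an ESRI ASCII grid (row 0 = north, as stored)."""
    path = Path(path)
    arr = np.asarray(array, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError("array does not match the grid shape")
    body = np.where(np.isfinite(arr), arr, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.lon_min}\n"
        f"yllcorner {grid.lat_min}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")
    return path


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid back into (array with NaN nodata, GridSpec)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        lon_min=header["xllcorner"],
        lat_min=header["yllcorner"],
        cell_size=header["cellsize"],
    )
    data = np.atleast_2d(np.asarray(data, dtype=float))
    data[data == header["nodata_value"]] = np.nan
    return data, grid


def write_stack(directory, stack: CovariateStack) -> list[Path]:
    """One .asc per layer plus a kinds manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in stack.layer_names:
        arr = np.where(stack.mask, np.nan, stack.layers[name])
        paths.append(write_ascii_grid(directory / f"{name}.asc", arr, stack.grid))
    manifest = directory / "layers.json"
    manifest.write_text(json.dumps({"kinds": stack.kinds}, indent=2))
    paths.append(manifest)
    return paths


def write_observations_csv(path, obs: ObservationTable) -> Path:
    path = Path(path)
    obs.frame[["point_id", "lon", "lat", "label"]].to_csv(path, index=False)
    return path


def write_observations_geojson(path, obs: ObservationTable) -> Path:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(lon), float(lat)]},
            "properties": {"point_id": pid, "label": label},
        }
        for pid, lon, lat, label in obs.frame[
            ["point_id", "lon", "lat", "label"]
        ].itertuples(index=False)
    ]
    path = Path(path)
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
    return path


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
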