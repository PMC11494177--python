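"""Readers and writers for the pipeline's on-disk formats.

Tables travel as CSV or Parquet with a JSON metadata sidecar carrying the
configuration hash, the seed and the package version; district geometry is
written as GeoJSON points; gridded temperatures as NetCDF (classic format
via the scipy backend).  Dates are ISO-8601 strings, temperatures decimal
degrees C, counts integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__

__all__ = ["write_table", "read_table", "write_geojson_points",
           "write_netcdf", "read_station_table", "StationTableReport",
           "write_checkpoint", "read_checkpoint"]

STATION_COLUMNS = ["station_id", "lon", "lat", "date", "tmean_c"]


def _sidecar(path: Path, metadata: dict | None) -> None:
    meta = {"version": __version__}
    meta.update(metadata or {})
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=str))


def write_table(df: pd.DataFrame, path: str | Path,
                metadata: dict | None = None) -> Path:
    """Write a table as CSV or Parquet (by extension) plus metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    elif path.suffix == ".csv":
        df.to_csv(path, index=False, date_format="%Y-%m-%d")
    else:
        raise ValueError(f"unsupported table format {path.suffix!r}")
    _sidecar(path, metadata)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def write_geojson_points(districts: pd.DataFrame, path: str | Path,
                         metadata: dict | None = None) -> Path:
    """District reference coordinates as a GeoJSON FeatureCollection."""
    feats = []
    for row in districts.itertuples(index=False):
        props = {k: getattr(row, k) for k in districts.columns
                 if k not in ("lon", "lat")}
        props = {k: (bool(v) if isinstance(v, np.bool_) else v)
                 for k, v in props.items()}
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row.lon), float(row.lat)]},
            "properties": props,
        })
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
    _sidecar(path, metadata)
    return path


def write_netcdf(da: xr.DataArray, path: str | Path, name: str = "tmean",
                 metadata: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds = da.to_dataset(name=name)
    for k, v in (metadata or {}).items():
        ds.attrs[k] = str(v)
    ds.attrs["version"] = __version__
    ds.to_netcdf(path, engine="scipy")
    return path


def write_checkpoint(arrays: dict[str, np.ndarray], path: str | Path,
                     metadata: dict | None = None) -> Path:
    """Serialize fitted parameters as one .npz checkpoint + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)
    _sidecar(path, metadata)
    return path


def read_checkpoint(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(Path(path)) as z:
        return {k: z[k] for k in z.files}


@dataclass
class StationTableReport:
    """Validation outcome of a station observation table."""

    n_stations: int
    n_rows: int
    gaps: dict[str, list]      # station_id -> missing dates within its span
    missing_values: int        # rows with NaN temperature (flagged, not filled)


def read_station_table(path: str | Path) -> tuple[pd.DataFrame, StationTableReport]:
    """Read and validate a station CSV (station_id, lon, lat, date, tmean_c).

    Produces a calendar-gap report per station; missing values are flagged
    in the report but left untouched.  Duplicate (station, date) rows raise
    an error naming the first offending row.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"station table is missing mandatory columns: {missing_cols}")
    df["date"] = pd.to_datetime(df["date"])
    dup = df.duplicated(subset=["station_id", "date"])
    if dup.any():
        i = int(np.nonzero(dup.values)[0][0])
        row = df.iloc[i]
        raise ValueError(
            f"duplicate (station, date) at row {i}: "
            f"{row['station_id']} {row['date'].date()}")
    gaps: dict[str, list] = {}
    for sid, g in df.groupby("station_id"):
        full = pd.date_range(g["date"].min(), g["date"].max(), freq="D")
        missing = full.difference(pd.DatetimeIndex(g["date"]))
        if len(missing):
            gaps[str(sid)] = [d.date().isoformat() for d in missing]
    report = StationTableReport(
        n_stations=df["station_id"].nunique(), n_rows=len(df),
        gaps=gaps, missing_values=int(df["tmean_c"].isna().sum()))
    return df, report
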