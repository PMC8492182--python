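"""File formats: ESRI ASCII grids, legends, manifests, date tables, reports.

All formats are plain text. Categorical biome rasters and arrival surfaces
travel as ESRI ASCII grids (the interchange format of the raster GIS
world); tables are CSV. Every CLI run also writes a JSON run record with
the resolved configuration so results can be reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ebm import ArrivalSurface
from .landscape import BiomeRaster, GridGeometry, LandscapeSeries

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "read_legend",
    "read_landscape_manifest",
    "write_landscape",
    "read_dates_csv",
    "write_dates_csv",
    "write_arrival",
    "read_arrival",
    "write_report",
    "write_run_record",
]

_HEADER_KEYS = (
    "ncols",
    "nrows",
    "xllcorner",
    "xllcenter",
    "yllcorner",
    "yllcenter",
    "cellsize",
    "nodata_value",
)


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry, float]:
    """Read an ESRI ASCII grid: (values, geometry, nodata value).

    Accepts both corner- and centre-referenced headers; geometry stores the
    lower-left cell centre. Values keep their float form; callers decide on
    integer casting.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing required header field {key!r}")
    cell = header["cellsize"]
    if "xllcenter" in header:
        x0 = header["xllcenter"]
    elif "xllcorner" in header:
        x0 = header["xllcorner"] + cell / 2.0
    else:
        raise ValueError(f"{path}: missing xllcorner/xllcenter")
    if "yllcenter" in header:
        y0 = header["yllcenter"]
    elif "yllcorner" in header:
        y0 = header["yllcorner"] + cell / 2.0
    else:
        raise ValueError(f"{path}: missing yllcorner/yllcenter")
    nodata = header.get("nodata_value", -9999.0)
    values = np.loadtxt(lines[data_start:], ndmin=2)
    geom = GridGeometry(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=cell,
        x_origin=x0,
        y_origin=y0,
    )
    if values.shape != geom.shape:
        raise ValueError(
            f"{path}: data block shape {values.shape} does not match header "
            f"({geom.n_rows} rows x {geom.n_cols} cols)"
        )
    return values, geom, nodata


def write_ascii_grid(
    values: np.ndarray,
    geometry: GridGeometry,
    path,
    nodata: float = -9999,
    fmt: str = "%.6g",
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    half = geometry.cell_size / 2.0
    with path.open("w") as fh:
        fh.write(f"ncols {geometry.n_cols}\n")
        fh.write(f"nrows {geometry.n_rows}\n")
        fh.write(f"xllcorner {geometry.x_origin - half:g}\n")
        fh.write(f"yllcorner {geometry.y_origin - half:g}\n")
        fh.write(f"cellsize {geometry.cell_size:g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, values, fmt=fmt)


def read_legend(path) -> dict[int, str]:
    """Read a biome legend CSV with columns ``code,name``."""
    df = pd.read_csv(path)
    missing = {"code", "name"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: legend is missing columns {sorted(missing)}")
    return dict(zip(df["code"].astype(int), df["name"].astype(str)))


def read_landscape_manifest(path) -> LandscapeSeries:
    """Read a manifest CSV (``slice_date,raster_path``) into a series.

    Raster paths are resolved relative to the manifest's directory. Slices
    must share one grid geometry; duplicates and mismatches are errors
    naming the slice.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"slice_date", "raster_path"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: manifest is missing columns {sorted(missing)}"
        )
    dup = df["slice_date"][df["slice_date"].duplicated()]
    if not dup.empty:
        raise ValueError(
            f"{path}: duplicate slice_date {sorted(set(dup.tolist()))}"
        )
    slices: dict[float, BiomeRaster] = {}
    ref_geom = None
    for row in df.itertuples(index=False):
        raster_path = path.parent / str(row.raster_path)
        values, geom, nodata = read_ascii_grid(raster_path)
        if ref_geom is None:
            ref_geom = geom
        elif geom != ref_geom:
            raise ValueError(
                f"slice {row.slice_date} BP ({raster_path}) has geometry "
                f"{geom.shape}, expected {ref_geom.shape}"
            )
        slices[float(row.slice_date)] = BiomeRaster(
            geometry=geom,
            codes=values.astype(int),
            nodata_code=int(nodata),
        )
    return LandscapeSeries(slices)


def write_landscape(series: LandscapeSeries, out_dir) -> Path:
    """Write a series as ASCII grids plus a manifest CSV; returns manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for d in series.slice_dates:
        raster = series[d]
        name = f"biomes_{int(d)}bp.asc"
        write_ascii_grid(
            raster.codes,
            raster.geometry,
            out_dir / name,
            nodata=raster.nodata_code,
            fmt="%d",
        )
        rows.append({"slice_date": d, "raster_path": name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dates_csv(path) -> pd.DataFrame:
    """Read a dated-site CSV with columns ``site_id,x,y,med_cal_bp``."""
    df = pd.read_csv(path)
    missing = [c for c in ("site_id", "x", "y", "med_cal_bp") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: date table is missing columns {missing}")
    for col in ("x", "y", "med_cal_bp"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col!r} in data row {int(bad[0]) + 1}"
            )
        if coerced.isna().any():
            raise ValueError(
                f"{path}: missing {col!r} in data row "
                f"{int(df.index[coerced.isna()][0]) + 1}"
            )
        df[col] = coerced
    return df


def write_dates_csv(dates: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dates.to_csv(path, index=False)


def write_arrival(surface: ArrivalSurface, path, nodata: float = -9999) -> None:
    """Write an arrival surface as an ASCII grid; unreached cells = NODATA."""
    values = np.where(np.isnan(surface.arrival), nodata, surface.arrival)
    write_ascii_grid(values, surface.geometry, path, nodata=nodata, fmt="%.3f")


def read_arrival(
    path, origin: tuple[int, int] = (0, 0), start=None, end=None
) -> ArrivalSurface:
    values, geom, nodata = read_ascii_grid(path)
    arrival = np.where(values == nodata, np.nan, values)
    finite = arrival[~np.isnan(arrival)]
    if start is None:
        start = float(finite.max()) if finite.size else 0.0
    if end is None:
        end = float(finite.min()) if finite.size else 0.0
    return ArrivalSurface(
        geometry=geom, arrival=arrival, origin=origin, start=start, end=end
    )


def write_report(report: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def write_run_record(config: dict, path) -> None:
    """Persist the resolved configuration of a run for exact reproduction."""
    from . import __version__

    record = {"package_version": __version__, "config": config}
    write_report(record, path)
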