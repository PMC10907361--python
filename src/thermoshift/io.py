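"""Readers and writers for the pipeline's tabular and raster formats.

Community, occurrence and trait tables are plain CSV read through pandas;
temperature grids use a self-describing plain-text dialect (header lines
followed by row-major values, north to south) so fixtures stay diffable.
All readers validate against the domain invariants and report rejected
rows instead of failing wholesale.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
import pandas as pd

from .types import TemperatureGrid

logger = logging.getLogger("thermoshift")

COMMUNITY_COLUMNS = ["site_id", "study_id", "taxon_group", "realm",
                     "latitude", "longitude", "year", "sample_id",
                     "species", "abundance"]
OCCURRENCE_COLUMNS = ["species", "latitude", "longitude", "year", "basis"]


class FormatError(ValueError):
    """Raised when a file's declared structure disagrees with its content."""


class ConfigError(ValueError):
    """Raised for unusable configuration (missing columns, bad thresholds)."""


def _valid_coords(lat: pd.Series, lon: pd.Series) -> pd.Series:
    lat = pd.to_numeric(lat, errors="coerce")
    lon = pd.to_numeric(lon, errors="coerce")
    return (lat.between(-90, 90) & lon.between(-180, 180)
            & np.isfinite(lat) & np.isfinite(lon))


def read_community_table(path, dialect: Optional[dict] = None
                         ) -> tuple[pd.DataFrame, dict]:
    """Read a long-format community time-series CSV.

    Parameters
    ----------
    path : str or Path
    dialect : dict, optional
        Mapping from the file's column names to the canonical names in
        ``COMMUNITY_COLUMNS``.

    Returns
    -------
    (DataFrame, report) where the report counts read, rejected and
    collapsed-duplicate rows. Duplicate (site_id, year, sample_id,
    species) rows are collapsed with abundances summed.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "study_id": str,
                                  "sample_id": str, "species": str})
    if dialect:
        df = df.rename(columns=dialect)
    mandatory = [c for c in COMMUNITY_COLUMNS if c != "abundance"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ConfigError(f"community table missing columns: {missing}")
    if "abundance" not in df.columns:
        df["abundance"] = np.nan
    report = {"n_read": len(df), "n_rejected": 0, "n_collapsed": 0,
              "rejections": []}
    if len(df) == 0:
        return df[COMMUNITY_COLUMNS], report

    ok = _valid_coords(df["latitude"], df["longitude"])
    ok &= df["species"].notna() & (df["species"].astype(str).str.strip() != "")
    ok &= pd.to_numeric(df["year"], errors="coerce").notna()
    for idx in df.index[~ok]:
        report["rejections"].append((int(idx), "invalid coordinate/year/species"))
    report["n_rejected"] = int((~ok).sum())
    df = df[ok].copy()
    df["latitude"] = pd.to_numeric(df["latitude"])
    df["longitude"] = pd.to_numeric(df["longitude"])
    df["year"] = pd.to_numeric(df["year"]).astype(int)
    df["abundance"] = pd.to_numeric(df["abundance"], errors="coerce")

    key = ["site_id", "year", "sample_id", "species"]
    n_before = len(df)
    agg = {c: "first" for c in df.columns if c not in key + ["abundance"]}
    agg["abundance"] = lambda s: s.sum() if s.notna().any() else np.nan
    df = df.groupby(key, as_index=False, sort=False).agg(agg)
    report["n_collapsed"] = n_before - len(df)
    if report["n_collapsed"]:
        logger.info("collapsed %d duplicate community rows", report["n_collapsed"])

    # realm must be consistent within a site
    bad_realm = df.groupby("site_id")["realm"].nunique()
    bad = bad_realm[bad_realm > 1]
    if len(bad):
        raise FormatError(f"sites with inconsistent realm: {list(bad.index)}")
    return df[COMMUNITY_COLUMNS], report


def write_community_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_occurrence_table(path, dialect: Optional[dict] = None
                          ) -> tuple[pd.DataFrame, dict]:
    """Read an occurrence CSV (species, latitude, longitude, year?, basis?).

    Rows failing the coordinate or species invariants are rejected and
    counted; cleaning proper (duplicates, (0,0) points, preserved
    specimens) is :func:`thermoshift.affinity.clean_occurrences`.
    """
    df = pd.read_csv(path, dtype={"species": str, "basis": str})
    if dialect:
        df = df.rename(columns=dialect)
    if "species" not in df.columns or "latitude" not in df.columns \
            or "longitude" not in df.columns:
        raise ConfigError("occurrence table needs species, latitude, longitude")
    for opt in ("year", "basis"):
        if opt not in df.columns:
            df[opt] = np.nan
    report = {"n_read": len(df), "n_rejected": 0}
    ok = _valid_coords(df["latitude"], df["longitude"])
    ok &= df["species"].notna() & (df["species"].astype(str).str.strip() != "")
    report["n_rejected"] = int((~ok).sum())
    df = df[ok].copy()
    df["latitude"] = pd.to_numeric(df["latitude"])
    df["longitude"] = pd.to_numeric(df["longitude"])
    df["year"] = pd.to_numeric(df["year"], errors="coerce")
    return df[OCCURRENCE_COLUMNS], report


def write_occurrence_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_trait_table(path) -> pd.DataFrame:
    """Read a species trait CSV with columns species, body_size_m."""
    df = pd.read_csv(path, dtype={"species": str})
    if "species" not in df.columns or "body_size_m" not in df.columns:
        raise ConfigError("trait table needs species, body_size_m")
    return df[["species", "body_size_m"]]


# ---------------------------------------------------------------- grid I/O

_NODATA = "NA"


def _layer_key_to_header(key) -> str:
    if isinstance(key, tuple):
        return f"layer {key[0]} {key[1]}"
    return f"layer {key}"


def write_temperature_grid(grid: TemperatureGrid, path) -> None:
    """Write a grid in the plain-text dialect (full decimal precision)."""
    with open(path, "w") as fh:
        fh.write(f"origin_lat {grid.origin_lat!r}\n")
        fh.write(f"origin_lon {grid.origin_lon!r}\n")
        fh.write(f"cell_size {grid.cell_size!r}\n")
        fh.write(f"n_rows {grid.n_rows}\n")
        fh.write(f"n_cols {grid.n_cols}\n")
        for key, arr in grid.layers.items():
            fh.write(_layer_key_to_header(key) + "\n")
            for row in arr:
                fh.write(" ".join(_NODATA if math.isnan(v) else repr(float(v))
                                  for v in row) + "\n")


def read_temperature_grid(path) -> TemperatureGrid:
    """Read a grid from the plain-text dialect; NaN marks no-data cells."""
    header: dict[str, float] = {}
    layers: dict = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines) and not lines[i].startswith("layer"):
        key, _, value = lines[i].partition(" ")
        header[key] = float(value)
        i += 1
    for req in ("origin_lat", "origin_lon", "cell_size", "n_rows", "n_cols"):
        if req not in header:
            raise FormatError(f"grid header missing {req}")
    n_rows, n_cols = int(header["n_rows"]), int(header["n_cols"])
    while i < len(lines):
        parts = lines[i].split()
        if parts[0] != "layer":
            raise FormatError(f"expected a layer header at line {i + 1}")
        key = parts[1] if len(parts) == 2 else (parts[1], int(parts[2]))
        i += 1
        values: list[float] = []
        while i < len(lines) and not lines[i].startswith("layer"):
            values.extend(float("nan") if tok == _NODATA else float(tok)
                          for tok in lines[i].split())
            i += 1
        if len(values) != n_rows * n_cols:
            raise FormatError(
                f"layer {key!r}: declared {n_rows}x{n_cols} = "
                f"{n_rows * n_cols} values, found {len(values)}")
        layers[key] = np.array(values).reshape(n_rows, n_cols)
    return TemperatureGrid(header["origin_lat"], header["origin_lon"],
                           header["cell_size"], n_rows, n_cols, layers)


def locate_cell(grid: TemperatureGrid, latitude: float, longitude: float
                ) -> Optional[tuple[int, int]]:
    """Map a point to its (row, col) cell, or None when outside the extent.

    Cells are half-open: a point on a shared edge belongs to the cell to
    the south/east, while the grid's northern and western edges are
    included so the closed extent is fully covered.
    """
    if not (np.isfinite(latitude) and np.isfinite(longitude)):
        return None
    row = math.floor((grid.origin_lat - latitude) / grid.cell_size)
    col = math.floor((longitude - grid.origin_lon) / grid.cell_size)
    if latitude == grid.origin_lat:
        row = 0
    if longitude == grid.origin_lon:
        col = 0
    if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
        return (row, col)
    return None


def locate_cells(grid: TemperatureGrid, latitudes, longitudes
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`locate_cell`: (rows, cols, in_extent mask)."""
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    row = np.floor((grid.origin_lat - lat) / grid.cell_size).astype(int)
    col = np.floor((lon - grid.origin_lon) / grid.cell_size).astype(int)
    row = np.where(lat == grid.origin_lat, 0, row)
    col = np.where(lon == grid.origin_lon, 0, col)
    ok = (np.isfinite(lat) & np.isfinite(lon)
          & (row >= 0) & (row < grid.n_rows)
          & (col >= 0) & (col < grid.n_cols))
    return row, col, ok


def setup_logging(verbosity: int = 0) -> None:
    """Configure the package logger to stderr; -1 quiet, 0 normal, 1 verbose."""
    level = {-1: logging.WARNING, 0: logging.INFO, 1: logging.DEBUG}.get(
        verbosity, logging.INFO)
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
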