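"""Raster I/O and land/sea/water classification.

The exchange format is the ESRI ASCII grid (``.asc``): a six-line header
(``ncols``, ``nrows``, ``xllcorner``, ``yllcorner``, ``cellsize``,
``NODATA_value``) followed by row-major, space-separated values with the
northernmost row first.  All grids in this package are non-georeferenced
0-based (row, col) arrays with row 0 the northernmost row; the only spatial
metadata that matters downstream is the cell size in kilometres.

Cells below sea level (altitude < 0 m) are sea; cells flagged in the
freshwater mask are freshwater sources and are never populable; nodata
cells behave as sea for connectivity and score zero for every desirability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "LAND",
    "SEA",
    "FRESHWATER",
    "ElevationGrid",
    "GridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "classify_cells",
    "distance_to_water",
]

# land/sea/freshwater labels for classification rasters
LAND = 0
SEA = 1
FRESHWATER = 2

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


class GridFormatError(ValueError):
    """Raised for a malformed ESRI ASCII grid file."""


@dataclass
class ElevationGrid:
    """Rectangular altitude field in metres; negative altitude is sea.

    Parameters
    ----------
    altitude
        2-D float array of altitudes A(i, j) in metres above sea level.
    cell_size_km
        Edge length of a (square) cell in kilometres.
    nodata
        Boolean mask of cells carrying the file's nodata sentinel; such
        cells are excluded from all scoring and behave as sea.
    """

    altitude: np.ndarray
    cell_size_km: float = 1.0
    nodata: np.ndarray | None = None
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.altitude = np.asarray(self.altitude, dtype=float)
        if self.altitude.ndim != 2 or self.altitude.size < 1:
            raise ValueError("altitude must be a non-empty 2-D array")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")
        if self.nodata is None:
            self.nodata = np.zeros(self.altitude.shape, dtype=bool)
        else:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.altitude.shape:
                raise ValueError("nodata mask shape must match altitude")

    @property
    def n_rows(self) -> int:
        return self.altitude.shape[0]

    @property
    def n_cols(self) -> int:
        return self.altitude.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.altitude.shape


def _parse_header(lines: list[str]) -> dict[str, float]:
    header: dict[str, float] = {}
    for line in lines:
        parts = line.split()
        if len(parts) != 2:
            raise GridFormatError(f"malformed header line: {line!r}")
        key = parts[0].lower()
        if key not in _HEADER_KEYS:
            raise GridFormatError(f"unknown header key: {parts[0]!r}")
        try:
            header[key] = float(parts[1])
        except ValueError as exc:
            raise GridFormatError(f"non-numeric header value: {line!r}") from exc
    return header


def read_ascii_grid(path: str | Path, cell_size_unit: str = "km") -> ElevationGrid:
    """Read an ESRI ASCII grid into an :class:`ElevationGrid`.

    ``cell_size_unit`` declares the unit of the file's ``cellsize`` field:
    ``"km"`` (default, taken as-is) or ``"m"`` (converted to kilometres).
    """
    path = Path(path)
    with open(path) as fh:
        raw = [ln for ln in fh.read().splitlines() if ln.strip()]
    if len(raw) < 6:
        raise GridFormatError(f"{path}: fewer than 6 header lines")

    # header is every leading line whose first token is non-numeric
    n_header = 0
    for ln in raw:
        tok = ln.split()[0]
        try:
            float(tok)
            break
        except ValueError:
            n_header += 1
    if n_header < 5:
        raise GridFormatError(f"{path}: incomplete header ({n_header} lines)")
    header = _parse_header(raw[:n_header])
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridFormatError(f"{path}: missing header key {key!r}")

    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata_value = header.get("nodata_value", -9999.0)

    rows: list[list[float]] = []
    for ln in raw[n_header:]:
        try:
            rows.append([float(tok) for tok in ln.split()])
        except ValueError as exc:
            raise GridFormatError(f"{path}: non-numeric data value") from exc
    flat = [v for row in rows for v in row]
    if len(flat) != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} values, found {len(flat)}"
        )
    # reject ragged rows when the file is laid out one grid-row per line
    if len(rows) == nrows and any(len(r) != ncols for r in rows):
        raise GridFormatError(f"{path}: ragged rows")

    values = np.array(flat, dtype=float).reshape(nrows, ncols)
    nodata = values == nodata_value
    cell = header["cellsize"]
    if cell_size_unit == "m":
        cell /= 1000.0
    elif cell_size_unit != "km":
        raise ValueError("cell_size_unit must be 'km' or 'm'")
    return ElevationGrid(
        altitude=values,
        cell_size_km=cell,
        nodata=nodata,
        nodata_value=nodata_value,
    )


def write_ascii_grid(
    values: np.ndarray | ElevationGrid,
    path: str | Path,
    cell_size_km: float = 1.0,
    nodata: np.ndarray | None = None,
    nodata_value: float = -9999.0,
) -> Path:
    """Write a per-cell field (or an :class:`ElevationGrid`) as ESRI ASCII.

    Non-finite values that are not covered by the nodata mask are an error;
    the round trip through :func:`read_ascii_grid` reproduces values to
    1e-6 relative and the nodata mask exactly.
    """
    if isinstance(values, ElevationGrid):
        grid = values
        values = grid.altitude
        cell_size_km = grid.cell_size_km
        nodata = grid.nodata
        nodata_value = grid.nodata_value
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be 2-D")
    if nodata is None:
        nodata = np.zeros(values.shape, dtype=bool)
    if not np.all(np.isfinite(values[~nodata])):
        raise ValueError("non-finite values outside the nodata mask")

    out = values.copy()
    out[nodata] = nodata_value
    path = Path(path)
    nrows, ncols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size_km!r}\n")
        fh.write(f"NODATA_value {nodata_value!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    return path


def classify_cells(elev: ElevationGrid, water: np.ndarray) -> np.ndarray:
    """Partition cells into land / sea / freshwater labels.

    A cell is freshwater wherever the water mask is set (mask priority),
    sea where altitude < 0 or the cell is nodata, land otherwise.

    Returns an integer array with values :data:`LAND`, :data:`SEA`,
    :data:`FRESHWATER`.
    """
    water = np.asarray(water, dtype=bool)
    if water.shape != elev.shape:
        raise ValueError(
            f"water mask shape {water.shape} != elevation shape {elev.shape}"
        )
    cls = np.full(elev.shape, LAND, dtype=np.int8)
    cls[(elev.altitude < 0) | elev.nodata] = SEA
    cls[water] = FRESHWATER
    return cls


def classification_counts(cls: np.ndarray) -> dict[str, int]:
    """Counts of each label in a classification raster."""
    return {
        "land": int(np.sum(cls == LAND)),
        "sea": int(np.sum(cls == SEA)),
        "freshwater": int(np.sum(cls == FRESHWATER)),
    }


def distance_to_water(cls: np.ndarray, cell_size_km: float = 1.0) -> np.ndarray:
    """Euclidean distance (km) from every cell centre to the nearest
    freshwater cell centre.

    Computed with an exact Euclidean distance transform; zero on freshwater
    cells.  A grid without any freshwater cell yields an all-infinite field
    with a warning (all water desirabilities will then be zero).
    """
    water = cls == FRESHWATER
    if not water.any():
        warnings.warn("no freshwater cells: distance field is infinite")
        return np.full(cls.shape, np.inf)
    dist = ndimage.distance_transform_edt(~water, sampling=cell_size_km)
    return np.asarray(dist, dtype=float)
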