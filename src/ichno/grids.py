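"""Shared grid definition and plain-text raster I/O.

All rasters in one pipeline run share a single :class:`GridSpec`
(square cells, row-major storage, row 0 at the top).  Rasters are
persisted as ESRI ASCII grids (``.asc``) — a plain-text interchange
format readable by any GIS — with the opaque CRS token in a sidecar
``.prj`` file.  In memory, nodata cells are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_NODATA = -9999.0


class GridError(ValueError):
    """Invalid grid definition or grid mismatch between rasters."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid.

    ``origin_x``/``origin_y`` are the map coordinates of the top-left
    corner of the top-left cell; y decreases down rows.  ``crs_token``
    is carried through unmodified (inputs must already share a CRS).
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_token: str = ""
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise GridError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError(
                f"grid must have at least one row and column, got "
                f"{self.n_rows}x{self.n_cols}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) arrays of cell-center coordinates, each of ``shape``."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_polygon_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of one cell."""
        minx = self.origin_x + col * self.cell_size
        maxy = self.origin_y - row * self.cell_size
        return (minx, maxy - self.cell_size, minx + self.cell_size, maxy)


@dataclass
class Raster:
    """A single-band raster bound to a :class:`GridSpec`.

    ``values`` is float64 with NaN marking nodata.  ``kind`` labels the
    band semantics: a factor symbol (L/H/E/S/W/K), ``unit`` for a unit
    index raster, ``elevation``, a suitability profile (A/B/C), or
    ``mask``.
    """

    grid: GridSpec
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"raster values shape {self.values.shape} does not match grid "
                f"{self.grid.shape}"
            )

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Raster":
        return Raster(self.grid, values, self.kind if kind is None else kind)


def ensure_shared_grid(rasters: dict[str, Raster]) -> GridSpec:
    """Assert all rasters share one grid; name the offender otherwise."""
    items = list(rasters.items())
    if not items:
        raise GridError("no rasters supplied")
    ref_name, ref = items[0]
    for name, raster in items[1:]:
        if raster.grid != ref.grid:
            raise GridError(
                f"raster {name!r} is on a different grid than {ref_name!r}"
            )
    return ref.grid


def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write an ESRI ASCII grid (+ ``.prj`` sidecar if a CRS token is set)."""
    path = Path(path)
    grid = raster.grid
    values = np.where(raster.nodata_mask, grid.nodata_value, raster.values)
    yll = grid.origin_y - grid.n_rows * grid.cell_size
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata_value!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt="%.10g")
    if grid.crs_token:
        path.with_suffix(".prj").write_text(grid.crs_token + "\n")
    return path


def read_ascii_grid(path: str | Path, kind: str = "") -> Raster:
    """Read an ESRI ASCII grid; a ``.prj`` sidecar supplies the CRS token."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"):
                header[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    prj = path.with_suffix(".prj")
    crs_token = prj.read_text().strip() if prj.exists() else ""
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        n_rows=n_rows,
        n_cols=n_cols,
        crs_token=crs_token,
        nodata_value=nodata,
    )
    values = np.where(values == nodata, np.nan, values)
    return Raster(grid, values, kind)
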