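"""Vector-to-raster factor scoring (workflow: score quantification).

Converts the bedrock and surficial geology maps and the elevation
model into per-factor score rasters on one shared grid:

* :func:`rasterize_units` burns polygon unit names onto the grid by
  cell-center containment (boundary counts as inside; where polygons
  overlap the later feature wins, mirroring map drawing order);
* :func:`score_raster` looks up L/H/E/S scores per cell;
* :func:`cover_score_raster` assigns K, with uncovered bedrock = 4;
* :func:`water_score_raster` thresholds the DEM at the shoreline
  elevation (strictly below = high score).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from ichno.catalogue import ScoreCatalogue, WaterScoreRule, lookup_score
from ichno.grids import GridSpec, Raster


class GeometryError(ValueError):
    """Invalid feature geometry, reported with its feature index."""


@dataclass
class GeologyMap:
    """An ordered list of (polygon, unit name) features of one kind.

    ``layer_kind`` is ``bedrock`` or ``surficial``; feature order is
    meaningful (later features win where polygons overlap).
    """

    layer_kind: str
    features: list[tuple[BaseGeometry, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.layer_kind not in ("bedrock", "surficial"):
            raise ValueError(
                f"layer_kind must be 'bedrock' or 'surficial', got "
                f"{self.layer_kind!r}"
            )

    def validate_against(self, catalogue: ScoreCatalogue) -> None:
        """Every unit name must resolve in the catalogue with matching category."""
        for i, (_, unit_name) in enumerate(self.features):
            entry = catalogue.unit(unit_name)  # raises for unknown units
            if entry.category != self.layer_kind:
                raise ValueError(
                    f"feature {i}: unit {unit_name!r} is {entry.category}, "
                    f"but this is a {self.layer_kind} map"
                )

    def unit_names(self) -> list[str]:
        return sorted({name for _, name in self.features})

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"unit": unit_name},
                    "geometry": mapping(geom),
                }
                for geom, unit_name in self.features
            ],
        }

    def write_geojson(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_geojson()))
        return path

    @classmethod
    def from_geojson(cls, path: str | Path, layer_kind: str) -> "GeologyMap":
        doc = json.loads(Path(path).read_text())
        features = [
            (shape(feat["geometry"]), str(feat["properties"]["unit"]))
            for feat in doc["features"]
        ]
        return cls(layer_kind, features)


@dataclass
class ElevationModel:
    """A DEM on the shared grid; elevations in metres, NaN = nodata."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"DEM shape {self.values.shape} does not match grid "
                f"{self.grid.shape}"
            )
        finite = np.isfinite(self.values) | np.isnan(self.values)
        if not finite.all():
            raise ValueError("DEM must contain finite elevations or NaN nodata")

    def as_raster(self) -> Raster:
        return Raster(self.grid, self.values, kind="elevation")


@dataclass
class UnitRaster:
    """Per-cell unit names via an index into ``unit_names`` (-1 = nodata)."""

    grid: GridSpec
    indices: np.ndarray
    unit_names: Sequence[str]

    def name_at(self, row: int, col: int) -> str | None:
        idx = int(self.indices[row, col])
        return None if idx < 0 else self.unit_names[idx]


def rasterize_units(geology: GeologyMap, grid: GridSpec) -> UnitRaster:
    """Burn polygon unit names onto the grid by cell-center containment.

    A cell takes the unit of the polygon covering its center (boundary
    inclusive); with overlapping polygons the later feature wins.
    Uncovered cells are nodata.
    """
    xs, ys = grid.cell_centers()
    indices = np.full(grid.shape, -1, dtype=np.int32)
    names: list[str] = []
    name_index: dict[str, int] = {}
    for i, (geom, unit_name) in enumerate(geology.features):
        if geom is None or geom.is_empty:
            raise GeometryError(f"feature {i} ({unit_name!r}): empty geometry")
        if not geom.is_valid:
            raise GeometryError(f"feature {i} ({unit_name!r}): invalid geometry")
        if unit_name not in name_index:
            name_index[unit_name] = len(names)
            names.append(unit_name)
        # covers() counts boundary points as inside, unlike contains().
        hit = shapely.intersects_xy(geom, xs, ys)
        indices[hit] = name_index[unit_name]
    return UnitRaster(grid, indices, names)


def score_raster(
    unit_raster: UnitRaster, catalogue: ScoreCatalogue, factor: str
) -> Raster:
    """Per-cell lookup of one bedrock factor (L, H, E or S).

    Nodata cells stay nodata.  A cell whose unit lacks the factor (a
    surficial name on a bedrock map) raises a lookup error.
    """
    scores = np.array(
        [lookup_score(catalogue, name, factor) for name in unit_raster.unit_names],
        dtype=float,
    )
    values = np.full(unit_raster.grid.shape, np.nan)
    covered = unit_raster.indices >= 0
    values[covered] = scores[unit_raster.indices[covered]]
    return Raster(unit_raster.grid, values, kind=factor)


def cover_score_raster(
    surficial_unit_raster: UnitRaster | None,
    catalogue: ScoreCatalogue,
    grid: GridSpec,
) -> Raster:
    """Surficial-cover factor K: mapped deposits get their unit's K,
    everywhere else uncovered bedrock scores the maximum 4."""
    values = np.full(grid.shape, 4.0)
    if surficial_unit_raster is not None:
        if surficial_unit_raster.grid != grid:
            raise ValueError("surficial raster is not on the shared grid")
        scores = np.array(
            [
                lookup_score(catalogue, name, "K")
                for name in surficial_unit_raster.unit_names
            ],
            dtype=float,
        )
        covered = surficial_unit_raster.indices >= 0
        values[covered] = scores[surficial_unit_raster.indices[covered]]
    return Raster(grid, values, kind="K")


def water_score_raster(dem: ElevationModel, rule: WaterScoreRule) -> Raster:
    """Water-table factor W from the DEM.

    Strictly below the shoreline elevation scores ``rule.high_score``;
    at or above scores ``rule.low_score``; nodata propagates.
    """
    values = np.where(
        dem.values < rule.shoreline_elevation,
        float(rule.high_score),
        float(rule.low_score),
    )
    values[np.isnan(dem.values)] = np.nan
    return Raster(dem.grid, values, kind="W")


def factor_rasters(
    bedrock: GeologyMap,
    surficial: GeologyMap | None,
    dem: ElevationModel,
    catalogue: ScoreCatalogue,
    rule: WaterScoreRule,
) -> dict[str, Raster]:
    """All six factor rasters (L, H, E, S, W, K) on the DEM's grid."""
    grid = dem.grid
    bedrock.validate_against(catalogue)
    bedrock_units = rasterize_units(bedrock, grid)
    rasters = {
        factor: score_raster(bedrock_units, catalogue, factor)
        for factor in ("L", "H", "E", "S")
    }
    surf_units = None
    if surficial is not None and surficial.features:
        surficial.validate_against(catalogue)
        surf_units = rasterize_units(surficial, grid)
    rasters["K"] = cover_score_raster(surf_units, catalogue, grid)
    rasters["W"] = water_score_raster(dem, rule)
    return rasters
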