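"""Threshold classification and site extraction (the survey strategy).

A suitability raster is classified at a threshold (default 3,
inclusive: the top quarter of the 1-4 scale).  Contiguous
above-threshold regions are extracted per profile, regions from
different profiles that share cells are merged into sites, and sites
are ranked to produce a survey strategy: for each site, the
ichnofossil types likely present (bioturbation for profile A,
bioerosion for B, biostratification for C) and the observation mode
best suited to them.  Bioerosion traces can be microscopic borings
beyond camera resolution, so any site recommending bioerosion calls
for sampling; bioturbation and biostratification structures are
resolvable by imaging alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from ichno.grids import GridSpec, Raster, ensure_shared_grid

#: Ichnofossil type predicted by each profile.
PROFILE_TYPES = {
    "A": "bioturbation",
    "B": "bioerosion",
    "C": "biostratification",
}

DEFAULT_THRESHOLD = 3.0
DEFAULT_MIN_CELLS = 4
DEFAULT_TOP_N = 10

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    8: np.ones((3, 3), dtype=int),
}


def classify(suitability: Raster, threshold: float = DEFAULT_THRESHOLD) -> Raster:
    """Boolean mask of cells at or above ``threshold`` (inclusive).

    Nodata cells stay nodata (NaN); true cells are 1.0, false 0.0.
    """
    values = np.where(suitability.values >= threshold, 1.0, 0.0)
    values[suitability.nodata_mask] = np.nan
    return Raster(suitability.grid, values, kind=f"mask_{suitability.kind}")


@dataclass(frozen=True)
class Region:
    """One connected component of true mask cells."""

    label: int
    cells: tuple[tuple[int, int], ...]  # (row, col), row-major sorted

    @property
    def cell_count(self) -> int:
        return len(self.cells)


def extract_regions(
    mask: Raster, connectivity: int = 8, min_cells: int = DEFAULT_MIN_CELLS
) -> list[Region]:
    """Connected components of true cells, smallest regions discarded.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or
    corner-adjacent).  Labels are assigned in row-major order of each
    region's first cell, starting at 1.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    truth = np.nan_to_num(mask.values, nan=0.0) > 0.5
    labelled, n = ndimage.label(truth, structure=_STRUCTURES[connectivity])
    regions = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labelled == lab)
        if rows.size < min_cells:
            continue
        cells = tuple(sorted(zip(rows.tolist(), cols.tolist())))
        regions.append(cells)
    # Deterministic labelling by row-major position of each region's
    # first cell (scipy's label order is an implementation detail).
    regions.sort(key=lambda cells: cells[0])
    return [Region(i + 1, cells) for i, cells in enumerate(regions)]


@dataclass
class Site:
    """A merged high-suitability site with ranking statistics."""

    site_id: int
    profile_memberships: tuple[str, ...]
    cells: tuple[tuple[int, int], ...]
    cell_count: int
    area: float  # m^2
    mean_score: dict[str, float]  # per member profile
    max_score: dict[str, float]
    centroid: tuple[float, float]  # map coordinates
    recommended_types: tuple[str, ...]
    detection_mode: str
    profile_cells: dict[str, tuple[tuple[int, int], ...]] = field(repr=False, default_factory=dict)

    def to_record(self) -> dict:
        return {
            "site_id": self.site_id,
            "profiles": "".join(self.profile_memberships),
            "cell_count": self.cell_count,
            "area_m2": self.area,
            **{f"mean_{p}": round(self.mean_score[p], 6) for p in self.profile_memberships},
            **{f"max_{p}": round(self.max_score[p], 6) for p in self.profile_memberships},
            "centroid_x": self.centroid[0],
            "centroid_y": self.centroid[1],
            "recommended_types": "+".join(self.recommended_types),
            "detection_mode": self.detection_mode,
        }


def _detection_mode(types: Sequence[str]) -> str:
    needs_sampling = "bioerosion" in types
    needs_imaging = any(t != "bioerosion" for t in types)
    if needs_sampling and needs_imaging:
        return "imaging+sampling"
    return "sampling" if needs_sampling else "imaging"


def build_strategy(
    regions_per_profile: Mapping[str, Sequence[Region]],
    suitability: Mapping[str, Raster],
    top_n: int = DEFAULT_TOP_N,
) -> list[Site]:
    """Merge per-profile regions into ranked sites with recommendations.

    Regions from different profiles that share at least one cell are
    merged into one site.  Sites are ranked by the maximum of their
    per-profile mean suitability scores (descending), ties broken by
    larger area, then by earlier row-major position; at most ``top_n``
    sites are returned, re-numbered 1..n in rank order.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    grid = ensure_shared_grid(dict(suitability))

    # Union-find over (profile, region) nodes keyed by shared cells.
    nodes: list[tuple[str, Region]] = [
        (profile, region)
        for profile in sorted(regions_per_profile)
        for region in regions_per_profile[profile]
    ]
    parent = list(range(len(nodes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    cell_owner: dict[tuple[int, int], int] = {}
    for idx, (_, region) in enumerate(nodes):
        for cell in region.cells:
            if cell in cell_owner:
                union(idx, cell_owner[cell])
            else:
                cell_owner[cell] = idx

    groups: dict[int, list[int]] = {}
    for idx in range(len(nodes)):
        groups.setdefault(find(idx), []).append(idx)

    sites: list[Site] = []
    for members in groups.values():
        profiles = sorted({nodes[i][0] for i in members})
        all_cells = tuple(
            sorted({cell for i in members for cell in nodes[i][1].cells})
        )
        profile_cells: dict[str, tuple[tuple[int, int], ...]] = {}
        mean_score: dict[str, float] = {}
        max_score: dict[str, float] = {}
        for profile in profiles:
            cells = tuple(
                sorted(
                    {
                        cell
                        for i in members
                        if nodes[i][0] == profile
                        for cell in nodes[i][1].cells
                    }
                )
            )
            profile_cells[profile] = cells
            rows = np.array([c[0] for c in cells])
            cols = np.array([c[1] for c in cells])
            scores = suitability[profile].values[rows, cols]
            mean_score[profile] = float(np.nanmean(scores))
            max_score[profile] = float(np.nanmax(scores))
        rows = np.array([c[0] for c in all_cells])
        cols = np.array([c[1] for c in all_cells])
        cx = grid.origin_x + (cols.mean() + 0.5) * grid.cell_size
        cy = grid.origin_y - (rows.mean() + 0.5) * grid.cell_size
        types = tuple(PROFILE_TYPES[p] for p in profiles)
        sites.append(
            Site(
                site_id=0,  # assigned after ranking
                profile_memberships=tuple(profiles),
                cells=all_cells,
                cell_count=len(all_cells),
                area=len(all_cells) * grid.cell_size**2,
                mean_score=mean_score,
                max_score=max_score,
                centroid=(float(cx), float(cy)),
                recommended_types=types,
                detection_mode=_detection_mode(types),
                profile_cells=profile_cells,
            )
        )

    sites.sort(key=lambda s: (-max(s.mean_score.values()), -s.area, s.cells[0]))
    sites = sites[:top_n]
    for rank, site in enumerate(sites, start=1):
        site.site_id = rank
    return sites


def sites_to_geojson(sites: Sequence[Site], grid: GridSpec) -> dict:
    """Dissolve each site's cells into polygons; properties carry the record."""
    features = []
    for site in sites:
        cells = [box(*grid.cell_polygon_bounds(r, c)) for r, c in site.cells]
        geom = unary_union(cells)
        features.append(
            {
                "type": "Feature",
                "properties": site.to_record(),
                "geometry": mapping(geom),
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_sites_geojson(sites: Sequence[Site], grid: GridSpec, path) -> None:
    from pathlib import Path

    Path(path).write_text(json.dumps(sites_to_geojson(sites, grid)))


def strategy_table(sites: Sequence[Site]):
    """Strategy table as a pandas DataFrame (one row per site)."""
    import pandas as pd

    return pd.DataFrame([site.to_record() for site in sites])
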