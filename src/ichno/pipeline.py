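"""End-to-end orchestration: inputs -> factor rasters -> suitability
maps -> threshold masks -> ranked sites -> manifest.

All outputs are plain text: ESRI ASCII grids for rasters, GeoJSON for
sites, CSV for the strategy table, JSON for the manifest.  A run is
deterministic: identical inputs and config give byte-identical
artifacts, which the manifest records as SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

from ichno import catalogue as cat
from ichno.factor_layers import ElevationModel, GeologyMap, factor_rasters
from ichno.grids import Raster, read_ascii_grid, write_ascii_grid
from ichno.overlay import run_all_profiles
from ichno.sites import (
    DEFAULT_MIN_CELLS,
    DEFAULT_THRESHOLD,
    DEFAULT_TOP_N,
    build_strategy,
    classify,
    extract_regions,
    strategy_table,
    write_sites_geojson,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    bedrock_path: str
    dem_path: str
    out_dir: str
    surficial_path: str | None = None
    config_path: str | None = None  # YAML/JSON catalogue/weights overrides
    weight_preset: str = "equations"
    threshold: float = DEFAULT_THRESHOLD
    connectivity: int = 8
    min_cells: int = DEFAULT_MIN_CELLS
    top_n: int = DEFAULT_TOP_N

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run scoring, overlay, classification and site extraction.

    Returns the manifest (also written to ``manifest.json``).  Any
    stage error removes partial outputs and raises
    :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        manifest = _run(config, out_dir, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return manifest


def _run(config: RunConfig, out_dir: Path, written: list[Path]) -> dict:
    score_catalogue = _stage("catalogue")(cat.load_catalogue)(config.config_path)
    profiles = _stage("weights")(cat.load_weight_profiles)(
        config.config_path, source=config.weight_preset
    )
    water_rule = _stage("water-rule")(cat.load_water_rule)(config.config_path)

    @_stage("read-inputs")
    def read_inputs():
        bedrock = GeologyMap.from_geojson(config.bedrock_path, "bedrock")
        surficial = (
            GeologyMap.from_geojson(config.surficial_path, "surficial")
            if config.surficial_path
            else None
        )
        dem_raster = read_ascii_grid(config.dem_path, kind="elevation")
        dem = ElevationModel(dem_raster.grid, dem_raster.values)
        return bedrock, surficial, dem

    bedrock, surficial, dem = read_inputs()

    @_stage("water-score")
    def check_dem():
        if dem is None:  # pragma: no cover - guarded by read-inputs
            raise ValueError("no DEM available for the water-score layer")

    check_dem()

    factors = _stage("factor-scoring")(factor_rasters)(
        bedrock, surficial, dem, score_catalogue, water_rule
    )
    logger.info(
        "factor rasters: %d cells, %d nodata in L",
        factors["L"].values.size,
        int(factors["L"].nodata_mask.sum()),
    )
    suitability = _stage("overlay")(run_all_profiles)(factors, profiles)

    masks = {
        name: _stage("classify")(classify)(raster, config.threshold)
        for name, raster in suitability.items()
    }
    regions = {
        name: _stage("region-extraction")(extract_regions)(
            mask, connectivity=config.connectivity, min_cells=config.min_cells
        )
        for name, mask in masks.items()
    }
    logger.info(
        "regions found: %s", {name: len(r) for name, r in regions.items()}
    )
    sites = _stage("strategy")(build_strategy)(
        regions, suitability, top_n=config.top_n
    )

    artifacts: dict[str, str] = {}

    def emit_raster(name: str, raster: Raster) -> None:
        path = out_dir / f"{name}.asc"
        write_ascii_grid(raster, path)
        written.append(path)
        artifacts[path.name] = _sha256(path)

    for factor, raster in factors.items():
        emit_raster(f"factor_{factor}", raster)
    for profile, raster in suitability.items():
        emit_raster(f"suitability_{profile}", raster)
    for profile, mask in masks.items():
        emit_raster(f"mask_{profile}", mask)

    sites_path = out_dir / "sites.geojson"
    write_sites_geojson(sites, dem.grid, sites_path)
    written.append(sites_path)
    artifacts[sites_path.name] = _sha256(sites_path)

    table_path = out_dir / "strategy.csv"
    strategy_table(sites).to_csv(table_path, index=False)
    written.append(table_path)
    artifacts[table_path.name] = _sha256(table_path)

    manifest = {
        "config": asdict(config),
        "config_sha256": config.digest(),
        "weight_preset": config.weight_preset,
        "n_sites": len(sites),
        "artifacts": artifacts,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(manifest_path)
    return manifest


def report_from_rasters(
    suitability: Mapping[str, Raster],
    threshold: float = DEFAULT_THRESHOLD,
    connectivity: int = 8,
    min_cells: int = DEFAULT_MIN_CELLS,
    top_n: int = DEFAULT_TOP_N,
) -> tuple[list, dict[str, float]]:
    """Strategy and per-profile above-threshold areas from existing
    suitability rasters (e.g. externally published predictive layers).

    Returns (sites, {profile: area in m^2 at or above threshold}).
    """
    masks = {name: classify(r, threshold) for name, r in suitability.items()}
    areas = {
        name: float((mask.values == 1.0).sum()) * mask.grid.cell_size**2
        for name, mask in masks.items()
    }
    regions = {
        name: extract_regions(mask, connectivity=connectivity, min_cells=min_cells)
        for name, mask in masks.items()
    }
    sites = build_strategy(regions, dict(suitability), top_n=top_n)
    return sites, areas
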