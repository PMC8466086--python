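"""Seeded synthetic crater landscapes for exercising the pipeline.

Real inputs for this kind of model are a photogeologic vector map and
a stereo-derived DEM of a crater palaeolake basin.  This module
synthesizes a structurally comparable landscape from analytic shapes
(annuli, wedge sectors, buffered channel lines) so that every stage is
testable without downloads: a rimmed impact crater with an interior
floor, a margin ring, a delta fan fed by an inlet channel breaching
the rim, patchy surficial cover, and a radial-bowl DEM that straddles
the configured shoreline elevation.

All polygon unit names come from the default score catalogue.  Output
is bit-identical for identical (params, seed): randomness goes through
``numpy.random.default_rng`` (PCG64) seeded from ``params.seed``.

Default dimensions are a desk-scale stand-in for the study setting (a
45-km crater is represented by a 2.4-km one on a 6-km grid): floor at
-2,450 m and rim crest at -2,000 m bracket the -2,200 m shoreline, in
the elevation range the source terrain occupies (lake levels between
-2,243 m and -2,410 m, basin base level near -2,400 m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, box

from ichno.factor_layers import ElevationModel, GeologyMap
from ichno.grids import GridSpec


class ParameterError(ValueError):
    """Landscape parameter invariant violation."""


def _default_grid() -> GridSpec:
    return GridSpec(
        origin_x=0.0,
        origin_y=6000.0,
        cell_size=60.0,
        n_rows=100,
        n_cols=100,
        crs_token="SYNTH:LOCAL",
    )


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the synthetic crater landscape.

    Distances and elevations in metres, angles in degrees
    (mathematical convention: 0 = +x, counterclockwise).
    """

    crater_radius: float = 2400.0
    rim_width: float = 400.0
    delta_azimuth: float = 180.0
    delta_spread: float = 60.0
    grid: GridSpec = field(default_factory=_default_grid)
    floor_elevation: float = -2450.0
    rim_elevation: float = -2000.0
    shoreline_elevation: float = -2200.0
    surficial_cover_fraction: float = 0.25
    noise_amplitude: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.floor_elevation < self.shoreline_elevation < self.rim_elevation):
            raise ParameterError(
                "require floor_elevation < shoreline_elevation < rim_elevation, "
                f"got {self.floor_elevation} / {self.shoreline_elevation} / "
                f"{self.rim_elevation}"
            )
        if not (0.0 <= self.surficial_cover_fraction <= 1.0):
            raise ParameterError(
                f"surficial_cover_fraction must be in [0, 1], got "
                f"{self.surficial_cover_fraction}"
            )
        if self.rim_width <= 0 or self.crater_radius <= self.rim_width:
            raise ParameterError(
                "require 0 < rim_width < crater_radius, got "
                f"rim_width={self.rim_width}, crater_radius={self.crater_radius}"
            )

    @property
    def center(self) -> tuple[float, float]:
        g = self.grid
        return (
            g.origin_x + g.n_cols * g.cell_size / 2.0,
            g.origin_y - g.n_rows * g.cell_size / 2.0,
        )


_RIM_UNITS = (
    "Crater rim blocky",
    "Crater rim breccia",
    "Crater rim layered",
    "Crater rim rough",
)

_SURFICIAL_UNITS = (
    "Aeolian bedforms, large",
    "Aeolian bedforms, small",
    "Minor Cover Units",
    "Moderate Cover Units",
    "Talus",
    "Undifferentiated smooth",
)

_CIRCLE_SEGS = 64  # quad_segs for buffer: smooth but hand-checkable shapes


def _disc(center: tuple[float, float], radius: float):
    return Point(center).buffer(radius, quad_segs=_CIRCLE_SEGS)


def _sector(center: tuple[float, float], radius: float, az: float, spread: float):
    """Circular wedge of half-angle spread/2 about azimuth az."""
    cx, cy = center
    angles = np.linspace(
        math.radians(az - spread / 2.0), math.radians(az + spread / 2.0), 32
    )
    pts = [(cx, cy)]
    pts += [(cx + radius * math.cos(a), cy + radius * math.sin(a)) for a in angles]
    from shapely.geometry import Polygon

    return Polygon(pts)


def generate_landscape(
    params: LandscapeParams | None = None,
) -> tuple[GeologyMap, GeologyMap, ElevationModel]:
    """Build (bedrock map, surficial map, DEM) for the given parameters.

    The bedrock map tiles the whole grid (a background plain under
    everything guarantees full coverage); feature order encodes the
    stratigraphic drawing order so the last-feature-wins rasterization
    reproduces the intended map.
    """
    if params is None:
        params = LandscapeParams()
    g = params.grid
    center = params.center
    rng = np.random.default_rng(params.seed)

    extent = box(
        g.origin_x,
        g.origin_y - g.n_rows * g.cell_size,
        g.origin_x + g.n_cols * g.cell_size,
        g.origin_y,
    )
    inner_radius = params.crater_radius - params.rim_width

    features: list = []
    # Background plain beyond the crater.
    features.append((extent, "Nili Planum fractured"))
    # Crater floor: two half-discs of the fractured floor units.
    floor = _disc(center, inner_radius)
    north = box(extent.bounds[0], center[1], extent.bounds[2], extent.bounds[3])
    south = box(extent.bounds[0], extent.bounds[1], extent.bounds[2], center[1])
    features.append((floor.intersection(north), "Crater floor fractured 1"))
    features.append((floor.intersection(south), "Crater floor fractured 2"))
    # Margin ring just inside the rim.
    margin = _disc(center, inner_radius).difference(
        _disc(center, 0.85 * inner_radius)
    )
    features.append((margin, "Margin fractured"))
    # Rim annulus in four quadrant arcs.
    rim = _disc(center, params.crater_radius).difference(_disc(center, inner_radius))
    for i, unit in enumerate(_RIM_UNITS):
        quadrant = _sector(center, 2.0 * params.crater_radius, 45.0 + 90.0 * i, 90.0)
        features.append((rim.intersection(quadrant), unit))
    # Delta fan: proximal blocky channel-mouth deposits, distal thin
    # layers split angularly with rough layered deposits.
    fan_radius = 0.75 * inner_radius
    fan = _sector(center, fan_radius, params.delta_azimuth, params.delta_spread)
    distal = fan.difference(_disc(center, 0.4 * inner_radius))
    half = _sector(
        center,
        fan_radius,
        params.delta_azimuth - params.delta_spread / 4.0,
        params.delta_spread / 2.0,
    )
    features.append((fan.intersection(_disc(center, 0.4 * inner_radius)), "Delta blocky"))
    features.append((distal.intersection(half), "Delta layered rough"))
    features.append((distal.difference(half), "Delta thinly layered"))
    # Inlet channel crossing the rim toward the fan.
    az = math.radians(params.delta_azimuth)
    reach = 2.0 * params.crater_radius
    channel_line = LineString(
        [
            (center[0] + 0.4 * inner_radius * math.cos(az),
             center[1] + 0.4 * inner_radius * math.sin(az)),
            (center[0] + reach * math.cos(az), center[1] + reach * math.sin(az)),
        ]
    )
    channel = channel_line.buffer(2.5 * g.cell_size, quad_segs=_CIRCLE_SEGS)
    features.append((channel.intersection(extent), "Neretva Vallis layered"))

    bedrock = GeologyMap(
        "bedrock", [(geom, name) for geom, name in features if not geom.is_empty]
    )

    # Surficial patches: random discs until the target cover fraction
    # of the grid area is approximately reached.
    surficial_features: list = []
    if params.surficial_cover_fraction > 0:
        target = params.surficial_cover_fraction * extent.area
        mean_radius = 4.0 * g.cell_size
        covered = 0.0
        # Fixed draw count keeps the stream deterministic; patches may
        # overlap, so covered area is an upper estimate.
        max_patches = int(np.ceil(target / (math.pi * mean_radius**2) * 2)) + 1
        for _ in range(max_patches):
            if covered >= target:
                break
            cx = rng.uniform(extent.bounds[0], extent.bounds[2])
            cy = rng.uniform(extent.bounds[1], extent.bounds[3])
            radius = rng.uniform(0.5 * mean_radius, 1.5 * mean_radius)
            unit = str(rng.choice(_SURFICIAL_UNITS))
            patch = _disc((cx, cy), radius).intersection(extent)
            if patch.is_empty:
                continue
            surficial_features.append((patch, unit))
            covered += patch.area
    surficial = GeologyMap("surficial", surficial_features)

    # Radial bowl DEM with small seeded roughness.
    xs, ys = g.cell_centers()
    r = np.hypot(xs - center[0], ys - center[1])
    t = np.clip(r / params.crater_radius, 0.0, 1.0)
    elevation = params.floor_elevation + (
        params.rim_elevation - params.floor_elevation
    ) * t**2
    elevation = elevation + rng.normal(0.0, params.noise_amplitude, size=g.shape)
    dem = ElevationModel(g, elevation)

    if not (
        (dem.values < params.shoreline_elevation).any()
        and (dem.values >= params.shoreline_elevation).any()
    ):
        raise ParameterError(
            "generated DEM does not straddle the shoreline elevation; "
            "adjust floor/rim/shoreline elevations"
        )
    return bedrock, surficial, dem


@dataclass(frozen=True)
class WorkedFixture:
    """Tiny 6x6 landscape with hand-enumerated suitability goldens."""

    bedrock: GeologyMap
    surficial: GeologyMap
    dem: ElevationModel
    expected: dict[str, np.ndarray]  # per-cell A, B, C (equations preset)


def worked_fixture() -> WorkedFixture:
    """A 6x6 landscape whose A/B/C values were enumerated by hand.

    Layout (100 m cells, origin top-left at (0, 600)):

    * columns 0-2: "Crater floor fractured 1" (L4 H2 E4 S4);
      columns 3-5: "Crater rim breccia" (L1 H4 E1 S4);
    * rows 0-2 at -2,100 m (above shoreline, W=1);
      rows 3-5 at -2,300 m (below, W=4);
    * one "Aeolian bedforms, large" patch (K=1) over rows 0-1,
      columns 0-1; everywhere else uncovered bedrock (K=4).

    Expected values are the weighted sums minus the cover penalty,
    computed cell class by cell class with the default (equations)
    weights and frozen here; e.g. the floor unit below shoreline,
    uncovered, scores A = 0.4*4 + 0.2*4 + 0.3*4 + 0.1*4 = 4.0, and the
    rim breccia above shoreline, uncovered, scores
    A = 0.4 + 0.2 + 1.2 + 0.1 = 1.9 and B = 1.6 + 0.1 + 1.2 + 0.2 = 3.1.
    """
    grid = GridSpec(
        origin_x=0.0,
        origin_y=600.0,
        cell_size=100.0,
        n_rows=6,
        n_cols=6,
        crs_token="SYNTH:LOCAL",
    )
    bedrock = GeologyMap(
        "bedrock",
        [
            (box(0.0, 0.0, 300.0, 600.0), "Crater floor fractured 1"),
            (box(300.0, 0.0, 600.0, 600.0), "Crater rim breccia"),
        ],
    )
    surficial = GeologyMap(
        "surficial",
        [(box(0.0, 400.0, 200.0, 600.0), "Aeolian bedforms, large")],
    )
    elevation = np.full(grid.shape, -2100.0)
    elevation[3:, :] = -2300.0
    dem = ElevationModel(grid, elevation)

    # Hand-enumerated goldens (equations preset), by cell class:
    #   floor/W1/K4: A 3.7, B 2.6, C 2.5   floor/W1/K1: A 0.7, B -0.4, C -0.5
    #   floor/W4/K4: A 4.0, B 3.2, C 4.0
    #   rim/W1/K4:   A 1.9, B 3.1, C 2.2   rim/W4/K4:   A 2.2, B 3.7, C 3.7
    a = np.full(grid.shape, np.nan)
    b = np.full(grid.shape, np.nan)
    c = np.full(grid.shape, np.nan)
    a[0:3, 0:3], b[0:3, 0:3], c[0:3, 0:3] = 3.7, 2.6, 2.5
    a[0:2, 0:2], b[0:2, 0:2], c[0:2, 0:2] = 0.7, -0.4, -0.5
    a[3:6, 0:3], b[3:6, 0:3], c[3:6, 0:3] = 4.0, 3.2, 4.0
    a[0:3, 3:6], b[0:3, 3:6], c[0:3, 3:6] = 1.9, 3.1, 2.2
    a[3:6, 3:6], b[3:6, 3:6], c[3:6, 3:6] = 2.2, 3.7, 3.7
    return WorkedFixture(bedrock, surficial, dem, {"A": a, "B": b, "C": c})
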