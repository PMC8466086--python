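# Methods

## Model

The pipeline implements ordinal multi-criteria suitability mapping by
weighted linear combination. Every cell of a shared grid receives factor
scores on a 1–4 scale (4 = most favourable for ichnofossil formation,
preservation and observation) and an aggregated suitability per
ichnofossil-type profile:

    N = ( Σ_i w_i · x_i ) − ( 4 − K )

where the x_i are the palaeoenvironmental factor scores (L, H, E, S, W),
the w_i non-negative weights summing to 1, and K the surficial-cover
score. The penalty term encodes that modern unconsolidated cover hides
bedrock regardless of how favourable the palaeoenvironment was. With
weights summing to 1 and K = 4 the result stays on the 1–4 ordinal scale;
under full cover (K = 1) with all factors at 1 it reaches the theoretical
minimum of −2. **No clamping is applied** — the sub-1 range carries
information (how much cover is suppressing an otherwise suitable cell),
and clamping would break the penalty-linearity identity
`N(K=k) = N(K=4) − (4 − k)` that the tests rely on.

### Assumptions

- Suitability is a *relative* ordinal ranking within the mapped area, not
  a probability. The threshold of 3 (inclusive) conventionally splits the
  top quarter of the scale.
- Factor scores attach to mapped geological units; within a unit the
  palaeoenvironment is treated as homogeneous at map scale.
- The water-table factor W is a pure elevation threshold: 4 strictly
  below the shoreline elevation, 1 at or above. "Below" is strict because
  the rule is stated as below-the-shoreline; a cell exactly at the
  shoreline is scored dry. This single convention is fixed, documented,
  and deliberately not configurable.
- All inputs share one CRS and, after rasterization, one grid taken from
  the DEM (the only intrinsically gridded input). The CRS token is passed
  through opaquely; no reprojection is attempted.

### Scoring tables and weight presets

The default catalogue holds 15 bedrock units (scored for L, H, E, S) and
6 surficial units (scored for K) covering a crater palaeolake landscape:
crater floor, margin, rim, inlet-valley and deltaic bedrock units, plus
aeolian bedforms, talus, and partial-cover classes. The catalogue is
data, not inference: users may override or extend any entry through the
YAML/JSON config (`units:` list), subject to validation (scores in 1–4,
bedrock units carry exactly {L,H,E,S}, surficial exactly {K}). Unit-name
matching is exact after trimming and collapsing internal whitespace — no
fuzzy matching, because a silent mis-score is worse than a hard error.

Two weight presets are shipped because the source publication prints two
inconsistent sets for the bioturbation (A) and bioerosion (B) profiles:
the operational formulas (0.4 substrate / 0.2 or 0.1 energy / 0.3
sedimentation / 0.1 or 0.2 water) and the weight table (0.5 / 0.1 / 0.2 /
0.2 for both). Both agree on biostratification (C: 0.1 E, 0.4 S, 0.5 W).
The `equations` preset is the default since those are the formulas
printed alongside the published results; selecting `table5` is one flag.
Which set produced the published rasters is not stated, hence the choice
stays user-visible. A log message notes the active preset at load time.

### Rasterization and nodata

Vector polygons are burned by **cell-center containment**, boundary
counted as inside, later features winning where polygons overlap —
deterministic and mirroring map drawing order. Cells covered by no
bedrock polygon are nodata; cells under no surficial polygon are
*uncovered* (K = 4), which is also the behaviour when no surficial map is
supplied at all. Nodata (NaN in memory, a sentinel in files) propagates
through every per-cell operation: an aggregated cell is nodata iff any
required input is nodata. No infilling is performed. Arithmetic is double
precision; the suite checks scalar/vector path agreement at 1e-12.

### Site extraction and the survey strategy

Classification is inclusive (suitability ≥ threshold). Connected regions
of high-suitability cells are extracted per profile with
`scipy.ndimage.label` (4- or 8-connectivity; default 8) and relabelled
into row-major order of each region's first cell so labels are
implementation-independent. Regions below `min_cells` (default 4) are
discarded as noise. Regions from different profiles sharing at least one
cell are merged into a site (union–find); a site's statistics (mean/max
suitability) are computed per member profile over that profile's
contributing cells. Sites are ranked by the maximum per-profile mean,
descending, ties broken by larger area then earlier row-major position,
truncated to `top_n` (default 10) and renumbered 1..n.

Recommendations derive from membership: profile A predicts bioturbation,
B bioerosion, C biostratification. The observation mode is `imaging` for
bioturbation/biostratification (structures built from sediment grains
cannot be smaller than the grains, so cameras resolve them), `sampling`
when only bioerosion is predicted (microborings can fall below imaging
resolution and need sample preparation), and `imaging+sampling` when
both kinds apply. These extraction/ranking/recommendation rules are this
package's formalization of what is normally done by expert judgement on
the printed maps; `min_cells`, connectivity and `top_n` are declared
defaults, not inferred values.

## Synthetic landscape generator

`ichno.synthetic_crater` builds seeded test landscapes from analytic
shapes — a background plain, a crater floor in two half-discs, a margin
ring, a rim annulus in four quadrant arcs, a delta fan wedge (proximal
blocky, distal thinly-layered/layered-rough) fed by a buffered channel
line breaching the rim — so expected region structure stays
hand-checkable, plus random disc patches of surficial cover and a
radial-bowl DEM with small Gaussian roughness. All randomness flows
through `numpy.random.default_rng(seed)` (PCG64, a named, stable
algorithm), making outputs bit-identical for identical parameters.

Defaults are a desk-scale stand-in for the study setting: a 2.4-km
crater on a 100×100 grid of 60-m cells (the real basin is a 45-km crater
mapped at HiRISE scale), floor at −2,450 m and rim at −2,000 m bracketing
the −2,200 m shoreline — inside the elevation range the real basin
occupies (lake levels −2,243 m to −2,410 m, base level near −2,400 m) —
and ~25 % surficial cover. The generator emulates the *structure* real
inputs have (unit mosaic, cover patches, a DEM straddling the shoreline);
it does not emulate photogeologic mapping noise, irregular unit contacts,
or DEM artefacts, so green tests demonstrate pipeline correctness, not
performance on real mapping. A hand-enumerated 6×6 fixture
(`worked_fixture`) ships frozen per-cell A/B/C goldens computed class by
class from the score tables.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| shoreline_elevation | −2,200 | m | extended high-stand shoreline; −2,243 m (strict high-stand) is equally valid and one config key away |
| threshold | 3 | score | inclusive; top quarter of the 1–4 scale |
| weight preset | `equations` | — | the operational published formulas |
| connectivity | 8 | — | diagonal-touching high cells are one field site |
| min_cells | 4 | cells | suppresses single-cell speckle regions |
| top_n | 10 | sites | length of the published-style strategy list |

## Known limitations

- The ten published field sites were delineated manually; this package's
  automated extraction is a reproducible surrogate, not a reproduction,
  and is not expected to match them site for site.
- Temporal resolution: one model for the palaeolake phase; no separate
  models per geological period.
- No terrain-hazard, traverse-energy or path optimization; the outputs
  are inputs to such planning, not a plan.
- No reprojection, no DEM generation, no imagery processing.

## Problem sizes in the shipped tests

Property and oracle tests run on 20×20 grids (exact agreement at 1e-12);
the end-to-end tests use a 50×50 or the default 100×100 synthetic
landscape. These sizes exercise every code path, including multi-region
merging, while keeping the whole suite a few seconds long.
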