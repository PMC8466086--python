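# ichno

Palaeontological predictive modelling of **ichnofossil suitability** — a
geospatial pipeline that turns a photogeologic map and a digital elevation
model of a crater palaeolake basin into ranked predictions of where
fossilized life–substrate interactions (trace fossils) are most likely to
be found and observed.

Ichnofossils — burrows (bioturbation), borings (bioerosion), and
stromatolites / microbially induced sedimentary structures
(biostratification) — are among the most durable biosignatures known, which
makes them attractive targets for rover-based astrobiology in ancient
lacustrine settings such as Jezero crater. This package implements the
multi-criteria weighted-overlay model used for that kind of site
prediction, for anyone who wants to rerun it, vary its weights and scores,
or apply it to a different mapped landscape.

## The model

Each mapped geological unit carries ordinal suitability scores (1–4,
4 = most favourable) for five palaeoenvironmental factors:

| symbol | factor |
|---|---|
| *L* | substrate suitability for bioturbation (loose substrates) |
| *H* | substrate suitability for bioerosion (lithified hardgrounds) |
| *E* | kinetic energy regime (low energy preserves traces) |
| *S* | sedimentation rate (slow accumulation gives organisms time) |
| *W* | water-table position (below the palaeolake shoreline) |

plus a surficial-cover score *K* (4 = uncovered bedrock, 1 = fully
concealed). The aggregated suitability at each cell is a weighted linear
combination with a cover penalty:

    N_xy = ( Σ_i w_i · x_i,xy ) − ( 4 − K_xy )

with non-negative weights summing to 1 per ichnofossil-type profile
(*A* bioturbation, *B* bioerosion, *C* biostratification). Two published
weight sets are shipped as presets — `equations`
(A: 0.4·L + 0.2·E + 0.3·S + 0.1·W; B: 0.4·H + 0.1·E + 0.3·S + 0.2·W;
C: 0.1·E + 0.4·S + 0.5·W) and `table5` (A/B: 0.5 substrate, 0.1·E, 0.2·S,
0.2·W; C identical) — because the source publication prints both.
*W* is scored from the DEM: 4 strictly below the configured shoreline
elevation (default −2,200 m), 1 at or above. Cells with suitability ≥ 3
(the top quarter of the 1–4 scale, inclusive) are classified as
high-suitability; contiguous regions are extracted, merged across
profiles, ranked, and annotated with the predicted ichnofossil types and
an observation mode (imaging, or sampling where microscopic borings may
exceed camera resolution).

## Worked example

Generate a seeded synthetic crater landscape (bedrock map, surficial map,
DEM — all plain-text GeoJSON/ESRI-ASCII) and score it:

```sh
$ ichno synth --seed 1 --out run/in
wrote bedrock.geojson, surficial.geojson, dem.asc to run/in

$ ichno score --bedrock run/in/bedrock.geojson \
              --surficial run/in/surficial.geojson \
              --dem run/in/dem.asc --out run/out
wrote 14 artifacts to run/out (2 sites)

$ head -3 run/out/strategy.csv
site_id,profiles,cell_count,area_m2,mean_A,mean_B,mean_C,max_A,max_B,max_C,centroid_x,centroid_y,recommended_types,detection_mode
1,ABC,2046,7365600.0,3.622434,3.2,3.614614,4.0,3.2,4.0,3135.4545454545455,3034.6627565982403,bioturbation+bioerosion+biostratification,imaging+sampling
2,B,5212,18763200.0,,3.194148,,,3.2,,2932.07981580967,2963.691481197237,bioerosion,sampling
```

Site 1 is the crater floor inside the palaeolake: high mean suitability in
all three profiles (mean A ≈ 3.62, C ≈ 3.61), so all three ichnofossil
types are plausible there and the recommendation is combined imaging and
sampling. Site 2 is the hardground-rich rim/margin belt: suitable for
bioerosion only (mean B ≈ 3.19), and because borings can be microscopic
the recommended mode is sampling. The 14 artifacts are the six factor
rasters (L, H, E, S, W, K), three suitability rasters, three threshold
masks, the dissolved site polygons (`sites.geojson`) and the strategy
table; `manifest.json` records SHA-256 checksums, and a rerun on the same
inputs is byte-identical.

`ichno report --suitability-dir run/out --out run/rep` re-derives the
strategy and per-profile above-threshold areas from existing suitability
rasters — including externally produced ones, as long as they are ESRI
ASCII grids named `suitability_A.asc` etc.

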