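"""Threshold classification, region extraction, and the site strategy."""

import numpy as np
import pytest

from ichno.grids import GridSpec, Raster
from ichno.sites import (
    Region,
    build_strategy,
    classify,
    extract_regions,
    sites_to_geojson,
    strategy_table,
)


def grid(n_rows=8, n_cols=8, cell=10.0):
    return GridSpec(
        origin_x=0.0, origin_y=n_rows * cell, cell_size=cell,
        n_rows=n_rows, n_cols=n_cols,
    )


def mask_raster(truth, g=None):
    truth = np.asarray(truth, dtype=float)
    g = g or grid(*truth.shape)
    return Raster(g, truth, kind="mask")


def flood_fill_components(truth, connectivity):
    """Independent oracle: BFS flood fill over true cells."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    n_rows, n_cols = truth.shape
    seen = np.zeros_like(truth, dtype=bool)
    components = []
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if not truth[r0, c0] or seen[r0, c0]:
                continue
            queue, cells = [(r0, c0)], []
            seen[r0, c0] = True
            while queue:
                r, c = queue.pop()
                cells.append((r, c))
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < n_rows and 0 <= cc < n_cols
                        and truth[rr, cc] and not seen[rr, cc]
                    ):
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            components.append(tuple(sorted(cells)))
    components.sort(key=lambda cells: cells[0])
    return components


class TestClassify:
    def test_uniform_above_threshold_all_true(self):
        suit = Raster(grid(), np.full((8, 8), 4.0), kind="A")
        assert (classify(suit, 3.0).values == 1.0).all()

    def test_exactly_at_threshold_is_true(self):
        suit = Raster(grid(), np.full((8, 8), 3.0), kind="A")
        assert (classify(suit, 3.0).values == 1.0).all()

    def test_just_below_threshold_all_false(self):
        suit = Raster(grid(), np.full((8, 8), 2.9), kind="A")
        assert (classify(suit, 3.0).values == 0.0).all()

    def test_nodata_propagates(self):
        values = np.full((8, 8), 3.5)
        values[1, 1] = np.nan
        out = classify(Raster(grid(), values, kind="A"), 3.0)
        assert np.isnan(out.values[1, 1]) and out.values[0, 0] == 1.0


class TestExtractRegions:
    def test_all_false_mask_gives_no_regions(self):
        assert extract_regions(mask_raster(np.zeros((8, 8)))) == []

    def test_single_block(self):
        truth = np.zeros((8, 8))
        truth[2:5, 3:6] = 1
        regions = extract_regions(mask_raster(truth), min_cells=1)
        assert len(regions) == 1
        assert regions[0].cell_count == 9
        assert regions[0].label == 1

    def test_diagonal_blocks_connectivity(self):
        truth = np.zeros((8, 8))
        truth[0:2, 0:2] = 1
        truth[2:4, 2:4] = 1  # touches the first block only at a corner
        assert len(extract_regions(mask_raster(truth), connectivity=8, min_cells=1)) == 1
        assert len(extract_regions(mask_raster(truth), connectivity=4, min_cells=1)) == 2

    def test_min_cells_filters_small_regions(self):
        truth = np.zeros((8, 8))
        truth[0, 0] = 1  # isolated single cell
        truth[4:7, 4:7] = 1
        regions = extract_regions(mask_raster(truth), min_cells=4)
        assert len(regions) == 1 and regions[0].cell_count == 9

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_masks(self, connectivity, rng):
        for _ in range(10):
            truth = rng.random((15, 15)) < 0.45
            regions = extract_regions(
                mask_raster(truth.astype(float), grid(15, 15)),
                connectivity=connectivity,
                min_cells=1,
            )
            expected = flood_fill_components(truth, connectivity)
            assert [r.cells for r in regions] == expected
            assert [r.label for r in regions] == list(range(1, len(expected) + 1))

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError, match="connectivity"):
            extract_regions(mask_raster(np.zeros((8, 8))), connectivity=6)


def make_suitability(g, values_by_profile):
    return {
        p: Raster(g, np.asarray(v, dtype=float), kind=p)
        for p, v in values_by_profile.items()
    }


class TestBuildStrategy:
    def test_single_profile_region_recommends_imaging(self):
        g = grid()
        values = np.full((8, 8), 3.5)
        suit = make_suitability(g, {"A": values})
        region = Region(1, tuple((r, c) for r in range(2) for c in range(2)))
        sites = build_strategy({"A": [region]}, suit)
        assert len(sites) == 1
        site = sites[0]
        assert site.profile_memberships == ("A",)
        assert site.recommended_types == ("bioturbation",)
        assert site.detection_mode == "imaging"
        assert site.mean_score["A"] == pytest.approx(3.5)
        assert site.area == pytest.approx(4 * 10.0**2)

    def test_bioerosion_only_recommends_sampling(self):
        g = grid()
        suit = make_suitability(g, {"B": np.full((8, 8), 3.2)})
        region = Region(1, ((0, 0), (0, 1), (1, 0), (1, 1)))
        sites = build_strategy({"B": [region]}, suit)
        assert sites[0].recommended_types == ("bioerosion",)
        assert sites[0].detection_mode == "sampling"

    def test_overlapping_b_and_c_merge_with_both_modes(self):
        g = grid()
        suit = make_suitability(
            g, {"B": np.full((8, 8), 3.1), "C": np.full((8, 8), 3.6)}
        )
        region_b = Region(1, ((0, 0), (0, 1), (1, 0), (1, 1)))
        region_c = Region(1, ((1, 1), (1, 2), (2, 1), (2, 2)))
        sites = build_strategy({"B": [region_b], "C": [region_c]}, suit)
        assert len(sites) == 1
        site = sites[0]
        assert site.profile_memberships == ("B", "C")
        assert site.recommended_types == ("bioerosion", "biostratification")
        assert site.detection_mode == "imaging+sampling"
        assert site.cell_count == 7  # union of the two 4-cell regions

    def test_disjoint_regions_stay_separate(self):
        g = grid()
        suit = make_suitability(
            g, {"A": np.full((8, 8), 3.5), "B": np.full((8, 8), 3.1)}
        )
        region_a = Region(1, ((0, 0), (0, 1)))
        region_b = Region(1, ((5, 5), (5, 6)))
        sites = build_strategy({"A": [region_a], "B": [region_b]}, suit)
        assert len(sites) == 2
        assert sites[0].profile_memberships == ("A",)  # higher mean first

    def test_ranking_by_mean_then_area(self):
        g = grid()
        values = np.full((8, 8), 3.0)
        values[0, :4] = 4.0  # first region's cells score higher
        suit = make_suitability(g, {"A": values})
        high = Region(1, tuple((0, c) for c in range(4)))
        large = Region(2, tuple((4, c) for c in range(6)))
        sites = build_strategy({"A": [large, high]}, suit)
        assert sites[0].mean_score["A"] == pytest.approx(4.0)
        assert sites[0].site_id == 1 and sites[1].site_id == 2
        # Equal means: larger area wins.
        tied_small = Region(3, tuple((6, c) for c in range(3)))
        sites = build_strategy({"A": [tied_small, large]}, suit)
        assert sites[0].cell_count == 6

    def test_truncation_to_top_n(self):
        g = grid(20, 20)
        suit = make_suitability(g, {"A": np.full((20, 20), 3.5)})
        regions = [
            Region(i + 1, ((2 * i, 0), (2 * i, 1)))
            for i in range(10)  # 10 disjoint two-cell strips
        ] + [
            Region(11 + i, ((2 * i, 10), (2 * i, 11)))
            for i in range(5)
        ]
        sites = build_strategy({"A": regions}, suit, top_n=10)
        assert len(sites) == 10
        assert [s.site_id for s in sites] == list(range(1, 11))

    def test_sites_are_pairwise_disjoint(self, rng):
        g = grid(12, 12)
        suit = make_suitability(
            g,
            {
                p: 2.0 + 2.0 * rng.random((12, 12))
                for p in ("A", "B", "C")
            },
        )
        masks = {p: classify(suit[p], 3.0) for p in suit}
        regions = {p: extract_regions(masks[p], min_cells=1) for p in masks}
        sites = build_strategy(regions, suit, top_n=50)
        seen = set()
        for site in sites:
            assert not (seen & set(site.cells))
            seen.update(site.cells)
            # Every cell clears the threshold in at least one member profile.
            for r, c in site.cells:
                assert any(
                    suit[p].values[r, c] >= 3.0 for p in site.profile_memberships
                )

    def test_top_n_must_be_positive(self):
        g = grid()
        suit = make_suitability(g, {"A": np.full((8, 8), 3.5)})
        with pytest.raises(ValueError, match="top_n"):
            build_strategy({"A": []}, suit, top_n=0)

    def test_geojson_and_table_outputs(self):
        g = grid()
        suit = make_suitability(g, {"A": np.full((8, 8), 3.5)})
        region = Region(1, ((0, 0), (0, 1), (1, 0), (1, 1)))
        sites = build_strategy({"A": [region]}, suit)
        doc = sites_to_geojson(sites, g)
        assert doc["type"] == "FeatureCollection"
        assert doc["features"][0]["properties"]["detection_mode"] == "imaging"
        table = strategy_table(sites)
        assert list(table["site_id"]) == [1]
        assert table.loc[0, "recommended_types"] == "bioturbation"
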