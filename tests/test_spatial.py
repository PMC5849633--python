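"""Tile maps, windowed distance-to-epithelium, heatmaps and immune counts."""

import numpy as np
import pandas as pd
import pytest

from caftools import (
    MARKERS,
    TILE_AREA_MM2,
    TileMap,
    assign_subsets,
    build_tile_map,
    count_immune_per_label,
    density_per_compartment,
    derive_thresholds,
    distance_to_epithelium,
    render_distance_heatmap,
    summarize_distance_by_subset,
)
from caftools.evaluation import brute_force_distance


def grid_map(epith, **channels):
    return TileMap(intensities={k: np.asarray(v, float) for k, v in channels.items()},
                   epithelial=np.asarray(epith, bool))


class TestBuildTileMap:
    def test_constant_raster_gives_constant_tiles(self):
        raster = np.full((30, 30), 7.5)
        mask = np.zeros((30, 30), bool)
        tiles = build_tile_map({"FAP": raster}, mask, pixel_size_um=5.0)
        assert tiles.shape == (10, 10)
        assert (tiles.intensities["FAP"] == 7.5).all()

    def test_half_mask_splits_compartments(self):
        raster = np.zeros((30, 60))
        mask = np.zeros((30, 60), bool)
        mask[:, :30] = True  # left half epithelial
        tiles = build_tile_map({"FAP": raster}, mask, pixel_size_um=5.0)
        assert tiles.shape == (10, 20)
        assert tiles.epithelial[:, :10].all()
        assert not tiles.epithelial[:, 10:].any()

    def test_partial_edge_tiles_dropped(self):
        # 3 px per tile at 5 um pixels: 32x31 px holds 10x10 whole tiles
        raster = np.zeros((32, 31))
        tiles = build_tile_map({"FAP": raster}, np.zeros((32, 31), bool), pixel_size_um=5.0)
        assert tiles.shape == (10, 10)

    def test_non_dividing_pixel_size_resampled(self):
        raster = np.full((40, 40), 3.0)
        tiles = build_tile_map({"FAP": raster}, np.zeros((40, 40), bool), pixel_size_um=4.0)
        assert tiles.shape[0] >= 2
        assert np.allclose(tiles.intensities["FAP"], 3.0)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_tile_map(
                {"FAP": np.zeros((30, 30)), "SMA": np.zeros((15, 30))},
                np.zeros((30, 30), bool),
                pixel_size_um=5.0,
            )


class TestAssignSubsets:
    def test_all_hi_profile_labeled_s1(self):
        epith = np.zeros((6, 6), bool)
        channels = {m: np.full((6, 6), 300.0) for m in MARKERS}
        tiles = grid_map(epith, **channels)
        ref = {m: np.array([10.0, 40.0, 100.0, 300.0]) for m in MARKERS}
        labeled = assign_subsets(tiles, derive_thresholds(ref))
        assert (labeled.labels == "CAF-S1").all()

    def test_zero_noise_tissue_fully_recovered(self, tissue_sample):
        truth = tissue_sample.truth
        tiles = build_tile_map(
            tissue_sample.rasters, tissue_sample.epithelial_mask, tissue_sample.pixel_size_um
        )
        thresholds = derive_thresholds(tiles.stromal_frame()[list(MARKERS)])
        labeled = assign_subsets(tiles, thresholds)
        stromal = truth.stromal
        assert (labeled.labels[stromal] == truth.labels[stromal]).all()
        assert all(l is None for l in labeled.labels[truth.epithelial])

    def test_idempotent(self, tissue_sample):
        tiles = tissue_sample.truth
        thresholds = derive_thresholds(tiles.stromal_frame()[list(MARKERS)])
        once = assign_subsets(tiles, thresholds)
        twice = assign_subsets(once, thresholds)
        assert (once.labels[once.stromal] == twice.labels[twice.stromal]).all()


class TestDistance:
    def test_diagonal_neighbor_is_sqrt2(self):
        epith = np.zeros((5, 5), bool)
        epith[2, 2] = True
        d = distance_to_epithelium(grid_map(epith)).distances
        assert d[1, 1] == pytest.approx(np.sqrt(2))
        assert d[2, 3] == pytest.approx(1.0)

    def test_outside_window_undefined(self):
        epith = np.zeros((3, 10), bool)
        epith[1, 9] = True
        d = distance_to_epithelium(grid_map(epith), window_radius=5).distances
        assert np.isnan(d[1, 3])  # 6 tiles away in x
        assert d[1, 4] == pytest.approx(5.0)

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            epith = rng.random((30, 30)) < rng.uniform(0.05, 0.4)
            tiles = grid_map(epith)
            fast = distance_to_epithelium(tiles).distances
            slow = brute_force_distance(tiles)
            assert np.array_equal(np.isnan(fast), np.isnan(slow))
            assert np.allclose(fast, slow, equal_nan=True)

    def test_window_monotonicity(self):
        rng = np.random.default_rng(1)
        epith = rng.random((20, 20)) < 0.1
        tiles = grid_map(epith)
        d5 = distance_to_epithelium(tiles, 5).distances
        d7 = distance_to_epithelium(tiles, 7).distances
        defined5 = np.isfinite(d5)
        assert (np.isfinite(d7)[defined5]).all()  # defined stays defined
        assert (d7[defined5] <= d5[defined5] + 1e-12).all()

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        epith = np.zeros((24, 24), bool)
        epith[4:9, 3:8] = rng.random((5, 5)) < 0.6
        shifted = np.roll(epith, (6, 6), axis=(0, 1))
        d0 = distance_to_epithelium(grid_map(epith)).distances
        d1 = distance_to_epithelium(grid_map(shifted)).distances
        inner = d0[:12, :12]
        assert np.allclose(inner, d1[6:18, 6:18], equal_nan=True)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError, match="window_radius"):
            distance_to_epithelium(grid_map(np.zeros((4, 4), bool)), 0)


class TestDistanceSummary:
    def test_means_ordered_by_construction(self):
        epith = np.zeros((3, 9), bool)
        epith[:, 0] = True
        labels = np.full((3, 9), None, dtype=object)
        labels[:, 1] = "CAF-S1"  # adjacent: d = 1
        labels[:, 5] = "CAF-S4"  # d = 5
        labels[:, 2:5] = "CAF-S3"
        labels[:, 6:] = "CAF-S2"
        tiles = TileMap(intensities={}, epithelial=epith, labels=labels)
        res = summarize_distance_by_subset(tiles, distance_to_epithelium(tiles))
        assert res.summary.loc["CAF-S1", "mean"] == pytest.approx(1.0)
        assert res.summary.loc["CAF-S4", "mean"] == pytest.approx(5.0)

    def test_undefined_distances_counted_not_zero(self):
        epith = np.zeros((3, 12), bool)
        epith[:, 0] = True
        labels = np.full((3, 12), None, dtype=object)
        labels[:, 1] = "CAF-S1"
        labels[:, 8:] = "CAF-S2"  # beyond the window: undefined
        labels[:, 2:8] = "CAF-S3"
        tiles = TileMap(intensities={}, epithelial=epith, labels=labels)
        res = summarize_distance_by_subset(tiles, distance_to_epithelium(tiles))
        assert res.summary.loc["CAF-S2", "n_defined"] == 0
        assert np.isnan(res.summary.loc["CAF-S2", "mean"])
        assert res.summary.loc["CAF-S2", "n_undefined"] == 12

    def test_unlabeled_map_rejected(self):
        tiles = grid_map(np.zeros((4, 4), bool))
        with pytest.raises(ValueError, match="label"):
            summarize_distance_by_subset(tiles, distance_to_epithelium(tiles))


class TestHeatmap:
    def _simple_map(self):
        epith = np.zeros((3, 8), bool)
        epith[:, 0] = True
        tiles = grid_map(epith)
        return tiles, distance_to_epithelium(tiles)

    def test_ramp_endpoints_red_and_yellow(self):
        tiles, dmap = self._simple_map()
        img = render_distance_heatmap(dmap, tiles)
        d = dmap.distances
        assert (img[d == np.nanmin(d)] == [255, 0, 0]).all()
        assert (img[d == np.nanmax(d)] == [255, 255, 0]).all()
        assert (img[tiles.epithelial] == [0, 0, 0]).all()

    def test_uniform_distance_uniform_color(self):
        epith = np.zeros((3, 3), bool)
        epith[1, 1] = True
        tiles = grid_map(epith)
        dmap = distance_to_epithelium(tiles)
        # keep only the four rook neighbours (all at d = 1)
        d = dmap.distances.copy()
        d[d > 1] = np.nan
        from caftools.spatial import DistanceMap

        img = render_distance_heatmap(DistanceMap(d, 5), tiles)
        colors = img[np.isfinite(d)]
        assert (colors == colors[0]).all()

    def test_round_trip_through_green_channel(self, tmp_path):
        import imageio.v3 as iio

        tiles, dmap = self._simple_map()
        path = tmp_path / "heat.png"
        render_distance_heatmap(dmap, tiles, path)
        img = iio.imread(path)
        d = dmap.distances
        defined = np.isfinite(d)
        dmin, dmax = np.nanmin(d), np.nanmax(d)
        recovered = dmin + img[..., 1][defined] / 255.0 * (dmax - dmin)
        assert np.allclose(recovered, d[defined], atol=(dmax - dmin) / 255.0)

    def test_all_undefined_rejected(self):
        tiles = grid_map(np.zeros((4, 4), bool))
        dmap = distance_to_epithelium(tiles)
        with pytest.raises(ValueError, match="no defined"):
            render_distance_heatmap(dmap, tiles)


class TestImmuneCounts:
    def _labeled_map(self):
        epith = np.zeros((4, 4), bool)
        epith[0, 0] = True
        labels = np.full((4, 4), "CAF-S3", dtype=object)
        labels[0, 0] = None
        labels[1, 1] = "CAF-S1"
        return TileMap(intensities={}, epithelial=epith, labels=labels)

    def test_point_in_tile_center(self):
        tiles = self._labeled_map()
        pts = pd.DataFrame({"x_um": [22.5], "y_um": [22.5]})  # center of tile (1,1)
        counts = count_immune_per_label(tiles, pts)
        assert counts["CAF-S1"] == 1
        assert sum(counts.values()) == 1

    def test_edge_point_goes_to_containing_half_open_tile(self):
        tiles = self._labeled_map()
        pts = pd.DataFrame({"x_um": [15.0], "y_um": [15.0]})  # shared corner
        counts = count_immune_per_label(tiles, pts)
        assert counts["CAF-S1"] == 1  # belongs to tile (1,1), not (0,0)

    def test_counts_conserve_total(self, tissue_sample):
        counts = count_immune_per_label(tissue_sample.truth, tissue_sample.cd3_points)
        assert sum(counts.values()) == len(tissue_sample.cd3_points)

    def test_poisson_rates_recovered_per_label(self):
        from caftools import TissueSimConfig, gen_tissue

        rates = {"CAF-S1": 5.0, "CAF-S2": 0.5, "CAF-S3": 0.5, "CAF-S4": 0.5, "epithelial": 0.5}
        sample = gen_tissue(TissueSimConfig(grid_shape=(50, 50), cd3_rate_per_subset=rates, seed=13))
        counts = count_immune_per_label(sample.truth, sample.cd3_points)
        labels = sample.truth.labels
        for subset, rate in (("CAF-S1", 5.0), ("CAF-S4", 0.5)):
            n_tiles = int((labels == subset).sum())
            mean = counts[subset] / n_tiles
            se = np.sqrt(rate / n_tiles)
            assert abs(mean - rate) < 3 * se

    def test_out_of_bounds_point_errors_with_coordinates(self):
        tiles = self._labeled_map()
        pts = pd.DataFrame({"x_um": [999.0], "y_um": [1.0]})
        with pytest.raises(ValueError, match="999"):
            count_immune_per_label(tiles, pts)


class TestDensities:
    def test_simple_density(self):
        out = density_per_compartment({"stromal": 50}, {"stromal": 2.0})
        assert out.loc["stromal", "density_per_mm2"] == 25.0

    def test_tile_area_conversion(self):
        # 45 cells over 1000 stromal tiles = 0.225 mm^2 -> 200 / mm^2
        assert 1000 * TILE_AREA_MM2 == pytest.approx(0.225)
        out = density_per_compartment({"stromal": 45}, {"stromal": 1000 * TILE_AREA_MM2})
        assert out.loc["stromal", "density_per_mm2"] == pytest.approx(200.0)

    def test_zero_cells_zero_density(self):
        out = density_per_compartment({"epithelial": 0}, {"epithelial": 1.0})
        assert out.loc["epithelial", "density_per_mm2"] == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            density_per_compartment({"stromal": 1}, {"stromal": 0.0})

    def test_compartment_areas_from_map(self, tissue_sample):
        areas = tissue_sample.truth.compartment_areas_mm2()
        total_tiles = tissue_sample.truth.epithelial.size
        assert areas["epithelial"] + areas["stromal"] == pytest.approx(total_tiles * TILE_AREA_MM2)
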