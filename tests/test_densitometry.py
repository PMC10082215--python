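"""Length estimation, counting frames, densities, heatmaps."""

from __future__ import annotations

import numpy as np
import pytest

from atriadense.densitometry import (
    CountingFrame,
    FramePlacementError,
    RoiSpec,
    compute_density,
    density_heatmap,
    place_counting_frames,
    roi_density,
    skeleton_length,
    summarize_density,
)
from atriadense.imageproc import SkeletonMask
from conftest import make_scene


def skel(mask: np.ndarray, px: float = 1.0) -> SkeletonMask:
    return SkeletonMask(mask.astype(bool), px)


class TestSkeletonLength:
    def test_axis_aligned_line_exact_under_both_methods(self):
        m = np.zeros((9, 120), dtype=bool)
        m[4, 10:110] = True  # 100 px
        s = skel(m)
        assert skeleton_length(s, "pixel_count") == pytest.approx(100.0)
        # 99 unit edges + 1 px endpoint convention
        assert skeleton_length(s, "diagonal_corrected") == pytest.approx(100.0)

    def test_diagonal_line_sqrt2_weighting(self):
        m = np.eye(100, dtype=bool)
        s = skel(m)
        assert skeleton_length(s, "pixel_count") == pytest.approx(100.0)
        want = 99 * np.sqrt(2.0) + 1.0
        assert skeleton_length(s, "diagonal_corrected") == pytest.approx(want)
        assert skeleton_length(s, "diagonal_corrected") == pytest.approx(141.4, abs=0.5)

    def test_pixel_size_scaling_and_isolated_pixels(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2, 2] = m[7, 7] = True
        s = skel(m, px=0.5)
        assert skeleton_length(s, "pixel_count") == pytest.approx(1.0)
        assert skeleton_length(s, "diagonal_corrected") == pytest.approx(1.0)

    def test_non_skeleton_input_rejected(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:3, 1:3] = True
        bad = SkeletonMask.__new__(SkeletonMask)  # bypass constructor check
        object.__setattr__(bad, "pixels", m)
        object.__setattr__(bad, "pixel_size_um", 1.0)
        with pytest.raises(ValueError, match="2x2"):
            skeleton_length(bad)

    def test_rendered_arbor_recovery_noise_free(self):
        """Clean renders of branching arbors recover truth length.

        Aggregated over several arbors: the diagonal-corrected estimator is
        nearly unbiased, while pixel counting understates oblique runs (the
        sqrt(2) bias) plus tip/junction erosion, but stays within 25%.
        """
        from atriadense import synthetic_scene as sc
        from atriadense.imageproc import PreprocConfig
        from atriadense.pipeline_io import segment_image

        est_d = est_p = true = 0.0
        for seed in range(6):
            p = sc.ArborGrowthParams(
                n_roots=2, branch_rate_per_um=0.005, max_total_length_um=800.0, seed=seed
            )
            truth = sc.simulate_arbor(p, bounds_um=(10, 10, 590, 590))
            optics = sc.OpticsParams(
                pixel_size_um=1.0, poisson_gain=0.0, gaussian_sigma=0.0,
                illumination_gradient_amplitude=0.0, n_fat_blobs=0, varicosity_gain=1.0,
            )
            raster, truth = sc.render_scene(truth, None, optics, (600, 600))
            s, _ = segment_image(raster, PreprocConfig(background_radius_px=40))
            true += truth.per_region_length_um["scene"]
            est_d += skeleton_length(s, "diagonal_corrected")
            est_p += skeleton_length(s, "pixel_count")
        assert est_d == pytest.approx(true, rel=0.10)
        assert est_p == pytest.approx(true, rel=0.25)


class TestCountingFrames:
    def roi(self, h=1000, w=1000):
        return RoiSpec("test", np.ones((h, w), dtype=bool))

    def test_grid_placement_six_disjoint_frames(self):
        frames = place_counting_frames(self.roi(), 6, (200, 200), "grid")
        assert len(frames) == 6
        for i, f in enumerate(frames):
            assert 0 <= f.row0 and f.row0 + 200 <= 1000
            assert 0 <= f.col0 and f.col0 + 200 <= 1000
            for g in frames[i + 1 :]:
                assert not f.overlaps(g)

    def test_roi_smaller_than_frame_errors(self):
        with pytest.raises(FramePlacementError):
            place_counting_frames(self.roi(150, 150), 1, (200, 200))

    def test_random_placement_deterministic_under_seed(self):
        f1 = place_counting_frames(self.roi(), 6, (200, 200), "random", seed=5)
        f2 = place_counting_frames(self.roi(), 6, (200, 200), "random", seed=5)
        assert f1 == f2
        f3 = place_counting_frames(self.roi(), 6, (200, 200), "random", seed=6)
        assert f1 != f3

    def test_frames_avoid_excluded_territory(self):
        include = np.ones((600, 600), dtype=bool)
        exclude = np.zeros((600, 600), dtype=bool)
        exclude[:, 200:400] = True  # central band forbidden
        roi = RoiSpec("banded", include, exclude)
        frames = place_counting_frames(roi, 4, (150, 150), "grid")
        for f in frames:
            assert not exclude[f.slices()].any()


class TestComputeDensity:
    def test_density_arithmetic(self):
        m = np.zeros((300, 300), dtype=bool)
        m[10, 0:250] = True
        m[30, 0:250] = True  # 500 px inside a 200x200 frame? place rows inside
        m = np.zeros((300, 300), dtype=bool)
        m[10, 50:250] = True
        m[30, 50:250] = True
        m[50, 50:150] = True  # 200+200+100 = 500 px in frame rows 0:200, cols 50:250
        frame = CountingFrame("roi", 0, 0, 50, 200, 200)
        rec = compute_density(skel(m), [frame], "pixel_count")[0]
        assert rec.frame_area_mm2 == pytest.approx(0.04)
        assert rec.axon_length_um == pytest.approx(500.0)
        assert rec.density_um_per_mm2 == pytest.approx(12_500.0)

    def test_empty_frame_zero_density(self):
        m = np.zeros((100, 100), dtype=bool)
        rec = compute_density(skel(m), [CountingFrame("r", 0, 0, 0, 50, 50)])[0]
        assert rec.density_um_per_mm2 == 0.0

    def test_frame_outside_raster_rejected(self):
        m = np.zeros((100, 100), dtype=bool)
        with pytest.raises(ValueError, match="outside"):
            compute_density(skel(m), [CountingFrame("r", 0, 90, 90, 50, 50)])

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        base = np.zeros((200, 200), dtype=bool)
        base[60, 20:120] = True
        base[80:120, 70] = True
        shift = 31
        shifted = np.roll(base, (shift, shift), axis=(0, 1))
        f0 = CountingFrame("r", 0, 40, 10, 100, 120)
        f1 = CountingFrame("r", 0, 40 + shift, 10 + shift, 100, 120)
        for method in ("pixel_count", "diagonal_corrected"):
            r0 = compute_density(skel(base), [f0], method)[0]
            r1 = compute_density(skel(shifted), [f1], method)[0]
            assert r0.density_um_per_mm2 == pytest.approx(r1.density_um_per_mm2)

    def test_exclusion_region_never_contributes(self):
        """Painting skeleton inside the exclusion zone changes no record."""
        include = np.ones((400, 400), dtype=bool)
        exclude = np.zeros((400, 400), dtype=bool)
        exclude[150:250, 150:250] = True
        roi = RoiSpec("roi", include, exclude)
        frames = place_counting_frames(roi, 4, (100, 100), "grid")
        base = np.zeros((400, 400), dtype=bool)
        base[50, 10:390] = True
        painted = base.copy()
        painted[160:240:4, 160:240] = True  # bundle crossing the exclusion zone
        rec_a = compute_density(skel(base), frames)
        rec_b = compute_density(skel(painted), frames)
        assert rec_a == rec_b
        # whole-ROI density with exclusion applied is also unchanged
        la, _ = roi_density(skel(base), roi)
        lb, _ = roi_density(skel(painted), roi)
        assert la == lb


class TestSummaries:
    def test_mean_and_sem_hand_example(self):
        from atriadense.densitometry import DensityRecord

        recs = [DensityRecord("r", i, d, 1.0, d) for i, d in enumerate([1.0, 2.0, 3.0])]
        (s,) = summarize_density(recs)
        assert s.mean_density == pytest.approx(2.0)
        assert s.sem == pytest.approx(1.0 / np.sqrt(3.0))
        assert s.n_frames == 3

    def test_equal_values_zero_sem_and_descending_order(self):
        from atriadense.densitometry import DensityRecord

        recs = [DensityRecord("lo", i, 5.0, 1.0, 5.0) for i in range(3)]
        recs += [DensityRecord("hi", i, 9.0, 1.0, 9.0) for i in range(3)]
        out = summarize_density(recs)
        assert [s.roi for s in out] == ["hi", "lo"]
        assert out[1].sem == 0.0

    def test_single_frame_roi_rejected(self):
        from atriadense.densitometry import DensityRecord

        with pytest.raises(ValueError, match="SEM"):
            summarize_density([DensityRecord("r", 0, 1.0, 1.0, 1.0)])


class TestHeatmap:
    def test_tile_lengths_conserve_total_pixel_count(self):
        rng = np.random.default_rng(3)
        m = rng.random((300, 500)) < 0.02
        from atriadense.imageproc import BinaryMask, skeletonize

        s = skeletonize(BinaryMask(m, 0.5))
        grid = density_heatmap(s, tile_px=64)
        assert grid.lengths_um.sum() == pytest.approx(
            skeleton_length(s, "pixel_count"), rel=1e-12
        )
        # ragged edge tiles carry their true area
        assert grid.areas_mm2[-1, -1] < grid.areas_mm2[0, 0]
        assert grid.areas_mm2.sum() == pytest.approx(300 * 500 * 0.25 / 1e6)

    def test_uniform_arbor_field_is_flat(self):
        """A spatially homogeneous fine-grained axon process yields a flat map."""
        from atriadense import synthetic_scene as sc
        from atriadense.imageproc import PreprocConfig
        from atriadense.pipeline_io import segment_image

        p = sc.ArborGrowthParams(
            n_roots=3000, branch_rate_per_um=0.0, max_total_length_um=24_000.0, seed=17
        )
        truth = sc.simulate_arbor(p, bounds_um=(2, 2, 1022, 1022))
        optics = sc.OpticsParams(
            pixel_size_um=2.0, poisson_gain=0.0, gaussian_sigma=0.0,
            illumination_gradient_amplitude=0.0, n_fat_blobs=0, varicosity_gain=1.0,
        )
        raster, truth = sc.render_scene(truth, None, optics, (512, 512))
        s, _ = segment_image(raster, PreprocConfig(background_radius_px=40))
        grid = density_heatmap(s, tile_px=128)
        assert grid.densities.max() / grid.densities.min() <= 1.5

    def test_hotspot_localizes_in_double_density_region(self):
        from atriadense import synthetic_scene as sc
        from atriadense.imageproc import PreprocConfig
        from atriadense.pipeline_io import segment_image

        densities = {"SAN": 2000.0, "AVN": 2000.0, "auricle": 2000.0, "IVC": 4000.0}
        raster, truth, regions = make_scene(
            31, shape_px=(512, 512), densities=densities, cells=None,
            arbor=sc.ArborGrowthParams(mean_arbor_length_um=50.0),
            poisson_gain=0.0, gaussian_sigma=0.0, n_fat_blobs=0,
            varicosity_gain=1.0, illumination_gradient_amplitude=0.0,
        )
        s, _ = segment_image(raster, PreprocConfig(background_radius_px=40))
        grid = density_heatmap(s, tile_px=128)
        # hottest tile must fall in the 2x-density quadrant (bottom-right)
        i, j = np.unravel_index(np.argmax(grid.densities), grid.densities.shape)
        assert i >= 2 and j >= 2

    def test_tile_size_lower_bound(self):
        m = np.zeros((64, 64), dtype=bool)
        with pytest.raises(ValueError):
            density_heatmap(skel(m), tile_px=4)
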