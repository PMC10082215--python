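"""Scene generator: exact length bookkeeping, determinism, rendering."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from atriadense import synthetic_scene as sc
from conftest import make_scene


class TestSimulateArbor:
    def test_straight_limit_single_polyline_of_exact_budget(self):
        p = sc.ArborGrowthParams(
            n_roots=1, persistence=1.0, branch_rate_per_um=0.0,
            max_total_length_um=500.0, step_um=5.0, seed=3,
        )
        truth = sc.simulate_arbor(p)
        assert len(truth.polylines) == 1
        verts = truth.polylines[0][1]
        assert truth.per_region_length_um["scene"] == pytest.approx(500.0, rel=1e-12)
        # collinear: all segments share one direction
        d = np.diff(verts, axis=0)
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        assert np.allclose(d, d[0], atol=1e-9)

    def test_identical_params_and_seed_bit_identical(self):
        p = sc.ArborGrowthParams(branch_rate_per_um=0.02, max_total_length_um=800.0, seed=9)
        t1, t2 = sc.simulate_arbor(p), sc.simulate_arbor(p)
        assert len(t1.polylines) == len(t2.polylines)
        for (r1, v1), (r2, v2) in zip(t1.polylines, t2.polylines):
            assert r1 == r2
            np.testing.assert_array_equal(v1, v2)

    @pytest.mark.parametrize("seed", range(4))
    def test_truth_length_equals_brute_force_resummation(self, seed):
        p = sc.ArborGrowthParams(
            persistence=0.8, branch_rate_per_um=0.03, max_total_length_um=1200.0, seed=seed
        )
        truth = sc.simulate_arbor(p)
        resum = sum(
            float(np.sqrt(((v[1:] - v[:-1]) ** 2).sum(axis=1)).sum())
            for _, v in truth.polylines
        )
        assert truth.per_region_length_um["scene"] == pytest.approx(resum, rel=1e-12)
        assert resum <= p.max_total_length_um + 1e-6

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sc.ArborGrowthParams(step_um=0.0)
        with pytest.raises(ValueError):
            sc.ArborGrowthParams(max_total_length_um=-5)
        with pytest.raises(ValueError):
            sc.ArborGrowthParams(persistence=1.5)


class TestRegionBookkeeping:
    def test_partition_conservation_and_clip_oracle(self):
        _, truth, regions = make_scene(5, shape_px=(256, 256), cells=None)
        total = sum(
            float(np.sqrt(((v[1:] - v[:-1]) ** 2).sum(axis=1)).sum())
            for _, v in truth.polylines
        )
        assert sum(truth.per_region_length_um.values()) == pytest.approx(total, rel=1e-12)
        # continuous clipping against the region rectangles reproduces the truth
        clipped = sc.region_lengths_from_rects(
            truth.polylines, {r.name: r.rect_um for r in regions}
        )
        for name, val in truth.per_region_length_um.items():
            assert clipped[name] == pytest.approx(val, rel=1e-9)

    def test_label_raster_midpoint_sampling_close_to_exact(self):
        _, truth, regions = make_scene(6, shape_px=(256, 256), cells=None)
        px = 2.0
        labels = np.zeros((256, 256), dtype=np.uint8)
        names = {}
        for i, reg in enumerate(regions, start=1):
            x0, y0, x1, y1 = (np.asarray(reg.rect_um) / px).round().astype(int)
            labels[y0:y1, x0:x1] = i
            names[i] = reg.name
        approx = sc.region_lengths_from_labels(truth.polylines, labels, px, names)
        for name, val in truth.per_region_length_um.items():
            if val > 0:
                assert approx[name] == pytest.approx(val, rel=0.02)


class TestRenderScene:
    def _noise_free_optics(self, **kw):
        defaults = dict(
            pixel_size_um=1.0, background_level=20.0, illumination_gradient_amplitude=0.0,
            poisson_gain=0.0, gaussian_sigma=0.0, n_fat_blobs=0,
        )
        defaults.update(kw)
        return sc.OpticsParams(**defaults)

    def test_clean_straight_axon_support_and_background(self):
        p = sc.ArborGrowthParams(persistence=1.0, branch_rate_per_um=0.0,
                                 max_total_length_um=100.0, step_um=5.0, seed=1)
        truth = sc.simulate_arbor(p)
        # shift the polyline into the frame center
        truth.polylines = [(r, v + 64.0) for r, v in truth.polylines]
        optics = self._noise_free_optics()
        raster, truth = sc.render_scene(truth, None, optics, (128, 128))
        fg = np.argwhere(raster.pixels > optics.background_level)
        assert len(fg) > 0
        verts = truth.polylines[0][1]
        sigma_px = np.hypot(optics.psf_sigma_um, 1.0)  # axon width 1 um at 1 um/px
        from shapely.geometry import LineString, Point

        line = LineString(verts)
        dmax = max(line.distance(Point(c, r)) for r, c in fg)
        assert dmax <= 4.0 * sigma_px
        # far background is exactly the base level
        far = raster.pixels[:40, :40]
        assert np.all(far == optics.background_level)

    def test_noiseless_render_deterministic(self):
        p = sc.ArborGrowthParams(max_total_length_um=300.0, seed=2)
        truth = sc.simulate_arbor(p)
        truth.polylines = [(r, v + 100.0) for r, v in truth.polylines]
        optics = self._noise_free_optics(illumination_gradient_amplitude=0.1, n_fat_blobs=3)
        r1, _ = sc.render_scene(truth, None, optics, (200, 200))
        r2, _ = sc.render_scene(truth, None, optics, (200, 200))
        np.testing.assert_array_equal(r1.pixels, r2.pixels)

    def test_noise_mean_converges_to_noiseless_render(self):
        p = sc.ArborGrowthParams(max_total_length_um=120.0, seed=4)
        truth = sc.simulate_arbor(p)
        truth.polylines = [(r, v + 32.0) for r, v in truth.polylines]
        # amplitude kept clear of the 8-bit ceiling so clipping cannot bias
        clean_optics = self._noise_free_optics(axon_intensity=80.0)
        clean, _ = sc.render_scene(truth, None, clean_optics, (64, 64))
        noisy_optics = self._noise_free_optics(
            axon_intensity=80.0, poisson_gain=0.5, gaussian_sigma=2.0
        )
        acc = np.zeros((64, 64))
        acc2 = np.zeros((64, 64))
        n = 200
        for i in range(n):
            r, _ = sc.render_scene(truth, None, noisy_optics, (64, 64), noise_seed=10_000 + i)
            acc += r.pixels
            acc2 += r.pixels.astype(float) ** 2
        mean = acc / n
        sem = np.sqrt(np.clip(acc2 / n - mean**2, 1e-9, None) / (n - 1))
        # quantization of the clean reference contributes up to 0.5
        frac_ok = np.mean(np.abs(mean - clean.pixels) <= 3.0 * sem + 0.5)
        assert frac_ok >= 0.98

    def test_overflow_clips_with_warning(self):
        p = sc.ArborGrowthParams(max_total_length_um=50.0, step_um=5.0, seed=0)
        truth = sc.simulate_arbor(p)
        truth.polylines = [(r, v + 32.0) for r, v in truth.polylines]
        optics = self._noise_free_optics(axon_intensity=5000.0)
        with pytest.warns(UserWarning, match="clipping"):
            raster, _ = sc.render_scene(truth, None, optics, (64, 64))
        assert raster.pixels.max() == 255


class TestCellPopulations:
    def test_class_separability_of_generated_diameters(self):
        _, truth, _ = make_scene(
            7, shape_px=(256, 256),
            cells=sc.CellPopulationParams(n_principal=40, sif_cluster_count=6),
        )
        sif = [c.diameter_um for c in truth.soma_inventory if c.cell_class == "SIF"]
        pri = [c.diameter_um for c in truth.soma_inventory if c.cell_class == "principal"]
        assert sif and pri
        assert max(sif) < 10.0
        assert min(pri) >= 14.0
        assert all(c.th_positive for c in truth.soma_inventory if c.cell_class == "SIF")

    def test_sif_cluster_sizes_within_range(self):
        cells = sc.CellPopulationParams(n_principal=0, sif_cluster_count=10)
        _, truth, _ = make_scene(8, shape_px=(256, 256), cells=cells)
        n_sif = sum(1 for c in truth.soma_inventory if c.cell_class == "SIF")
        assert 3 * 10 <= n_sif <= 8 * 10

    def test_invalid_cell_params_rejected(self):
        with pytest.raises(ValueError):
            sc.CellPopulationParams(sif_diameter_um=12.0)
        with pytest.raises(ValueError):
            sc.CellPopulationParams(th_positive_fraction=1.5)
        with pytest.raises(ValueError):
            sc.CellPopulationParams(sif_intensity_gain=0.9)


class TestFixtureRoundTrip:
    def test_export_import_reproduces_truth_exactly(self, tmp_path):
        raster, truth, _ = make_scene(9, shape_px=(128, 128))
        paths = sc.export_fixture(truth, raster, tmp_path / "fx")
        raster2, truth2 = sc.import_fixture(tmp_path / "fx")
        np.testing.assert_array_equal(raster.pixels, raster2.pixels)
        assert truth2.per_region_length_um == truth.per_region_length_um
        assert len(truth2.polylines) == len(truth.polylines)
        for (r1, v1), (r2, v2) in zip(truth.polylines, truth2.polylines):
            assert r1 == r2
            np.testing.assert_array_equal(v1, v2)
        assert [dataclasses.astuple(c) for c in truth2.soma_inventory] == [
            dataclasses.astuple(c) for c in truth.soma_inventory
        ]

    def test_swc_export_of_y_tree(self, tmp_path):
        nodes = np.array([[0.0, 0.0], [0.0, 10.0], [-5.0, 20.0], [5.0, 20.0]])
        arbor = sc.Arbor(nodes, np.array([-1, 0, 1, 1]))
        sc.write_swc(tmp_path / "y.swc", [arbor])
        from atriadense.morpho_cyto import branched_structure_analysis, parse_swc

        res = branched_structure_analysis(parse_swc((tmp_path / "y.swc").read_text()))
        assert (res.n_trees, res.n_nodes, res.n_terminals) == (1, 1, 2)

    def test_exported_region_lengths_feed_densitometry_truth(self, tmp_path):
        raster, truth, regions = make_scene(10, shape_px=(128, 128), cells=None)
        sc.export_fixture(truth, raster, tmp_path / "fx")
        _, truth2 = sc.import_fixture(tmp_path / "fx")
        for reg in regions:
            want = truth.per_region_length_um[reg.name] / reg.area_mm2()
            got = truth2.per_region_length_um[reg.name] / reg.area_mm2()
            assert got == pytest.approx(want, rel=1e-12)


def test_named_streams_isolate_axon_geometry():
    """Adding cells/fat distractors must not perturb axon polylines."""
    _, t_plain, _ = make_scene(12, shape_px=(128, 128), cells=None, n_fat_blobs=0)
    _, t_full, _ = make_scene(12, shape_px=(128, 128),
                              cells=sc.CellPopulationParams(n_principal=10))
    assert len(t_plain.polylines) == len(t_full.polylines)
    for (r1, v1), (r2, v2) in zip(t_plain.polylines, t_full.polylines):
        np.testing.assert_array_equal(v1, v2)
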