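"""Landscape geometry construction and the synthetic succession generator."""

import math

import numpy as np
import pytest

from metapatch.geometry import (DEFAULT_PIXEL_PITCH, LandscapeGeometry, ROI,
                                build_geometry, virtual_masks)
from metapatch.pipeline import process_stack
from metapatch.synthetic import (SyntheticParams, render_images,
                                 simulate_succession)


class TestGeometry:
    def test_patchy_has_85_patches_and_corridors(self):
        g = build_geometry("patchy")
        assert g.n_patches == 85
        assert len(g.corridor_rois) == 85

    def test_patch_pixel_size_at_camera_calibration(self):
        g = build_geometry("patchy", pixel_pitch=DEFAULT_PIXEL_PITCH)
        roi = g.patch_rois[0]
        assert roi.x1 - roi.x0 == 112           # round(100 um / 0.896 um)
        assert roi.y1 - roi.y0 == 112
        assert g.pixel_area == pytest.approx(0.803, abs=0.001)

    def test_flat_strip_spans_85_motifs(self):
        g = build_geometry("flat", pixel_pitch=2.0)
        strip = g.strip_roi
        motif_px = round(100 / 2.0) + round(50 / 2.0)
        assert strip.x1 - strip.x0 == 85 * motif_px     # 12750 um total
        assert strip.y1 - strip.y0 == 50                # 100 um tall

    def test_masks_pairwise_disjoint(self):
        g = build_geometry("patchy", pixel_pitch=5.0)
        label = g.to_label_image()
        # disjointness means each pixel got exactly one code
        n_px = sum(r.n_pixels for r in g.patch_rois + g.corridor_rois)
        assert (label > 0).sum() == n_px

    def test_virtual_masks_match_real_footprint(self):
        flat = build_geometry("flat", pixel_pitch=2.0)
        vm = virtual_masks(flat)
        real = build_geometry("patchy", pixel_pitch=2.0)
        assert vm.n_patches == 85
        assert vm.patch_rois[0].n_pixels == real.patch_rois[0].n_pixels
        assert vm.corridor_rois[0].n_pixels == real.corridor_rois[0].n_pixels

    def test_short_strip_rejected(self):
        flat = build_geometry("flat", pixel_pitch=2.0)
        flat.strip_roi = ROI(0, 50, 0, 100)
        with pytest.raises(ValueError):
            virtual_masks(flat)

    def test_json_round_trip(self, tmp_path):
        g = build_geometry("patchy", pixel_pitch=5.0)
        g.to_json(tmp_path / "geo.json")
        g2 = LandscapeGeometry.from_json(tmp_path / "geo.json")
        assert g2.patch_rois == g.patch_rois
        assert g2.corridor_rois == g.corridor_rois
        assert g2.shape == g.shape

    def test_label_image_round_trip(self):
        g = build_geometry("patchy", pixel_pitch=5.0)
        g2 = LandscapeGeometry.from_label_image(g.to_label_image(),
                                                pixel_pitch=5.0)
        assert g2.patch_rois == g.patch_rois


class TestSuccession:
    GEO = build_geometry("patchy", pixel_pitch=7.168)

    def test_colonizer_arrivals_strictly_increasing(self):
        truth = simulate_succession(SyntheticParams(), self.GEO)
        assert np.all(np.diff(truth.colonizer_arrival) > 0)

    def test_colonizer_precedes_competitor_everywhere(self):
        truth = simulate_succession(SyntheticParams(), self.GEO)
        assert np.all(truth.colonizer_arrival <= truth.competitor_arrival)

    def test_unblocked_front_arrival_arithmetic(self):
        p = SyntheticParams(p_block=0.0)
        truth = simulate_succession(p, self.GEO)
        expected = p.entry_delay + 85 / p.front_speed
        assert truth.competitor_arrival[-1] == pytest.approx(expected)

    def test_permanent_block_fragments_landscape(self):
        p = SyntheticParams(p_block=1.0, p_block_permanent=1.0)
        truth = simulate_succession(p, self.GEO,
                                    rng=np.random.default_rng(0))
        # front is stopped at the first corridor forever
        assert np.isfinite(truth.competitor_arrival[0])
        assert np.isinf(truth.competitor_arrival[1:]).all()
        assert truth.P[1:].max() == 0.0
        # colonizer keeps the distal patches
        assert truth.E[40:, -1].min() > 0.3

    def test_occupancies_bounded(self):
        truth = simulate_succession(SyntheticParams(), self.GEO,
                                    rng=np.random.default_rng(5))
        for arr in (truth.E, truth.P, truth.corridor_E, truth.corridor_P):
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_zero_speed_warns(self):
        with pytest.warns(UserWarning):
            simulate_succession(SyntheticParams(wave_speed=0.0), self.GEO)

    def test_flat_geometry_disables_blockage(self):
        flat = build_geometry("flat", pixel_pitch=7.168)
        p = SyntheticParams(p_block=1.0, p_block_permanent=1.0)
        truth = simulate_succession(p, flat, rng=np.random.default_rng(0))
        assert truth.blockages == []
        assert np.isfinite(truth.competitor_arrival).all()


class TestRender:
    def test_same_seed_bit_identical(self, coarse_geometry, short_synth_params):
        truth = simulate_succession(short_synth_params, coarse_geometry,
                                    rng=np.random.default_rng(2))
        s1, _ = render_images(truth, coarse_geometry,
                              rng=np.random.default_rng(9))
        s2, _ = render_images(truth, coarse_geometry,
                              rng=np.random.default_rng(9))
        assert np.array_equal(s1.frames, s2.frames)

    def test_empty_truth_renders_pure_background(self, coarse_geometry):
        p = SyntheticParams(horizon=1.0, wave_amplitude=0.0,
                            occupancy_jitter=0.0)
        truth = simulate_succession(p, coarse_geometry,
                                    rng=np.random.default_rng(1))
        stack, _ = render_images(truth, coarse_geometry,
                                 rng=np.random.default_rng(1))
        table = process_stack(stack, coarse_geometry, background_radius=10)
        # mean+3SD threshold leaves a sub-percent false-positive rate
        assert table.E.mean() < 0.01
        assert table.P.mean() < 0.01
        assert table.E.max() < 0.03

    def test_noiseless_round_trip_is_exact(self, coarse_geometry):
        p = SyntheticParams(horizon=2.0, bg_sd=0.0, occupancy_jitter=0.0)
        truth = simulate_succession(p, coarse_geometry,
                                    rng=np.random.default_rng(3))
        stack, quant = render_images(truth, coarse_geometry, params=p,
                                     rng=np.random.default_rng(4))
        table = process_stack(stack, coarse_geometry,
                              correct_background=False)
        assert np.array_equal(table.E, quant.E)
        assert np.array_equal(table.P, quant.P)
        assert np.array_equal(table.corridor_E, quant.corridor_E)

    def test_full_patch_reads_back_as_one(self, coarse_geometry):
        p = SyntheticParams(horizon=0.5, bg_sd=0.0, occupancy_jitter=0.0)
        truth = simulate_succession(p, coarse_geometry,
                                    rng=np.random.default_rng(3))
        truth.E[:, :] = 1.0
        stack, _ = render_images(truth, coarse_geometry, params=p,
                                 rng=np.random.default_rng(4))
        # explicit cell-free control: the first frame is no longer empty
        control = np.full((2, 500), p.bg_mean)
        table = process_stack(stack, coarse_geometry, control=control,
                              correct_background=False)
        assert np.all(table.E == 1.0)


class TestEnsembleShape:
    """Landscape-scale signature of blockage in the generated ensembles."""

    def _ensemble_theta(self, p_block, seed=7, n=16):
        from metapatch.pipeline import ensemble_average, spatial_average

        par = SyntheticParams(p_block=p_block)
        rng = np.random.default_rng(seed)
        geo = build_geometry("patchy", pixel_pitch=7.168)
        tabs = [simulate_succession(par, geo, rng=rng, landscape=s).to_table()
                for s in range(n)]
        return ensemble_average([spatial_average(t) for t in tabs])

    def test_blockage_produces_rise_then_relaxation(self):
        theta = self._ensemble_theta(p_block=0.03)
        peak = np.nanmax(theta)
        assert peak > theta[-1] + 0.002      # partial relaxation after peak
        assert np.nanargmax(theta) < len(theta) - 6

    def test_no_blockage_is_monotone_nondecreasing(self):
        theta = self._ensemble_theta(p_block=0.0)
        assert np.nanmax(theta) <= theta[-1] + 0.002
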