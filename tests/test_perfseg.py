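"""Perfusion-image segmentation stages: normalization, baseline, polar
edges, PCA washout, active contours, slice propagation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import SLICES, dice
from mbfseg import geometry
from mbfseg import perfseg as ps
from mbfseg.core import Condition, Contour, PerfusionSeries, SliceLocation
from mbfseg.errors import (ArrivalNotFound, DegenerateContour,
                           GrowthOverflow, InsufficientFrames, LVNotFound,
                           NoEdgeFound)
from mbfseg.landmarks import detect_ventricles
from mbfseg.phantom import PhantomConfig, SliceGeometry, generate_phantom

BASE, MID, APEX = SliceLocation.BASE, SliceLocation.MID, SliceLocation.APEX
REST = Condition.REST


def _series(frames):
    return PerfusionSeries(BASE, np.asarray(frames, dtype=float))


class TestTemporalNormalize:
    def test_minmax_scaling_per_pixel(self):
        frames = np.full((12, 1, 1), 2.0)
        frames[:3, 0, 0] = [2, 4, 6]
        out = ps.temporal_normalize(_series(frames)).frames[:3, 0, 0]
        assert np.allclose(out, [0, 0.5, 1.0], atol=1e-5)

    def test_constant_pixel_maps_to_zero(self):
        frames = np.full((12, 2, 2), 5.0)
        frames[:, 0, 0] = np.linspace(0, 10, 12)  # sets a global range
        out = ps.temporal_normalize(_series(frames))
        assert np.allclose(out.frames[:, 1, 1], 0.0)

    def test_weak_enhancement_amplified_to_full_range(self):
        # a hypoperfused pixel with 10% of the healthy enhancement still
        # normalizes to peak 1 — the stated purpose of the step
        frames = np.zeros((12, 1, 2))
        curve = np.concatenate([np.zeros(4), np.linspace(0, 1, 8)])
        frames[:, 0, 0] = 10 * curve
        frames[:, 0, 1] = 1 * curve
        out = ps.temporal_normalize(_series(frames))
        assert out.frames[:, 0, 1].max() == pytest.approx(1.0, abs=1e-4)
        assert np.allclose(out.frames[:, 0, 0], out.frames[:, 0, 1],
                           atol=1e-4)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.1, 50), st.floats(-100, 100))
    def test_invariant_to_per_pixel_affine_rescaling(self, a, b):
        rng = np.random.default_rng(3)
        frames = rng.random((15, 6, 6))
        n1 = ps.temporal_normalize(_series(frames)).frames
        n2 = ps.temporal_normalize(_series(a * frames + b)).frames
        assert np.allclose(n1, n2, atol=1e-4)


class TestBaselineImage:
    def test_windowing_uses_frames_before_arrival(self):
        frames = np.zeros((20, 2, 2))
        frames[:, 0, 0] = np.arange(20)  # marker pixel equals frame index
        series = _series(frames)
        lv_curve = np.concatenate([np.zeros(8), np.full(12, 10.0)])
        lv_curve[:3] += [0.0, 0.01, -0.01]  # baseline sd > 0
        out = ps.baseline_image(series, lv_curve)
        # arrival at frame 8 -> mean of marker over frames 0..7 = 3.5
        assert out[0, 0] == pytest.approx(np.arange(8).mean())

    def test_flat_lv_curve_raises(self):
        series = _series(np.random.default_rng(0).random((20, 4, 4)))
        with pytest.raises(ArrivalNotFound):
            ps.baseline_image(series, np.ones(20))

    def test_phantom_myocardium_darker_than_background(self, noisy_study):
        tr = noisy_study.truth[BASE]
        s = noisy_study.series[(BASE, REST)]
        norm = ps.temporal_normalize(s)
        lv_curve = s.frames[:, tr.lv_mask].mean(axis=1)
        base = ps.baseline_image(norm, lv_curve)
        bg = ~(tr.myo_mask | tr.lv_mask | tr.rv_mask)
        assert base[tr.myo_mask].mean() < base[bg].mean()


class TestPolarTransform:
    def test_constant_image_stays_constant(self):
        pol = ps.polar_transform(np.full((32, 32), 3.3), (16, 16))
        assert np.allclose(pol.values, 3.3)

    def test_disk_transition_at_expected_radius_bin(self):
        img = np.zeros((64, 64))
        rr, cc = np.mgrid[0:64, 0:64]
        img[np.hypot(rr - 32, cc - 32) <= 10] = 1.0
        pol = ps.polar_transform(img, (32, 32), 360, 56, 28.0)
        transition = (pol.values < 0.5).argmax(axis=1)
        expected = int(10 / pol.radius_bin_px)
        assert np.all(np.abs(transition - expected) <= 1)

    def test_inverse_consistency_on_smooth_image(self):
        rr, cc = np.mgrid[0:64, 0:64]
        img = np.sin(rr / 10.0) + np.cos(cc / 7.0)
        pol = ps.polar_transform(img, (32, 32), 360, 56, 28.0)
        back = ps.polar_inverse(pol, (64, 64))
        inside = np.hypot(rr - 32, cc - 32) < 26
        err = np.abs(back - img)[inside].mean()
        assert err < 0.02 * (img.max() - img.min())


class TestGrowLV:
    def test_noiseless_phantom_lv_recovered(self, noiseless_study):
        tr = noiseless_study.truth[BASE]
        s = noiseless_study.series[(BASE, REST)]
        v = detect_ventricles(s)
        grown = ps.grow_lv(s, v.lv_mask, v.peak_lv_frame)
        assert dice(grown, tr.lv_mask) >= 0.95

    def test_papillary_notch_included_by_hull(self):
        # a dark papillary muscle inside the cavity ends up inside the hull
        frames = np.ones((12, 32, 32))
        rr, cc = np.mgrid[0:32, 0:32]
        lv = np.hypot(rr - 16, cc - 16) <= 8
        frames[6][lv] = 10.0
        notch = (np.abs(rr - 16) <= 1) & (np.abs(cc - 16) <= 1)
        frames[6][notch] = 1.0
        seed = np.hypot(rr - 16, cc - 10) <= 1.5  # off-centre seed in pool
        grown = ps.grow_lv(_series(frames), seed, 6)
        assert grown[notch].all()

    def test_uniform_image_overflows(self):
        frames = np.ones((12, 32, 32))
        seed = np.zeros((32, 32), dtype=bool)
        seed[16, 16] = True
        with pytest.raises(GrowthOverflow):
            ps.grow_lv(_series(frames), seed, 0)


class TestDetectEpicardialEdge:
    def _rv_free_study(self):
        geo = {BASE: SliceGeometry((32.0, 32.0), 10.0, 16.0, False),
               MID: SliceGeometry((32.0, 32.0), 9.0, 14.5, False),
               APEX: SliceGeometry((32.0, 32.0), 7.0, 11.5, False)}
        return generate_phantom(PhantomConfig(
            geometry=geo, noise_sd=0.0, mbf_noise_sd=0.0, rng_seed=1))

    def test_noiseless_annulus_recovered_within_two_px(self):
        study = self._rv_free_study()
        tr = study.truth[BASE]
        s = study.series[(BASE, REST)]
        norm = ps.temporal_normalize(s)
        base = ps.baseline_image(norm, s.frames[:, tr.lv_mask].mean(axis=1))
        pol = ps.polar_transform(base, (32, 32), 360, 56, 28.0)
        edge = ps.detect_epicardial_edge(pol, 10.0)
        assert np.abs(edge.radius_px - 16.0).max() <= 2.0

    def test_deleted_arc_flagged_extended_and_interpolated(self):
        vals = np.zeros((360, 56))
        radii = (np.arange(56) + 0.5) * 0.5
        vals[:, radii > 16.0] = 1.0
        vals[100:190, :] = 0.0          # kill the edge over a 90 deg arc
        pol = ps.PolarImage(vals, (32, 32), 360, 56, 28.0)
        edge = ps.detect_epicardial_edge(pol, 10.0)
        assert not edge.detected[115:175].any()
        assert np.abs(edge.radius_px[100:190] - 16.0).max() <= 3.0

    def test_pure_noise_raises_no_edge_found(self):
        rng = np.random.default_rng(11)
        pol = ps.PolarImage(rng.standard_normal((360, 56)), (32, 32),
                            360, 56, 28.0)
        with pytest.raises(NoEdgeFound):
            ps.detect_epicardial_edge(pol, 10.0)


class TestPCAWashout:
    def test_rank_one_series_recovers_spatial_pattern(self):
        rng = np.random.default_rng(5)
        f = rng.random((16, 16))
        scales = np.array([3.0, 2.2, 1.5, 1.0, 0.6])
        frames = np.concatenate([np.zeros((10, 16, 16)),
                                 scales[:, None, None] * f[None]])
        out = ps.pca_washout_image(_series(frames), 9)
        cos = np.dot(out.ravel(), f.ravel()) / (
            np.linalg.norm(out) * np.linalg.norm(f))
        assert abs(cos) >= 0.999

    def test_contrast_to_noise_beats_typical_washout_frame(self,
                                                           noisy_study):
        # the leading component concentrates coherent kinetics: its
        # myo/background contrast-to-noise far exceeds that of a typical
        # (median) washout frame
        tr = noisy_study.truth[BASE]
        s = noisy_study.series[(BASE, REST)]
        peak = int(np.argmax(s.frames[:, tr.lv_mask].mean(axis=1)))
        out = ps.pca_washout_image(s, peak)
        bg = ~(tr.myo_mask | tr.lv_mask | tr.rv_mask)

        def cnr(img):
            return abs(img[tr.myo_mask].mean() - img[bg].mean()) / max(
                img[bg].std(), 1e-12)

        singles = [cnr(f) for f in s.frames[peak + 1:]]
        assert cnr(out) >= np.median(singles)

    def test_too_few_washout_frames(self):
        frames = np.random.default_rng(0).random((12, 8, 8))
        with pytest.raises(InsufficientFrames):
            ps.pca_washout_image(_series(frames), 9)


class TestActiveContour:
    def _disk_image(self, radius=15.0):
        rr, cc = np.mgrid[0:64, 0:64]
        return (np.hypot(rr - 32, cc - 32) <= radius).astype(float)

    def test_contour_on_edge_barely_moves(self):
        img = self._disk_image()
        init = Contour(geometry.disk_contour((32, 32), 15.0, 120))
        out = ps.refine_active_contour(init, img)
        moved = np.linalg.norm(out.points - init.points, axis=1).mean()
        assert moved < 0.5

    def test_contour_inside_converges_onto_edge(self):
        img = self._disk_image()
        init = Contour(geometry.disk_contour((32, 32), 12.0, 120))
        out = ps.refine_active_contour(init, img)
        r = np.hypot(out.points[:, 0] - 32, out.points[:, 1] - 32)
        assert abs(r.mean() - 15.0) <= 1.0

    def test_no_image_force_collapses_to_degenerate(self):
        img = self._disk_image()
        init = Contour(geometry.disk_contour((32, 32), 15.0, 120))
        params = ps.SnakeParams(w_edge=0.0, alpha=5.0, step=1.0,
                                max_iter=1000, tol=0.0)
        with pytest.raises(DegenerateContour):
            ps.refine_active_contour(init, img, params)


class TestPropagateSlice:
    def test_mid_slice_lv_recovered(self, noiseless_study):
        s0 = noiseless_study.series[(BASE, REST)]
        v0 = detect_ventricles(s0)
        s1 = noiseless_study.series[(MID, REST)]
        v1 = ps.propagate_slice(v0, s0, s1)
        assert dice(v1.lv_mask, noiseless_study.truth[MID].lv_mask) >= 0.9

    def test_apex_without_rv_continues_and_segments(self, noiseless_study):
        prev_v = detect_ventricles(noiseless_study.series[(BASE, REST)])
        prev_s = noiseless_study.series[(BASE, REST)]
        for loc in (MID, APEX):
            s = noiseless_study.series[(loc, REST)]
            v = ps.propagate_slice(prev_v, prev_s, s)
            prev_v, prev_s = v, s
        assert v.rv_mask is None
        seg = ps.segment_perfusion_slice(prev_s, v)
        assert seg.myo_mask.any()

    def test_uncorrelated_noise_raises_lv_not_found(self, noiseless_study):
        s0 = noiseless_study.series[(BASE, REST)]
        v0 = detect_ventricles(s0)
        rng = np.random.default_rng(9)
        noise = PerfusionSeries(MID, rng.random(s0.frames.shape))
        with pytest.raises(LVNotFound):
            ps.propagate_slice(v0, s0, noise)


class TestSegmentPerfusionSlice:
    def test_noiseless_dice_all_slices(self, noiseless_study):
        prev_v = detect_ventricles(noiseless_study.series[(BASE, REST)])
        prev_s = noiseless_study.series[(BASE, REST)]
        for loc in SLICES:
            s = noiseless_study.series[(loc, REST)]
            v = prev_v if loc == BASE else ps.propagate_slice(
                prev_v, prev_s, s)
            seg = ps.segment_perfusion_slice(s, v)
            assert dice(seg.myo_mask,
                        noiseless_study.truth[loc].myo_mask) >= 0.85
            prev_v, prev_s = v, s

    def test_endo_inside_epi_invariant(self, noisy_study):
        from shapely.geometry import Point, Polygon

        v = detect_ventricles(noisy_study.series[(BASE, REST)])
        seg = ps.segment_perfusion_slice(noisy_study.series[(BASE, REST)], v)
        poly = Polygon(seg.epi.points)
        assert all(poly.covers(Point(p)) for p in seg.endo.points)
        # myo mask excludes the cavity
        assert not (seg.myo_mask
                    & seg.endo.mask(seg.myo_mask.shape)).any()

    def test_deterministic_for_same_inputs(self, noisy_study):
        s = noisy_study.series[(BASE, REST)]
        v = detect_ventricles(s)
        a = ps.segment_perfusion_slice(s, v)
        b = ps.segment_perfusion_slice(s, v)
        assert np.array_equal(a.endo.points, b.endo.points)
        assert np.array_equal(a.epi.points, b.epi.points)
        assert np.array_equal(a.myo_mask, b.myo_mask)
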