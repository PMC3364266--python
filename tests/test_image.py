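"""Image-domain processing: unwrap, segmentation, rims, background, flow."""

import numpy as np
import pytest

from csfpulse import (
    DegenerateImageError,
    RoiPolygon,
    SegmentationMask,
    VelocityImageSeries,
    compute_flow,
    correct_background,
    otsu_threshold,
    rim_check,
    segment_compartment,
    segment_spinal_frequency,
    unwrap_velocity,
)
from csfpulse.synthetic import GeometrySpec, generate_waveform, synthesize_velocity_series
from csfpulse.templates import default_template


def make_series(phase, magnitude=None, venc=100.0, pixel_mm=(1.0, 1.0), wrapped=True):
    phase = np.asarray(phase, dtype=float)
    if magnitude is None:
        magnitude = np.ones_like(phase)
    return VelocityImageSeries(
        phase=phase,
        magnitude=magnitude,
        venc_cm_s=venc,
        pixel_mm=pixel_mm,
        frame_times_ms=np.arange(phase.shape[0]) * 25.0,
        wrapped=wrapped,
    )


def brute_force_otsu(image):
    """Exhaustive 256-level sweep maximizing between-class variance; ties
    (an empty plateau between well-separated modes) resolve to the middle
    candidate."""
    image = np.asarray(image, dtype=float).ravel()
    lo, hi = image.min(), image.max()
    edges = np.linspace(lo, hi, 257)
    centers = (edges[:-1] + edges[1:]) / 2.0
    scores = []
    for t in centers:
        below, above = image[image <= t], image[image > t]
        if below.size == 0 or above.size == 0:
            scores.append(-np.inf)
            continue
        scores.append(below.size * above.size * (below.mean() - above.mean()) ** 2)
    scores = np.asarray(scores)
    best = np.flatnonzero(scores >= scores.max() * (1 - 1e-12))
    return centers[best[(len(best) - 1) // 2]]


class TestUnwrap:
    def test_aliased_pixel_sequence_recovered(self):
        # true velocities [80, 130, 90] at venc 100 store as [80, -70, 90]
        phase = np.array([80.0, -70.0, 90.0]).reshape(3, 1, 1)
        ser = make_series(phase)
        out = unwrap_velocity(ser)
        assert np.allclose(out.phase.ravel(), [80.0, 130.0, 90.0])

    def test_smooth_low_velocities_unchanged(self):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-40, 40, (6, 4, 4))
        phase.sort(axis=0)  # smooth in time
        out = unwrap_velocity(make_series(phase))
        assert np.allclose(out.phase, phase)

    def test_constant_sequence_identity(self):
        phase = np.full((5, 3, 3), 33.0)
        out = unwrap_velocity(make_series(phase))
        assert np.allclose(out.phase, phase)

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        phase = rng.uniform(-99, 99, (8, 5, 5))
        once = unwrap_velocity(make_series(phase))
        twice = unwrap_velocity(once)
        assert np.allclose(once.phase, twice.phase)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            unwrap_velocity(make_series(np.zeros((1, 3, 3))))


class TestOtsu:
    def test_bimodal_separation(self):
        img = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        t = otsu_threshold(img)
        assert 0.0 < t < 10.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_sweep(self, seed):
        rng = np.random.default_rng(seed)
        img = np.concatenate([
            rng.normal(0.0, 5.0, 5000), rng.normal(100.0, 5.0, 5000)
        ])
        t = otsu_threshold(img)
        assert t == pytest.approx(brute_force_otsu(img), abs=(img.max() - img.min()) / 128)
        assert 25.0 < t < 75.0

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((8, 8), 7.0))


class TestSegmentation:
    def _disk_series(self, radius=5.0, n=8, shape=(40, 40), per_frame_radius=None):
        w = generate_waveform(default_template("aqueduct", "young"), 900.0)
        geo = GeometrySpec(
            shape=shape, center=(20.0, 20.0),
            radius_px=per_frame_radius if per_frame_radius is not None else radius,
            pixel_mm=(0.5, 0.5), venc_cm_s=15.0,
        )
        return synthesize_velocity_series(w, geo, n_frames=max(n, 22), seed=2)

    def test_bright_disk_area_recovered(self):
        ser = self._disk_series(radius=5.0)
        roi = RoiPolygon.rectangle(8, 8, 32, 32)
        mask = segment_compartment(ser, roi, mode="single_frame")
        constructed = ser.meta["true_masks"][0].sum()
        assert mask.masks.sum() == pytest.approx(constructed, rel=0.10)
        assert mask.masks.sum() == pytest.approx(np.pi * 25.0, rel=0.15)

    def test_per_frame_masks_track_radius(self):
        radii = np.tile([4.0, 6.0], 11)
        ser = self._disk_series(per_frame_radius=radii, n=22)
        roi = RoiPolygon.rectangle(8, 8, 32, 32)
        mask = segment_compartment(ser, roi, mode="per_frame")
        areas = mask.masks.sum(axis=(1, 2))
        for area, r in zip(areas, radii):
            ring = np.pi * ((r + 2) ** 2 - (r - 2) ** 2)  # +-2 px annulus
            assert abs(area - np.pi * r * r) <= ring

    def test_off_lumen_roi_rejected(self):
        ser = self._disk_series()
        roi = RoiPolygon.rectangle(0, 0, 6, 6)
        with pytest.raises(DegenerateImageError):
            segment_compartment(ser, roi, mode="single_frame")


class TestFrequencySegmentation:
    def _pulsatile_series(self, amplitude=3.0, noise=0.3, seed=4):
        rng = np.random.default_rng(seed)
        t = np.arange(32) / 32.0
        phase = rng.normal(0.0, noise, (32, 24, 24))
        truth = np.zeros((24, 24), dtype=bool)
        truth[8:14, 9:15] = True
        phase[:, truth] += amplitude * np.sin(2 * np.pi * t)[:, None]
        return make_series(phase, venc=12.0), truth

    def test_pulsatile_voxels_recovered_exactly(self):
        ser, truth = self._pulsatile_series()
        roi = RoiPolygon.rectangle(2, 2, 22, 22)
        mask = segment_spinal_frequency(ser, roi)
        assert np.array_equal(mask.masks, truth)

    def test_threshold_scale_invariance_under_amplitude_doubling(self):
        ser1, _ = self._pulsatile_series(amplitude=3.0)
        ser2, _ = self._pulsatile_series(amplitude=6.0)
        roi = RoiPolygon.rectangle(2, 2, 22, 22)
        m1 = segment_spinal_frequency(ser1, roi)
        m2 = segment_spinal_frequency(ser2, roi)
        assert np.array_equal(m1.masks, m2.masks)

    def test_all_static_roi_rejected(self):
        rng = np.random.default_rng(5)
        ser = make_series(rng.normal(0, 0.01, (16, 20, 20)), venc=12.0)
        roi = RoiPolygon.rectangle(2, 2, 18, 18)
        with pytest.raises(DegenerateImageError):
            segment_spinal_frequency(ser, roi)

    def test_too_few_frames_rejected(self):
        ser = make_series(np.random.default_rng(0).normal(size=(4, 10, 10)), venc=12.0)
        with pytest.raises(ValueError):
            segment_spinal_frequency(ser, RoiPolygon.rectangle(1, 1, 9, 9))


class TestRimCheck:
    def _phantom(self, noise=0.0):
        w = generate_waveform(default_template("arterial", "young"), 831.0)
        geo = GeometrySpec(shape=(48, 48), center=(24, 24), radius_px=6.0,
                           pixel_mm=(0.8, 0.7), venc_cm_s=100.0)
        ser = synthesize_velocity_series(w, geo, n_frames=32, noise_sd=noise, seed=6)
        return ser, ser.meta["true_masks"][0]

    def test_ground_truth_mask_passes(self):
        ser, truth = self._phantom()
        report = rim_check(ser, SegmentationMask(truth, per_frame=False), noise_sd=0.1)
        assert report.passed
        assert report.suggestion == "keep"

    def test_eroded_mask_fails_with_grow(self):
        from scipy import ndimage as ndi

        ser, truth = self._phantom()
        eroded = ndi.binary_erosion(truth)
        report = rim_check(ser, SegmentationMask(eroded, per_frame=False), noise_sd=0.1)
        assert not report.passed
        assert report.suggestion == "grow"

    def test_single_pixel_mask_rejected(self):
        ser, truth = self._phantom()
        tiny = np.zeros_like(truth)
        tiny[24, 24] = True
        with pytest.raises(DegenerateImageError):
            rim_check(ser, SegmentationMask(tiny, per_frame=False))


class TestBackgroundCorrection:
    def _phantom_with_offset(self, c):
        w = generate_waveform(default_template("aqueduct", "young"), 900.0)
        geo = GeometrySpec(shape=(48, 48), center=(24, 24), radius_px=4.0,
                           pixel_mm=(0.4, 0.4), venc_cm_s=15.0, ramp=(c, 0.0, 0.0))
        ser = synthesize_velocity_series(w, geo, n_frames=24)
        return ser, ser.meta["true_masks"][0]

    def test_uniform_offset_removed_exactly(self):
        clean, truth = self._phantom_with_offset(0.0)
        offset, _ = self._phantom_with_offset(1.5)
        corrected = correct_background(
            offset, SegmentationMask(truth, per_frame=False), "rectangle", (2, 12, 2, 12)
        )
        assert np.allclose(corrected.phase, clean.phase, atol=1e-9)

    def test_zero_offset_identity(self):
        clean, truth = self._phantom_with_offset(0.0)
        corrected = correct_background(
            clean, SegmentationMask(truth, per_frame=False), "contour"
        )
        assert np.allclose(corrected.phase, clean.phase, atol=1e-9)

    def test_reference_overlapping_mask_rejected(self):
        ser, truth = self._phantom_with_offset(1.0)
        with pytest.raises(ValueError):
            correct_background(
                ser, SegmentationMask(truth, per_frame=False), "rectangle", (20, 30, 20, 30)
            )


class TestComputeFlow:
    def test_three_pixel_arithmetic(self):
        # velocities 1/2/3 cm/s (=10/20/30 mm/s) over 1 mm^2 pixels
        phase = np.zeros((1, 4, 4))
        phase[0, 0, :3] = [1.0, 2.0, 3.0]
        ser = make_series(phase, venc=100.0, pixel_mm=(1.0, 1.0))
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :3] = True
        flow = compute_flow(ser, SegmentationMask(mask, per_frame=False))
        assert flow.flow[0] == pytest.approx(0.06)

    def test_zero_velocity_frame(self):
        ser = make_series(np.zeros((2, 4, 4)))
        mask = np.ones((4, 4), dtype=bool)
        flow = compute_flow(ser, SegmentationMask(mask, per_frame=False))
        assert np.allclose(flow.flow, 0.0)

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(8)
        ser = make_series(rng.normal(size=(3, 8, 8)))
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[:4] = True
        b[4:] = True
        fa = compute_flow(ser, SegmentationMask(a, per_frame=False)).flow
        fb = compute_flow(ser, SegmentationMask(b, per_frame=False)).flow
        fab = compute_flow(ser, SegmentationMask(a | b, per_frame=False)).flow
        assert np.allclose(fa + fb, fab)


class TestRoiPolygon:
    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [10, 10], [0, 10], [10, 0]], dtype=float)
        with pytest.raises(ValueError):
            RoiPolygon(bowtie)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            RoiPolygon(np.array([[0, 0], [1, 1]], dtype=float))


def test_magnitude_rescaling_does_not_change_mask():
    w = generate_waveform(default_template("aqueduct", "young"), 900.0)
    geo = GeometrySpec(shape=(40, 40), center=(20, 20), radius_px=5.0,
                       pixel_mm=(0.5, 0.5), venc_cm_s=15.0)
    ser = synthesize_velocity_series(w, geo, n_frames=24, seed=3)
    roi = RoiPolygon.rectangle(8, 8, 32, 32)
    m1 = segment_compartment(ser, roi, mode="single_frame")
    rescaled = VelocityImageSeries(
        phase=ser.phase, magnitude=ser.magnitude * 3.0 + 50.0,
        venc_cm_s=ser.venc_cm_s, pixel_mm=ser.pixel_mm,
        frame_times_ms=ser.frame_times_ms, meta=dict(ser.meta),
    )
    m2 = segment_compartment(rescaled, roi, mode="single_frame")
    assert np.array_equal(m1.masks, m2.masks)
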