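"""Beating-heart video mechanics: segmentation, geometry, volumes, cycles,
strain and velocity-strain loops."""

import numpy as np
import pytest

from fishheart.exceptions import (
    CycleDetectionError,
    EmptyMaskError,
    InvalidParameterError,
    OpenLoopError,
    SegmentationError,
    StageError,
    ZeroDivisionInputError,
)
from fishheart.video import (
    AnalysisConfig,
    BiplaneVideo,
    biplane_volume,
    cycle_indices,
    detect_cycles,
    frame_geometry,
    segment_ventricle,
    strain_velocity_series,
    summarize_heart,
    velocity_strain_loop,
)


def _disk_frame(radius=50, shape=(160, 160), fg=220.0, bg=20.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    return np.where((yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2, fg, bg)


class TestSegmentVentricle:
    def test_disk_area_within_one_percent(self):
        mask = segment_ventricle(_disk_frame(radius=50))
        assert mask.sum() == pytest.approx(np.pi * 50**2, rel=0.01)

    def test_constant_frame_raises(self):
        with pytest.raises(SegmentationError):
            segment_ventricle(np.full((64, 64), 37.0))

    def test_largest_component_retained(self):
        frame = np.full((100, 200), 20.0)
        frame[10:50, 10:35] = 220.0  # 1000 px blob
        frame[70:80, 150:160] = 220.0  # 100 px blob
        mask = segment_ventricle(frame)
        assert 900 <= mask.sum() <= 1150  # only the big blob (closing may pad edges)
        assert not mask[70:80, 150:160].any()


class TestFrameGeometry:
    def test_disk_radii_nearly_uniform(self):
        mask = _disk_frame(radius=50) > 100
        geo = frame_geometry(mask, pixel_size=1.0, n_rays=36)
        cv = np.std(geo.radii) / np.mean(geo.radii)
        assert cv < 0.02

    def test_disk_caliper_length_is_diameter(self):
        mask = _disk_frame(radius=50) > 100
        geo = frame_geometry(mask, pixel_size=1.0)
        assert geo.long_length == pytest.approx(100.0, abs=2.0)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            frame_geometry(np.zeros((10, 10), dtype=bool), 1.0)


class TestBiplaneVolume:
    def test_hand_arithmetic(self):
        assert biplane_volume(3.0, 2.0) == pytest.approx(4.0)

    def test_zero_area_gives_zero(self):
        assert biplane_volume(0.0, 5.0) == 0.0

    def test_negative_input_raises(self):
        with pytest.raises(InvalidParameterError):
            biplane_volume(-1.0, 2.0)

    def test_exact_on_ellipsoid(self):
        # a=b=1, c=1.5 mm: A=pi, L=3 -> V = 2*pi = (4/3) pi a^2 c
        assert biplane_volume(np.pi, 3.0) == pytest.approx(4.0 / 3.0 * np.pi * 1.5)


class TestDetectCycles:
    def test_raised_cosine_three_seconds_gives_six_cycles(self):
        t = np.arange(int(3 * 66)) / 66.0
        v = 2.0 + (1.0 + np.cos(2 * np.pi * 2.0 * t))  # 2 Hz, ED at t=0
        cycles = detect_cycles(v, frame_rate=66.0, pacing_rate=2.0)
        assert len(cycles) == 6

    def test_constant_trace_raises(self):
        with pytest.raises(CycleDetectionError):
            detect_cycles(np.full(200, 3.0), 66.0, 2.0)

    def test_ed_frames_match_generator_truth(self, noiseless_video):
        video, truth = noiseless_video
        cycles = detect_cycles(truth["volume"], video.frame_rate, truth["heart_rate"])
        for cyc, ed_true in zip(cycles, truth["ed_frames"]):
            assert abs(cyc.ed_frame - ed_true) <= 1


class TestCycleIndices:
    def test_hand_arithmetic(self):
        c = cycle_indices(edv=4.0, esv=2.0, l_d=2.0, l_s=1.5, eda=3.0, esa=2.0)
        assert c.ef == pytest.approx(0.5)
        assert c.fs == pytest.approx(0.25)
        assert c.fac == pytest.approx(1.0 / 3.0)

    def test_no_ejection(self):
        c = cycle_indices(edv=4.0, esv=4.0, l_d=2.0, l_s=2.0, eda=3.0, esa=3.0)
        assert c.ef == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionInputError):
            cycle_indices(edv=0.0, esv=0.0, l_d=2.0, l_s=1.0, eda=3.0, esa=2.0)


class TestStrainVelocity:
    def test_analytic_extrema_of_raised_cosine_strain(self):
        # strain s(t) = -0.1 (1 - cos(2 pi 2 t)) / 2 -> max |ds/dt| = 0.1*pi*2
        fs = 500.0
        t = np.arange(int(fs)) / fs
        radii = 1.0 * (1.0 + (-0.1) * (1 - np.cos(2 * np.pi * 2 * t)) / 2)
        sv = strain_velocity_series(radii, fs, ed_frame=0)
        assert abs(sv.max_contraction_velocity) == pytest.approx(0.1 * np.pi * 2, rel=0.02)
        assert sv.max_relaxation_velocity == pytest.approx(0.1 * np.pi * 2, rel=0.02)

    def test_constant_radii_give_zero_strain_and_velocity(self):
        sv = strain_velocity_series(np.full(50, 2.0), 66.0)
        assert np.allclose(sv.strain, 0.0)
        assert np.allclose(sv.velocity, 0.0)

    def test_smoothing_barely_changes_noiseless_extrema(self):
        fs = 500.0
        t = np.arange(int(fs)) / fs
        radii = 1.0 - 0.05 * (1 - np.cos(2 * np.pi * 2 * t))
        raw = strain_velocity_series(radii, fs, ed_frame=0, smooth_window=1)
        smooth = strain_velocity_series(radii, fs, ed_frame=0, smooth_window=7)
        assert smooth.max_relaxation_velocity == pytest.approx(
            raw.max_relaxation_velocity, rel=0.02
        )


class TestVelocityStrainLoop:
    def test_harmonic_loop_area_is_pi_omega_d_squared(self):
        omega = 4 * np.pi
        t = np.linspace(0, 2 * np.pi / omega, 2000, endpoint=False)
        s = 0.1 * np.sin(omega * t)
        v = 0.1 * omega * np.cos(omega * t)
        area = velocity_strain_loop(s, v, closure_tol=0.05)
        assert area == pytest.approx(np.pi * omega * 0.1**2, rel=0.01)

    def test_zero_amplitude_gives_zero_area(self):
        assert velocity_strain_loop(np.zeros(10), np.zeros(10)) == 0.0

    def test_orientation_symmetry(self):
        omega = 4 * np.pi
        t = np.linspace(0, 2 * np.pi / omega, 300, endpoint=False)
        s, v = 0.1 * np.sin(omega * t), 0.1 * omega * np.cos(omega * t)
        assert velocity_strain_loop(s, v) == pytest.approx(
            velocity_strain_loop(s[::-1], v[::-1])
        )

    def test_open_loop_raises(self):
        s = np.linspace(0, 1, 50)  # strain drifts, never closes
        with pytest.raises(OpenLoopError):
            velocity_strain_loop(s, np.ones(50), closure_tol=0.05)

    def test_area_converges_with_sampling_density(self):
        omega = 4 * np.pi
        exact = np.pi * omega * 0.01
        errs = []
        for n in (20, 80, 320):
            t = np.linspace(0, 2 * np.pi / omega, n, endpoint=False)
            s, v = 0.1 * np.sin(omega * t), 0.1 * omega * np.cos(omega * t)
            errs.append(abs(velocity_strain_loop(s, v) - exact))
        assert errs[0] > errs[1] > errs[2]


class TestSummarizeHeart:
    def test_noiseless_ef_within_002(self, noiseless_summary):
        assert noiseless_summary.means["ef"] == pytest.approx(0.5, abs=0.02)
        assert noiseless_summary.n_cycles >= 3

    def test_means_are_arithmetic_means_of_cycles(self, noiseless_summary):
        table = noiseless_summary.cycles.drop(columns=["ed_frame", "es_frame"])
        np.testing.assert_allclose(
            noiseless_summary.means.to_numpy(), table.mean().to_numpy()
        )

    def test_indices_invariant_to_calibration_and_intensity(self, noiseless_video):
        video, _ = noiseless_video
        rescaled = BiplaneVideo(
            plane_long=(video.plane_long.astype(float) * 0.5).astype(np.uint8),
            plane_short=(video.plane_short.astype(float) * 0.5).astype(np.uint8),
            pixel_size=video.pixel_size * 3.0,
            frame_rate=video.frame_rate,
        )
        base = summarize_heart(video)
        alt = summarize_heart(rescaled)
        for key in ("ef", "fs", "fac"):
            assert alt.means[key] == pytest.approx(base.means[key], abs=1e-6)

    def test_per_frame_area_recovered_within_one_percent(self, clean_masks_video):
        video, truth = clean_masks_video
        cfg = AnalysisConfig()
        for i in (0, 16, 33):
            mask = segment_ventricle(video.plane_short[i], cfg.segmentation)
            geo = frame_geometry(mask, video.pixel_size)
            assert geo.area == pytest.approx(truth["area_short"][i], rel=0.01)

    def test_stage_error_carries_stage_identity(self):
        flat = np.full((210, 64, 64), 50, dtype=np.uint8)
        video = BiplaneVideo(flat, flat, pixel_size=0.02, frame_rate=66.0)
        with pytest.raises(StageError) as err:
            summarize_heart(video)
        assert err.value.stage == "segmentation/geometry"
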