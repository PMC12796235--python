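import numpy as np
import pytest

import opusmotion as om
from opusmotion.synthetic_data import (
    Absorber,
    MotionSegment,
    SimConfig,
    absorber_spectrum,
    make_concentration_canvas,
    make_us_canvas,
    motion_trajectory,
    render_oa,
    render_us,
    simulate_scan,
    tremor_process,
)


class TestTrajectory:
    def test_stationary_segment_constant_pose(self):
        segs = [MotionSegment("stationary", 5.0)]
        poses = motion_trajectory(segs, np.linspace(0, 5, 11), rng=0)
        np.testing.assert_array_equal(poses, np.zeros((11, 3)))

    def test_drift_linear_interpolation(self):
        segs = [MotionSegment("drift", 2.0, amplitude=10.0, direction=(0.0, 1.0))]
        poses = motion_trajectory(segs, [0.0, 1.0, 2.0], rng=0)
        np.testing.assert_allclose(poses[:, 0], [0.0, 5.0, 10.0])
        np.testing.assert_allclose(poses[:, 1:], 0.0)

    def test_rotation_linear_in_angle(self):
        segs = [MotionSegment("rotation", 4.0, amplitude=8.0)]
        poses = motion_trajectory(segs, [0.0, 2.0, 4.0], rng=0)
        np.testing.assert_allclose(poses[:, 2], [0.0, 4.0, 8.0])

    def test_jerk_steps_then_holds(self):
        segs = [
            MotionSegment("stationary", 1.0),
            MotionSegment("jerk", 1.0, amplitude=3.0, direction=(0.0, 1.0)),
            MotionSegment("stationary", 1.0),
        ]
        poses = motion_trajectory(segs, [0.5, 1.5, 2.5], rng=0)
        np.testing.assert_allclose(poses[:, 0], [0.0, 3.0, 3.0])

    def test_continuity_across_non_jerk_boundaries(self):
        segs = [
            MotionSegment("drift", 2.0, amplitude=6.0, direction=(1.0, 0.0)),
            MotionSegment("stationary", 1.0),
            MotionSegment("drift", 2.0, amplitude=4.0, direction=(0.0, 1.0)),
        ]
        t = np.array([2.0 - 1e-9, 2.0, 3.0 - 1e-9, 3.0])
        poses = motion_trajectory(segs, t, rng=0)
        np.testing.assert_allclose(poses[0], poses[1], atol=1e-7)
        np.testing.assert_allclose(poses[2], poses[3], atol=1e-7)

    def test_jitter_zero_mean_and_seeded(self):
        segs = [MotionSegment("jitter", 100.0, sigma=1.0)]
        t = np.linspace(0, 100, 2000)
        a = motion_trajectory(segs, t, rng=5)
        b = motion_trajectory(segs, t, rng=5)
        np.testing.assert_array_equal(a, b)
        assert abs(a[:, 0].mean()) < 0.1
        assert a[:, 0].std() == pytest.approx(1.0, rel=0.1)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            MotionSegment("wobble", 1.0)

    def test_tremor_is_seeded_and_stationary_process(self):
        t = np.arange(0, 60, 0.04)
        a = tremor_process(t, 0.2, 0.4, np.random.default_rng(9))
        b = tremor_process(t, 0.2, 0.4, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)
        assert a[:, 0].std() == pytest.approx(0.2, rel=0.2)


class TestRendering:
    def test_identical_poses_identical_us_images(self):
        rng = np.random.default_rng(0)
        canvas = make_us_canvas(rng, (32, 32), pad=10)
        img1 = render_us(canvas, (2.0, -1.0, 0.0), 0.0, rng, (32, 32), 10)
        img2 = render_us(canvas, (2.0, -1.0, 0.0), 0.0, rng, (32, 32), 10)
        np.testing.assert_array_equal(img1, img2)

    def test_us_shift_equivariance(self):
        """Integer translation equals a shifted crop of the zero-pose image."""
        rng = np.random.default_rng(1)
        canvas = make_us_canvas(rng, (32, 32), pad=10)
        base = render_us(canvas, (0.0, 0.0, 0.0), 0.0, rng, (32, 32), 10)
        shifted = render_us(canvas, (3.0, 2.0, 0.0), 0.0, rng, (32, 32), 10)
        # pose (dx=3, dy=2) samples canvas rows +2, cols +3
        np.testing.assert_allclose(
            shifted[:-2, :-3], base[2:, 3:], atol=1e-12
        )

    def test_us_output_nonnegative(self):
        rng = np.random.default_rng(2)
        canvas = make_us_canvas(rng, (16, 16), pad=6)
        img = render_us(canvas, (0.5, 0.5, 3.0), 0.5, rng, (16, 16), 6)
        assert np.all(img >= 0)

    def test_oa_spectrum_ratio(self):
        """With one absorber and spectrum ratio 2 between wavelengths, the
        noise-free images differ exactly by a factor 2 inside the absorber."""
        absorber = Absorber("a", (8.0, 8.0), 4.0, spectrum=[1.0, 2.0], edge_sigma=0.0)
        conc = make_concentration_canvas(absorber, (16, 16), pad=4)
        spec = [np.array([1.0, 2.0])]
        img0 = render_oa([conc], spec, 0, (0, 0, 0), 0.0, None, (16, 16), 4)
        img1 = render_oa([conc], spec, 1, (0, 0, 0), 0.0, None, (16, 16), 4)
        np.testing.assert_allclose(img1, 2.0 * img0, atol=1e-12)

    def test_oa_zero_concentration_zero_image(self):
        absorber = Absorber("a", (8.0, 8.0), 4.0, spectrum=[1.0], concentration=0.0)
        conc = make_concentration_canvas(absorber, (16, 16), pad=4)
        img = render_oa([conc], [np.array([1.0])], 0, (0, 0, 0), 0.0, None, (16, 16), 4)
        assert np.all(img == 0.0)


class TestSimulateScan:
    def test_stream_lengths_from_rates(self):
        cfg = SimConfig(
            shape=(16, 16),
            wavelengths=(700.0, 710.0),
            segments=[MotionSegment("stationary", 4.0)],
        )
        scan, _ = simulate_scan(cfg, seed=0)
        assert scan.n_us == 25  # 4 s at 6.25 Hz
        assert scan.n_oa == 100  # 4 s at 25 Hz

    def test_wavelengths_cycle_with_preset_period(self, small_scan):
        scan, _ = small_scan
        nl = scan.n_lambda
        np.testing.assert_array_equal(
            scan.oa_wavelengths[nl:], scan.oa_wavelengths[:-nl]
        )

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(
            shape=(16, 16),
            wavelengths=tuple(float(w) for w in range(700, 760, 10)),
            segments=[
                MotionSegment("jitter", 1.5, sigma=0.5),
                MotionSegment("stationary", 1.5),
            ],
        )
        s1, t1 = simulate_scan(cfg, seed=123)
        s2, t2 = simulate_scan(cfg, seed=123)
        np.testing.assert_array_equal(s1.us_images, s2.us_images)
        np.testing.assert_array_equal(s1.oa_images, s2.oa_images)
        np.testing.assert_array_equal(t1.us_pose, t2.us_pose)
        assert t1.stationary_frame_intervals == t2.stationary_frame_intervals

    def test_truth_stationary_us_matches_segments(self, small_scan):
        scan, truth = small_scan
        # stationary segments at t [2,4] and [6.5,8.5]
        for (lo, hi), (tlo, thi) in zip(
            truth.stationary_us_intervals, truth.stationary_time_intervals
        ):
            ts = scan.us_timestamps
            inside = np.nonzero((ts >= tlo) & (ts <= thi))[0]
            assert (lo, hi) == (inside[0], inside[-1])

    def test_scan_passes_model_invariants(self, small_scan):
        scan, _ = small_scan
        scan.validate()
        assert scan.n_ms == scan.n_oa - scan.n_lambda + 1

    def test_stationary_frame_unmixes_exactly_without_noise(self):
        """Noise-free stationary frames satisfy the linear mixing model, so
        NNLS with the true spectra leaves essentially no residual."""
        cfg = SimConfig(
            shape=(24, 24),
            wavelengths=tuple(float(w) for w in range(700, 780, 10)),
            segments=[MotionSegment("stationary", 2.0)],
            us_noise_sigma=0.0,
            oa_noise_sigma=0.0,
            tremor_sigma=0.0,
            absorbers=[Absorber("dye_disk", (10.0, 10.0), 5.0, "dye")],
        )
        scan, truth = simulate_scan(cfg, seed=0)
        frames = om.ms_frames(scan)
        i_ms = om.frame_to_matrix(scan, frames[0])
        w = np.vstack(list(truth.spectra.values()))
        assert om.nnls_unmix(i_ms, w).e <= 1e-6

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = SimConfig(shape=(16, 16), wavelengths=(700.0, 710.0))
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SimConfig.from_yaml(path)
        assert back.shape == cfg.shape
        assert back.wavelengths == cfg.wavelengths
        assert [s.kind for s in back.segments] == [s.kind for s in cfg.segments]

    def test_truth_json_round_trip(self, tmp_path, small_scan):
        import json

        _, truth = small_scan
        path = tmp_path / "truth.json"
        truth.to_json(path)
        data = json.loads(path.read_text())
        assert data["stationary_frame_intervals"] == [
            list(t) for t in truth.stationary_frame_intervals
        ]


class TestSpectra:
    def test_builtin_phantom_spectra_normalized(self):
        wl = np.arange(700.0, 971.0, 10.0)
        for name in ("dye", "oil"):
            spec = absorber_spectrum(name, wl)
            assert spec.max() == pytest.approx(1.0)
            assert np.all(spec > 0)

    def test_oil_peaks_near_930(self):
        wl = np.arange(700.0, 971.0, 10.0)
        spec = absorber_spectrum("oil", wl)
        assert wl[np.argmax(spec)] == 930.0

    def test_chromophore_names_resolve(self):
        wl = np.arange(700.0, 971.0, 10.0)
        spec = absorber_spectrum("hbo2", wl)
        assert spec.shape == wl.shape
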