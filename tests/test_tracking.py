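"""Tests of the fused muscle-boundary tracker."""

import numpy as np
import pytest

import sonomyo as sm
from sonomyo.tracking import box_kernel_shape, envelope


def _integer_shift_series(pulse, shift_samples: int, n_frames: int = 60, start_mm: float = 26.0):
    """Noiseless scene whose boundary advances by an exact integer number of
    samples per frame (depths are exact multiples of the sample spacing)."""
    dz = 1540.0 / (2 * 50e6) * 1e3
    start_idx = round(start_mm / dz)

    def traj(t):
        return (start_idx + shift_samples * np.round(t * 90.0)) * dz

    scen = sm.SimScenario(
        boundary_trajectories=[traj], echo_amplitudes=[1.0],
        noise_snr=None, duration=n_frames / 90.0,
    )
    return sm.simulate_frame_series(scen, pulse)


class TestSelectTransducer:
    def test_scaled_channel_wins(self, static_series):
        series, _ = static_series
        data = np.concatenate([series.data] * 4, axis=0).copy()
        data[2] *= 2.0
        stack = sm.UltrasoundFrameSeries(
            data, series.sampling_frequency, series.frame_rate,
            series.speed_of_sound, series.timestamps,
        )
        assert sm.select_transducer(stack, sm.DepthWindow(25, 35)) == 2

    def test_tie_breaks_to_lowest_index(self, static_series):
        series, _ = static_series
        data = np.concatenate([series.data] * 4, axis=0)
        stack = sm.UltrasoundFrameSeries(
            data, series.sampling_frequency, series.frame_rate,
            series.speed_of_sound, series.timestamps,
        )
        assert sm.select_transducer(stack, sm.DepthWindow(25, 35)) == 0

    def test_matches_brute_force_on_random_stack(self, rng):
        data = rng.standard_normal((4, 20, 512))
        stack = sm.UltrasoundFrameSeries(data, 50e6, 90.0, 1540.0, np.arange(20) / 90.0)
        window = sm.DepthWindow(1.0, 6.0)
        sl = window.to_slice(stack)
        brute = np.argmax(
            [np.abs(envelope(data[k]))[:, sl].max(axis=1).mean() for k in range(4)]
        )
        assert sm.select_transducer(stack, window) == brute

    def test_empty_window_rejected(self, static_series):
        series, _ = static_series
        with pytest.raises(ValueError):
            sm.select_transducer(series, sm.DepthWindow(200.0, 210.0))


class TestEnvelope:
    def test_pure_tone_envelope_is_amplitude(self):
        t = np.arange(4096) / 50e6
        rf = 0.7 * np.sin(2 * np.pi * 5e6 * t)
        env = envelope(rf)
        interior = env[100:-100]
        assert np.allclose(interior, 0.7, rtol=0.01)

    def test_zero_line_zero_envelope(self):
        assert np.all(envelope(np.zeros(64)) == 0)

    def test_envelope_bounds_rf(self, bench):
        series, _ = bench
        rf = series.data[0, :5].astype(float)
        env = envelope(rf)
        assert np.all(env >= np.abs(rf) - 1e-9 * np.abs(rf).max())

    def test_gabor_envelope_peaks_at_center(self, pulse):
        env = envelope(pulse.samples)
        center = pulse.samples.size // 2
        assert abs(int(np.argmax(env)) - center) <= 2


class TestTrackBrightness:
    def test_static_boundary_constant(self, static_series):
        series, truth = static_series
        trace = sm.track_brightness(series, sm.DepthWindow(25, 35))
        assert np.all(np.abs(trace.depth_mm - 30.0) <= 2 * series.sample_spacing_mm)

    def test_default_kernel_shape(self, static_series):
        series, _ = static_series
        # 2.5 mm / 15.4 µm = 162.3 -> 163 odd; 0.05 s * 90 Hz = 4.5 -> 5 odd
        assert box_kernel_shape(series, 2.5, 0.05) == (5, 163)

    def test_window_smaller_than_kernel_rejected(self, static_series):
        series, _ = static_series
        with pytest.raises(ValueError, match="window"):
            sm.track_brightness(series, sm.DepthWindow(29.5, 30.5))

    def test_brightness_noisier_than_fused_above_cutoff(self, pulse):
        scen = sm.make_mechanical_test_scenario(duration=10.0, seed=5)
        series, truth = sm.simulate_frame_series(scen, pulse)
        window = sm.DepthWindow(20, 40)
        bright = sm.track_brightness(series, window, 0)
        fused, _ = sm.track_boundary(series, window, transducer=0)
        g = truth.boundary_depths_mm[0]

        def highband_power(err):
            spec = np.abs(np.fft.rfft(err - err.mean())) ** 2
            freqs = np.fft.rfftfreq(err.size, 1.0 / series.frame_rate)
            return spec[freqs > 1.5].sum()

        assert highband_power(bright.depth_mm - g) > highband_power(fused.depth_mm - g)


class TestTrackXcorr:
    def test_zero_motion_zero_trace(self, static_series):
        series, _ = static_series
        trace = sm.track_xcorr(series, sm.DepthWindow(25, 35))
        assert trace.kind == "relative"
        assert np.all(np.abs(trace.depth_mm) < 1e-6)

    def test_integer_shift_recovered_exactly(self, pulse):
        series, truth = _integer_shift_series(pulse, shift_samples=3)
        trace = sm.track_xcorr(series, sm.DepthWindow(20, 45))
        expected = truth.boundary_depths_mm[0] - truth.boundary_depths_mm[0][0]
        assert np.allclose(trace.depth_mm, expected, atol=1e-6)
        per_frame = np.diff(trace.depth_mm)
        assert np.allclose(per_frame, 3 * series.sample_spacing_mm, atol=1e-9)

    def test_subsample_shift_within_tolerance(self, pulse):
        dz = 1540.0 / (2 * 50e6) * 1e3

        def traj(t):
            return 26.0 + 0.30 * dz * np.round(t * 90.0)

        scen = sm.SimScenario(
            boundary_trajectories=[traj], echo_amplitudes=[1.0],
            noise_snr=None, duration=60 / 90.0,
        )
        series, _ = sm.simulate_frame_series(scen, pulse)
        trace = sm.track_xcorr(series, sm.DepthWindow(20, 40))
        delays = np.diff(trace.depth_mm) / series.sample_spacing_mm
        assert np.all(np.abs(delays - 0.30) <= 0.05)

    def test_zero_energy_window_names_frame(self):
        silent = sm.UltrasoundFrameSeries(
            np.zeros((1, 5, 4096), dtype=np.float32), 50e6, 90.0, 1540.0, np.arange(5) / 90.0
        )
        with pytest.raises(ValueError, match="frame 0"):
            sm.track_xcorr(silent, sm.DepthWindow(10, 50))


class TestFusion:
    def test_identical_constant_inputs_pass_through(self):
        b = sm.BoundaryTrace(np.full(300, 30.0), 90.0)
        x = sm.BoundaryTrace(np.zeros(300), 90.0, kind="relative")
        fused = sm.fuse_tracks(b, x)
        assert np.allclose(fused.depth_mm, 30.0, atol=0.01)

    def test_fusion_beats_both_inputs(self, rng):
        # brightness = truth + high-frequency noise; xcorr = truth + slow drift
        fr, n = 90.0, 2700
        t = np.arange(n) / fr
        truth = 30.0 + 4.0 * np.sin(2 * np.pi * 0.4 * t)
        hf = 0.4 * np.sin(2 * np.pi * 7.0 * t + 1.0) + 0.2 * rng.standard_normal(n)
        drift = 0.002 * t**2 + 0.05 * t
        b = sm.BoundaryTrace(truth + hf, fr)
        x_rel = truth + drift
        x = sm.BoundaryTrace(x_rel - x_rel[0], fr, kind="relative")
        fused = sm.fuse_tracks(b, x)

        def rmse(v):
            return np.sqrt(np.mean((v - truth) ** 2))

        assert rmse(fused.depth_mm) < min(rmse(b.depth_mm), rmse(x.depth_mm + truth[0]))

    def test_length_mismatch_rejected(self):
        b = sm.BoundaryTrace(np.full(10, 30.0), 90.0)
        x = sm.BoundaryTrace(np.zeros(11), 90.0, kind="relative")
        with pytest.raises(ValueError):
            sm.fuse_tracks(b, x)

    def test_cutoff_near_nyquist_returns_brightness(self, rng):
        fr = 90.0
        b = sm.BoundaryTrace(30 + rng.standard_normal(500) * 0.1, fr)
        x = sm.BoundaryTrace(np.r_[0, rng.standard_normal(499)].cumsum() * 0.01, fr, kind="relative")
        x.depth_mm -= x.depth_mm[0]
        fused = sm.fuse_tracks(b, x, cutoff=44.0)
        assert np.allclose(fused.depth_mm, b.depth_mm, atol=0.02)

    def test_low_cutoff_keeps_xcorr_shape(self, rng):
        fr, n = 90.0, 2000
        t = np.arange(n) / fr
        b = sm.BoundaryTrace(np.full(n, 30.0), fr)
        x = sm.BoundaryTrace(2.0 * np.sin(2 * np.pi * 1.0 * t), fr, kind="relative")
        fused = sm.fuse_tracks(b, x, cutoff=0.3)
        # 1 Hz content is far above the 0.3 Hz cutoff: passes the HP branch
        interior = slice(600, -600)
        assert np.allclose(
            fused.depth_mm[interior] - 30.0, x.depth_mm[interior], atol=0.1
        )


class TestThickness:
    def test_constant_offset(self):
        deep = sm.BoundaryTrace(np.full(10, 40.0), 90.0)
        th = sm.compute_thickness(deep, 5.0)
        assert np.all(th.thickness_mm == 35.0)

    def test_degenerate_rejected(self):
        deep = sm.BoundaryTrace(np.full(10, 40.0), 90.0)
        with pytest.raises(ValueError, match="thickness"):
            sm.compute_thickness(deep, 40.0)

    def test_shift_invariance(self):
        t = np.linspace(0, 1, 50)
        deep = sm.BoundaryTrace(40.0 + 5.0 * np.sin(2 * np.pi * t), 90.0)
        th = sm.compute_thickness(deep, 5.0)
        assert np.allclose(th.thickness_mm, deep.depth_mm - 5.0)


class TestRunMbta:
    def test_static_scene_thickness_stable(self, static_series):
        series, _ = static_series
        th, idx = sm.run_mbta(series, sm.DepthWindow(25, 35), superficial_depth_mm=5.0)
        assert idx == 0
        assert np.std(th.thickness_mm) < 0.02
        assert np.allclose(th.thickness_mm, 25.0, atol=2 * series.sample_spacing_mm)

    def test_deterministic(self, bench):
        series, _ = bench
        w = sm.DepthWindow(20, 40)
        th1, i1 = sm.run_mbta(series, w, 5.0)
        th2, i2 = sm.run_mbta(series, w, 5.0)
        assert i1 == i2
        assert np.array_equal(th1.thickness_mm, th2.thickness_mm)

    def test_bench_tracking_is_accurate(self, bench):
        series, truth = bench
        fused, _ = sm.track_boundary(series, sm.DepthWindow(20, 40))
        g = truth.boundary_depths_mm[0]
        rmse = np.sqrt(np.mean((fused.depth_mm - g) ** 2))
        assert 100.0 * rmse / np.ptp(g) <= 0.5


class TestInvariances:
    def test_amplitude_invariance(self, bench):
        series, _ = bench
        w = sm.DepthWindow(20, 40)
        scaled = sm.UltrasoundFrameSeries(
            series.data * 3.7, series.sampling_frequency, series.frame_rate,
            series.speed_of_sound, series.timestamps,
        )
        assert sm.select_transducer(series, w) == sm.select_transducer(scaled, w)
        b1 = sm.track_brightness(series, w, 0)
        b2 = sm.track_brightness(scaled, w, 0)
        assert np.allclose(b1.depth_mm, b2.depth_mm, atol=1e-9)
        x1 = sm.track_xcorr(series, w, 0)
        x2 = sm.track_xcorr(scaled, w, 0)
        assert np.allclose(x1.depth_mm, x2.depth_mm, atol=1e-9)

    def test_shift_equivariance(self, pulse):
        w = sm.DepthWindow(20, 45)
        series1, _ = _integer_shift_series(pulse, 0, n_frames=40, start_mm=26.0)
        dz = series1.sample_spacing_mm
        offset = 100 * dz  # integer number of samples, stays inside the window
        series2, _ = _integer_shift_series(pulse, 0, n_frames=40, start_mm=26.0 + offset)
        b1 = sm.track_brightness(series1, w, 0)
        b2 = sm.track_brightness(series2, w, 0)
        assert np.allclose(b2.depth_mm - b1.depth_mm, offset, atol=1e-6)
        x1 = sm.track_xcorr(series1, w, 0)
        x2 = sm.track_xcorr(series2, w, 0)
        assert np.allclose(x1.depth_mm, x2.depth_mm, atol=1e-9)
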