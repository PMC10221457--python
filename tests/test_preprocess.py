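import numpy as np
import pytest
from scipy import signal as sp_signal

from emgknee.preprocess import (
    PreprocessConfig,
    average_feature,
    average_feature_series,
    bandpass_filter,
    build_dataset,
    full_wave_rectify,
    knee_angle_from_markers,
    lowpass_envelope,
    minmax_normalize,
    segment_gait_cycles,
    time_normalize_cycle,
)
from emgknee.recordings import (
    AngleTrace,
    DegenerateInputError,
    EmgRecording,
    MarkerTrajectory,
)

RATE = 2000.0


def _rec(samples):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 1:
        samples = samples.T
    names = ("RF", "VM", "VL", "GM", "GL")[: samples.shape[1]]
    return EmgRecording(samples, RATE, names)


def _tone(freq, seconds=2.0, amp=1.0):
    t = np.arange(int(seconds * RATE)) / RATE
    return amp * np.sin(2 * np.pi * freq * t)


class TestFilters:
    def test_stopband_rejection_of_slow_drift(self):
        out = bandpass_filter(_rec(_tone(1.0)), 20, 500, 4)
        assert np.max(np.abs(out.samples)) < 0.05

    def test_passband_preserves_in_band_tone(self):
        out = bandpass_filter(_rec(_tone(100.0, seconds=4.0)), 20, 500, 4)
        mid = out.samples[2000:-2000, 0]  # steady state away from edges
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.05)

    def test_noise_power_above_band_attenuated_20db(self, rng):
        noise = rng.standard_normal(2 ** 15)
        out = bandpass_filter(_rec(noise), 20, 500, 4)
        freqs, p_raw = sp_signal.periodogram(noise, fs=RATE)
        _, p_flt = sp_signal.periodogram(out.samples[:, 0], fs=RATE)
        stop = freqs > 650  # past the transition region of the 500 Hz edge
        band = (freqs > 50) & (freqs < 450)
        rejection_db = 10 * np.log10(
            (p_flt[band].mean() / p_raw[band].mean())
            / (p_flt[stop].mean() / p_raw[stop].mean())
        )
        assert rejection_db >= 20

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(_rec(_tone(10)), 20, 1000, 4)
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_envelope(_rec(_tone(10)), cutoff_hz=1000)

    def test_envelope_preserves_dc(self):
        out = lowpass_envelope(_rec(np.full(4000, 3.3)), 6, 4)
        np.testing.assert_allclose(out.samples, 3.3, rtol=1e-9)

    def test_envelope_of_rectified_tone_is_its_mean(self):
        rect = full_wave_rectify(_rec(_tone(100.0, seconds=4.0)))
        out = lowpass_envelope(rect, 6, 4)
        mid = out.samples[2000:-2000, 0]
        assert np.median(mid) == pytest.approx(2 / np.pi, rel=0.10)

    def test_envelope_smooths_impulse_train(self, rng):
        x = np.zeros(8000)
        x[::200] = 1.0
        out = lowpass_envelope(_rec(x), 6, 4)
        assert np.max(np.abs(np.diff(out.samples[:, 0]))) < np.max(np.abs(np.diff(x)))


class TestRectifyNormalize:
    def test_rectify_definition_and_idempotence(self):
        rec = _rec([-1.0, 2.0, -3.0])
        out = full_wave_rectify(rec)
        np.testing.assert_array_equal(out.samples[:, 0], [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(
            full_wave_rectify(out).samples, out.samples
        )
        zero = full_wave_rectify(_rec(np.zeros(5)))
        np.testing.assert_array_equal(zero.samples, 0.0)

    def test_minmax_forced_values_and_idempotence(self):
        np.testing.assert_allclose(minmax_normalize([1.0, 2.0, 3.0]), [0, 0.5, 1])
        once = minmax_normalize([4.0, 9.0, 5.5, 6.0])
        np.testing.assert_allclose(minmax_normalize(once), once)
        assert once.min() == 0.0 and once.max() == 1.0

    def test_minmax_order_preserving(self, rng):
        x = rng.normal(0, 5, 50)
        np.testing.assert_array_equal(np.argsort(minmax_normalize(x)), np.argsort(x))

    def test_minmax_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            minmax_normalize([5.0, 5.0, 5.0])


class TestAverageFeature:
    def test_hand_value(self):
        # ten samples of 1.0, M=10, dt=1/2000: 10 / (9/2000) = 2222.2...
        assert average_feature(np.ones(10), 10, 1 / 2000) == pytest.approx(
            10 / (9 / 2000)
        )

    def test_zero_window(self):
        assert average_feature(np.zeros(10), 10, 1 / 2000) == 0.0

    def test_linearity(self, rng):
        w = rng.random(10)
        assert average_feature(2 * w, 10, 1 / 2000) == pytest.approx(
            2 * average_feature(w, 10, 1 / 2000)
        )

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            average_feature(np.ones(1), 1, 1 / 2000)

    def test_series_matches_scalar_op(self, rng):
        x = rng.random((50, 2))
        series = average_feature_series(x, 10, 1 / 2000)
        assert series.shape == (5, 2)
        for i in range(5):
            for j in range(2):
                assert series[i, j] == pytest.approx(
                    average_feature(x[10 * i:10 * (i + 1), j], 10, 1 / 2000)
                )


class TestKneeAngle:
    def test_collinear_markers_zero_angle(self):
        traj = MarkerTrajectory([[0, 0, 0]], [[1, 0, 0]], [[2, 0, 0]])
        assert knee_angle_from_markers(traj).angle_deg[0] == pytest.approx(0.0)

    def test_orthogonal_markers_right_angle(self):
        traj = MarkerTrajectory([[0, 0, 0]], [[1, 0, 0]], [[1, 1, 0]])
        assert knee_angle_from_markers(traj).angle_deg[0] == pytest.approx(90.0)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        pts = rng.normal(0, 100, (3, 20, 3))
        traj = MarkerTrajectory(*pts)
        base = knee_angle_from_markers(traj).angle_deg
        rot = Rotation.random(rng=np.random.default_rng(1)).as_matrix()
        shift = np.array([10.0, -20.0, 5.0])
        moved = MarkerTrajectory(*[p @ rot.T + shift for p in pts])
        np.testing.assert_allclose(
            knee_angle_from_markers(moved).angle_deg, base, atol=1e-9
        )

    def test_coincident_markers_rejected(self):
        traj = MarkerTrajectory([[1, 0, 0]], [[1, 0, 0]], [[2, 0, 0]])
        with pytest.raises(DegenerateInputError):
            knee_angle_from_markers(traj)


class TestSegmentation:
    def test_concatenated_identical_cycles_found_exactly(self):
        cycle = 30 - 25 * np.cos(2 * np.pi * np.arange(120) / 120)
        trace = AngleTrace(np.tile(cycle, 10), 100.0)
        ranges = segment_gait_cycles(trace, min_cycle_s=0.8)
        assert len(ranges) == 10
        starts = [a for a, _ in ranges]
        np.testing.assert_allclose(starts, np.arange(10) * 120, atol=1)

    def test_monotone_ramp_has_no_cycles(self):
        trace = AngleTrace(np.linspace(0, 60, 500), 100.0)
        assert segment_gait_cycles(trace) == []

    def test_nan_rejected(self):
        trace = AngleTrace(np.concatenate([[np.nan], np.zeros(200)]), 100.0)
        with pytest.raises(ValueError, match="NaN"):
            segment_gait_cycles(trace)

    def test_boundaries_match_simulator_truth(self, clean_bout):
        _, _, markers, truth = clean_bout
        ranges = segment_gait_cycles(knee_angle_from_markers(markers))
        assert len(ranges) == len(truth.cycle_boundaries)
        detected = np.array([a for a, _ in ranges] + [ranges[-1][1]])
        expected = np.array(
            [a for a, _ in truth.cycle_boundaries] + [truth.cycle_boundaries[-1][1]]
        )
        assert np.max(np.abs(detected - expected)) <= 3


class TestTimeNormalize:
    def test_identity_when_sizes_match(self, rng):
        f, a = rng.random((100, 5)), rng.random(100)
        fo, ao = time_normalize_cycle(f, a, 100)
        np.testing.assert_allclose(fo, f, atol=1e-12)
        np.testing.assert_allclose(ao, a, atol=1e-12)

    def test_linear_ramp_exact(self):
        t0 = 37
        ramp = np.linspace(0, 1, t0)
        _, out = time_normalize_cycle(np.zeros((t0, 1)), ramp, 100)
        np.testing.assert_allclose(out, np.arange(100) / 99, atol=1e-12)

    def test_round_trip_on_smooth_cycle(self):
        t0 = 60
        a = 30 + 25 * np.sin(2 * np.pi * np.arange(t0) / t0)
        f = np.column_stack([a / 60, a / 80])
        f2, a2 = time_normalize_cycle(f, a, 2 * t0 - 1)  # refine on same grid
        f3, a3 = time_normalize_cycle(f2, a2, t0)
        np.testing.assert_allclose(a3, a, rtol=1e-6)
        np.testing.assert_allclose(f3, f, rtol=1e-6)


class TestBuildDataset:
    def test_full_pipeline_on_clean_bout(self, clean_bout):
        cfg, emg, markers, truth = clean_bout
        ds = build_dataset(emg, markers)
        assert ds.n_cycles == len(truth.cycle_boundaries)
        assert ds.features.shape == (cfg.n_cycles, 100, 5)
        assert np.isfinite(ds.features).all()
        assert ds.features.min() >= 0.0 and ds.features.max() <= 1.0

    def test_cycle_count_recovered_at_default_noise(self, default_bout, default_dataset):
        cfg, _, _, truth = default_bout
        assert default_dataset.n_cycles == len(truth.cycle_boundaries) == cfg.n_cycles

    def test_too_short_bout_rejected(self):
        rec = EmgRecording(np.zeros((2000, 5)), 2000.0)
        traj = MarkerTrajectory(
            np.zeros((100, 3)), np.tile([0, 500, 0.0], (100, 1)),
            np.tile([0, 900, 0.0], (100, 1)),
        )
        with pytest.raises(DegenerateInputError):
            build_dataset(rec, traj)
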