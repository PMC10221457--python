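import numpy as np
import pytest

from emgknee.preprocess import (
    bandpass_filter,
    full_wave_rectify,
    knee_angle_from_markers,
    lowpass_envelope,
)
from emgknee.simulate import (
    GaitSimConfig,
    SUBJECT_CYCLE_PRESETS,
    activation_profiles,
    angle_profile,
    generate_dataset,
    synthesize_emg,
    synthesize_markers,
)

DENSE = np.linspace(0.0, 1.0, 20000, endpoint=False)


class TestAngleProfile:
    def test_periodic_endpoints(self):
        assert angle_profile(np.array([0.0]))[0] == pytest.approx(
            angle_profile(np.array([1.0]))[0]
        )

    def test_range_within_physiologic_bounds(self):
        values = angle_profile(DENSE)
        assert values.min() >= 0.0
        assert values.max() <= 75.0

    def test_two_local_maxima_per_cycle(self):
        values = angle_profile(DENSE)
        wrapped = np.concatenate([values, values[:1]])
        sign = np.sign(np.diff(wrapped))
        n_max = int(np.sum(np.diff(np.concatenate([sign, sign[:1]])) < 0))
        assert n_max == 2

    def test_global_minimum_at_heel_strike(self):
        values = angle_profile(DENSE)
        argmin_phase = DENSE[values.argmin()]
        assert min(argmin_phase, 1 - argmin_phase) < 0.01

    def test_unknown_mapping_rejected(self):
        with pytest.raises(ValueError):
            angle_profile(DENSE, mapping="spline")


class TestActivationProfiles:
    def test_bounded_and_periodic(self):
        act = activation_profiles(DENSE)
        assert act.shape == (DENSE.size, 5)
        assert act.min() >= 0.0 and act.max() <= 1.0
        np.testing.assert_allclose(
            activation_profiles(np.array([0.0])),
            activation_profiles(np.array([1.0])),
        )

    def test_channel_peak_phases_distinct(self):
        act = activation_profiles(DENSE)
        peaks = DENSE[act.argmax(axis=0)]
        assert len(np.unique(np.round(peaks, 3))) == 5


class TestSynthesizeEmg:
    def test_zero_activation_gives_silent_channel(self):
        act = np.zeros((4000, 5))
        rec = synthesize_emg(act, snr_db=20.0, seed=0)
        assert np.max(np.abs(rec.samples)) == 0.0

    def test_deterministic_per_seed(self):
        act = activation_profiles(np.arange(40000) / 2520.0)
        a = synthesize_emg(act, 20.0, seed=9)
        b = synthesize_emg(act, 20.0, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)
        c = synthesize_emg(act, 20.0, seed=10)
        assert np.any(c.samples != a.samples)

    def test_envelope_recovers_activation_at_20db(self):
        """Rectified + low-passed synthetic sEMG correlates r>=0.9 with truth."""
        phase = np.arange(252000) / 2520.0  # 100 cycles of 1.26 s at 2000 Hz
        act = activation_profiles(phase)
        worst = 1.0
        for seed in range(10):
            rec = synthesize_emg(act, snr_db=20.0, seed=seed)
            env = lowpass_envelope(
                full_wave_rectify(bandpass_filter(rec))
            ).samples
            r = [np.corrcoef(env[:, ch], act[:, ch])[0, 1] for ch in range(5)]
            worst = min(worst, min(r))
        assert worst >= 0.9


class TestSynthesizeMarkers:
    def test_exact_inversion_without_noise(self):
        angle = angle_profile(np.linspace(0, 1, 500))
        traj = synthesize_markers(angle, seed=0, noise_mm=0.0)
        recovered = knee_angle_from_markers(traj).angle_deg
        np.testing.assert_allclose(recovered, angle, atol=1e-9)

    def test_rotation_of_whole_trajectory_leaves_angle_unchanged(self):
        from scipy.spatial.transform import Rotation

        angle = angle_profile(np.linspace(0, 1, 200))
        traj = synthesize_markers(angle, seed=1, noise_mm=0.3)
        base = knee_angle_from_markers(traj).angle_deg
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        from emgknee.recordings import MarkerTrajectory

        moved = MarkerTrajectory(
            traj.points_a @ rot.T, traj.points_b @ rot.T, traj.points_c @ rot.T
        )
        np.testing.assert_allclose(
            knee_angle_from_markers(moved).angle_deg, base, atol=1e-9
        )

    def test_default_noise_angle_error_small(self):
        angle = angle_profile(np.linspace(0, 1, 1000))
        traj = synthesize_markers(angle, seed=2, noise_mm=0.3)
        recovered = knee_angle_from_markers(traj).angle_deg
        assert np.max(np.abs(recovered - angle)) <= 0.5

    def test_deterministic_per_seed(self):
        angle = angle_profile(np.linspace(0, 1, 100))
        a = synthesize_markers(angle, seed=5)
        b = synthesize_markers(angle, seed=5)
        np.testing.assert_array_equal(a.points_c, b.points_c)


class TestGenerateDataset:
    def test_cycle_count_and_boundary_partition(self):
        cfg = GaitSimConfig(n_cycles=60, seed=1)
        _, _, truth = generate_dataset(cfg)
        assert len(truth.cycle_boundaries) == 60
        starts = [a for a, _ in truth.cycle_boundaries]
        stops = [b for _, b in truth.cycle_boundaries]
        assert starts[0] == 0
        assert starts[1:] == stops[:-1]
        assert stops[-1] == truth.clean_angle.size

    def test_cycle_length_distribution(self):
        cfg = GaitSimConfig(n_cycles=200, seed=4)
        _, _, truth = generate_dataset(cfg)
        lengths = np.diff([a for a, _ in truth.cycle_boundaries])
        se = cfg.cycle_len_sd_samples / np.sqrt(len(lengths))
        assert abs(lengths.mean() - cfg.cycle_len_mean_samples) < 2 * se + 0.5

    def test_streams_rates_consistent(self):
        cfg = GaitSimConfig(n_cycles=5, seed=2)
        emg, markers, truth = generate_dataset(cfg)
        assert emg.n_samples == 20 * markers.n_frames
        assert markers.n_frames == truth.clean_angle.size

    def test_fully_deterministic_per_seed(self):
        cfg = GaitSimConfig(n_cycles=4, seed=11)
        e1, m1, t1 = generate_dataset(cfg)
        e2, m2, t2 = generate_dataset(cfg)
        np.testing.assert_array_equal(e1.samples, e2.samples)
        np.testing.assert_array_equal(m1.points_b, m2.points_b)
        np.testing.assert_array_equal(t1.clean_angle, t2.clean_angle)
        assert t1.cycle_boundaries == t2.cycle_boundaries

    def test_subject_presets_span_reported_cycle_lengths(self):
        assert set(SUBJECT_CYCLE_PRESETS) == {"S1", "S2", "S3", "S4", "S5"}
        cfg = GaitSimConfig.for_subject("S5", n_cycles=3, seed=0)
        assert cfg.cycle_len_mean_samples == 122

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GaitSimConfig(n_cycles=0)
        with pytest.raises(ValueError):
            GaitSimConfig(emg_rate_hz=1999.0)
        with pytest.raises(ValueError):
            GaitSimConfig(mapping="nope")


def test_closed_loop_angle_fidelity(clean_bout):
    """Marker-derived per-cycle angles correlate r>=0.99 with the clean angle."""
    _, _, markers, truth = clean_bout
    recovered = knee_angle_from_markers(markers).angle_deg
    for start, stop in truth.cycle_boundaries:
        r = np.corrcoef(recovered[start:stop], truth.clean_angle[start:stop])[0, 1]
        assert r >= 0.99
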