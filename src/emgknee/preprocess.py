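"""Raw sEMG + marker trajectories -> model-ready gait-cycle dataset.

The chain, applied offline to a walking bout:

1. band-pass the raw sEMG (4th-order Butterworth, 20-500 Hz) to remove DC
   offset, motion artifact and out-of-band noise;
2. full-wave rectify;
3. low-pass the rectified signal (4th-order Butterworth, 6 Hz) to obtain the
   linear envelope;
4. min-max normalize each channel to [0, 1];
5. summarise the envelope in sliding windows with the average feature
   AF = sum_j x(j) / ((M-1) dt), M = 10 samples, dt = 1/2000 s;
6. compute the knee angle from the three marker trajectories
   (phi = arccos of the angle between thigh and shank vectors);
7. cut the bout into gait cycles at prominent knee-angle minima (heel-strike
   proxy) and resample every cycle onto a fixed grid of phase points
   (default 100), yielding [AF_t, Y_t] pairs.

All Butterworth stages are applied forward-backward (zero phase), which is
appropriate offline and doubles the effective order; envelope negativity
introduced by the zero-phase low-pass is clipped at zero before
normalization, since envelopes are physically non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recordings import (
    AngleTrace,
    DegenerateInputError,
    EmgRecording,
    GaitCycleDataset,
    MarkerTrajectory,
)


@dataclass(frozen=True)
class PreprocessConfig:
    """Pipeline parameters; defaults follow the acquisition protocol."""

    bandpass_low_hz: float = 20.0
    bandpass_high_hz: float = 500.0
    bandpass_order: int = 4
    lowpass_cutoff_hz: float = 6.0
    lowpass_order: int = 4
    af_window: int = 10          # M samples per AF window (non-overlapping)
    af_dt_s: float | None = None  # sampling period; None = 1/rate_hz
    points_per_cycle: int = 100
    normalization_scope: str = "recording"  # or "cycle"
    min_cycle_s: float = 0.8
    prominence_deg: float = 5.0

    def __post_init__(self) -> None:
        if self.normalization_scope not in ("recording", "cycle"):
            raise ValueError("normalization_scope must be 'recording' or 'cycle'")
        if self.af_window < 2:
            raise ValueError("af_window must be >= 2")
        if self.points_per_cycle < 2:
            raise ValueError("points_per_cycle must be >= 2")


def _butter_sos(rate_hz, order, cutoff, btype):
    nyquist = rate_hz / 2.0
    cutoffs = np.atleast_1d(cutoff)
    if order < 1:
        raise ValueError("filter order must be >= 1")
    if np.any(cutoffs <= 0) or np.any(cutoffs >= nyquist):
        raise ValueError(
            f"cutoff(s) {cutoff} must lie strictly between 0 and the "
            f"Nyquist frequency {nyquist} Hz"
        )
    wn = float(cutoffs[0]) if cutoffs.size == 1 else cutoffs
    return signal.butter(order, wn, btype=btype, fs=rate_hz, output="sos")


def bandpass_filter(
    rec: EmgRecording, low_hz: float = 20.0, high_hz: float = 500.0, order: int = 4
) -> EmgRecording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    if not low_hz < high_hz:
        raise ValueError("low_hz must be below high_hz")
    sos = _butter_sos(rec.rate_hz, order, (low_hz, high_hz), "bandpass")
    return rec.with_samples(signal.sosfiltfilt(sos, rec.samples, axis=0))


def full_wave_rectify(rec: EmgRecording) -> EmgRecording:
    """Replace every sample by its absolute value."""
    return rec.with_samples(np.abs(rec.samples))


def lowpass_envelope(
    rec: EmgRecording, cutoff_hz: float = 6.0, order: int = 4
) -> EmgRecording:
    """Zero-phase Butterworth low-pass; smooths a rectified signal into its
    linear envelope.  (Negative undershoot is clipped later, at the
    normalization stage of :func:`build_dataset`.)"""
    sos = _butter_sos(rec.rate_hz, order, cutoff_hz, "lowpass")
    return rec.with_samples(signal.sosfiltfilt(sos, rec.samples, axis=0))


def minmax_normalize(series: np.ndarray) -> np.ndarray:
    """Map a series onto [0, 1]: (x - min) / (max - min), per column if 2-D."""
    arr = np.asarray(series, dtype=float)
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    if np.any(hi - lo <= 0):
        raise DegenerateInputError(
            "constant series cannot be min-max normalized (max == min)"
        )
    return (arr - lo) / (hi - lo)


def average_feature(window: np.ndarray, m: int | None = None, dt: float = 1.0 / 2000) -> float:
    """Average feature of one window: sum of the M samples over (M-1)*dt.

    Units are amplitude per second (the divisor is a time span); the value is
    linear and positively homogeneous in the window samples.
    """
    window = np.asarray(window, dtype=float).ravel()
    if m is None:
        m = window.size
    if m < 2:
        raise ValueError("m must be >= 2 (the (M-1)*dt divisor would vanish)")
    if window.size != m:
        raise ValueError(f"window length {window.size} != m = {m}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(window.sum() / ((m - 1) * dt))


def average_feature_series(samples: np.ndarray, m: int, dt: float) -> np.ndarray:
    """AF over consecutive non-overlapping windows of M samples (stride M).

    Input ``(n, C)``; output ``(n // m, C)``; trailing samples that do not
    fill a window are dropped.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if m < 2:
        raise ValueError("m must be >= 2")
    n_windows = samples.shape[0] // m
    trimmed = samples[: n_windows * m]
    return trimmed.reshape(n_windows, m, -1).sum(axis=1) / ((m - 1) * dt)


def knee_angle_from_markers(traj: MarkerTrajectory) -> AngleTrace:
    """Knee angle per frame: arccos of the angle between B-A and C-B (degrees).

    The cosine is clamped to [-1, 1] against round-off, so the result always
    lies in [0, 180] degrees and is invariant under rigid motions of the
    marker set.
    """
    v_ab = traj.points_b - traj.points_a
    v_bc = traj.points_c - traj.points_b
    norm_ab = np.linalg.norm(v_ab, axis=1)
    norm_bc = np.linalg.norm(v_bc, axis=1)
    if np.any(norm_ab == 0) or np.any(norm_bc == 0):
        raise DegenerateInputError(
            "coincident markers: zero-length thigh or shank vector"
        )
    cosine = np.einsum("ij,ij->i", v_ab, v_bc) / (norm_ab * norm_bc)
    angle = np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0)))
    return AngleTrace(angle, traj.rate_hz)


def segment_gait_cycles(
    angles: AngleTrace,
    min_cycle_s: float = 0.8,
    prominence_deg: float = 5.0,
) -> list[tuple[int, int]]:
    """Cut a knee-angle trace into gait cycles at prominent angle minima.

    Knee flexion is minimal around heel strike, so prominent local minima of
    the angle trace serve as cycle boundaries.  The trace endpoints are
    eligible boundaries (a bout that starts or ends at heel strike keeps its
    edge cycles).  Returns disjoint, ordered half-open index ranges, each at
    least ``min_cycle_s`` long; an empty list if no cycle is found.
    """
    angle = np.asarray(angles.angle_deg, dtype=float)
    if np.any(~np.isfinite(angle)):
        raise ValueError("angle trace contains NaN or infinite values")
    min_len = max(int(round(min_cycle_s * angles.rate_hz)), 1)
    if angle.size <= min_len:
        return []
    # Pad with -inf so endpoint minima are detectable as peaks of -angle.
    padded = np.concatenate([[-np.inf], -angle, [-np.inf]])
    peaks, _ = signal.find_peaks(
        padded, distance=min_len, prominence=prominence_deg
    )
    boundaries = np.clip(peaks - 1, 0, angle.size - 1)
    ranges = [
        (int(a), int(b))
        for a, b in zip(boundaries[:-1], boundaries[1:])
        if b - a >= min_len
    ]
    return ranges


def time_normalize_cycle(
    features: np.ndarray, angles: np.ndarray, t_out: int = 100
):
    """Resample one cycle onto ``t_out`` equally spaced phase points.

    Linear interpolation over normalized phase in [0, 1]; the first and last
    samples are preserved exactly.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    angles = np.asarray(angles, dtype=float).ravel()
    t0 = features.shape[0]
    if t0 != angles.size:
        raise ValueError("features and angles length mismatch")
    if t0 < 2 or t_out < 2:
        raise ValueError("need at least two samples in and out")
    phase_in = np.linspace(0.0, 1.0, t0)
    phase_out = np.linspace(0.0, 1.0, t_out)
    out_feats = np.column_stack(
        [np.interp(phase_out, phase_in, features[:, j]) for j in range(features.shape[1])]
    )
    out_angles = np.interp(phase_out, phase_in, angles)
    return out_feats, out_angles


def build_dataset(
    rec: EmgRecording,
    traj: MarkerTrajectory,
    config: PreprocessConfig | None = None,
    boundaries: list[tuple[int, int]] | None = None,
) -> GaitCycleDataset:
    """Run the full chain and return the stacked [AF_t, Y_t] dataset.

    ``boundaries`` (half-open angle-sample index ranges) may be supplied
    explicitly, e.g. from an event file; otherwise cycles are detected from
    the knee-angle minima.  Raises :class:`DegenerateInputError` if fewer
    than one complete cycle is found.
    """
    config = config or PreprocessConfig()

    filtered = bandpass_filter(
        rec, config.bandpass_low_hz, config.bandpass_high_hz, config.bandpass_order
    )
    envelope = lowpass_envelope(
        full_wave_rectify(filtered), config.lowpass_cutoff_hz, config.lowpass_order
    )
    clipped = np.clip(envelope.samples, 0.0, None)

    if config.normalization_scope == "recording":
        normalized = minmax_normalize(clipped)
    else:
        normalized = clipped  # per-cycle normalization happens below

    dt = config.af_dt_s if config.af_dt_s is not None else 1.0 / rec.rate_hz
    af = average_feature_series(normalized, config.af_window, dt)
    if config.normalization_scope == "recording":
        # The AF divisor (M-1)*dt scales features out of the unit interval;
        # min-max normalizing the AF series per channel restores the [0, 1]
        # range the regression kernels assume.  AF ordering is preserved.
        af = minmax_normalize(af)
    af_rate = rec.rate_hz / config.af_window
    # AF value i summarises samples [i*M, (i+1)*M); stamp it at the window centre.
    af_times = (np.arange(af.shape[0]) + 0.5) / af_rate

    angle_trace = knee_angle_from_markers(traj)
    if boundaries is None:
        boundaries = segment_gait_cycles(
            angle_trace, config.min_cycle_s, config.prominence_deg
        )
    if not boundaries:
        raise DegenerateInputError("no complete gait cycle found in the bout")

    t_out = config.points_per_cycle
    phase = np.linspace(0.0, 1.0, t_out)
    cycles_feats = []
    cycles_angles = []
    for start, stop in boundaries:
        angle_cycle = angle_trace.angle_deg[start:stop]
        times = (start + phase * (stop - 1 - start)) / angle_trace.rate_hz
        feats = np.column_stack(
            [np.interp(times, af_times, af[:, j]) for j in range(af.shape[1])]
        )
        if config.normalization_scope == "cycle":
            feats = minmax_normalize(feats)
        _, angles_out = time_normalize_cycle(
            np.zeros((angle_cycle.size, 1)), angle_cycle, t_out
        )
        cycles_feats.append(feats)
        cycles_angles.append(angles_out)

    return GaitCycleDataset(
        np.stack(cycles_feats), np.stack(cycles_angles), rec.channel_names
    )
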