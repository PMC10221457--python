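"""Core containers for sEMG recordings, marker trajectories and gait-cycle datasets.

The pipeline operates on three synchronized streams: multi-channel raw sEMG
sampled at 2000 Hz, 3-D trajectories of three knee markers (A on the thigh,
B at the joint centre, C on the shank) sampled at 100 Hz, and the knee
flexion angle derived from the markers.  After preprocessing, the model-ready
table is a stack of time-normalized gait cycles, each pairing a T x C matrix
of average-feature (AF) values with a length-T knee-angle trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CHANNELS = ("RF", "VM", "VL", "GM", "GL")


class DegenerateInputError(ValueError):
    """Raised when an input is valid in shape but degenerate in content."""


@dataclass(frozen=True)
class EmgRecording:
    """Multi-channel sEMG samples, shape ``(n_samples, n_channels)``.

    Amplitudes are in arbitrary (mV-scale) units; ``rate_hz`` is the sampling
    frequency (2000 Hz for the supported acquisition setup).
    """

    samples: np.ndarray
    rate_hz: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim == 1:
            samples = samples[:, None]
        if samples.ndim != 2:
            raise ValueError("samples must be a (n_samples, n_channels) array")
        if samples.shape[1] < 1:
            raise ValueError("at least one channel required")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if len(self.channel_names) != samples.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{samples.shape[1]} channels"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def with_samples(self, samples: np.ndarray) -> "EmgRecording":
        """Copy of this recording with the sample matrix replaced."""
        return EmgRecording(samples, self.rate_hz, self.channel_names)


@dataclass(frozen=True)
class MarkerTrajectory:
    """3-D trajectories (mm) of markers A, B, C; each ``(n_frames, 3)``."""

    points_a: np.ndarray
    points_b: np.ndarray
    points_c: np.ndarray
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        arrays = []
        for name in ("points_a", "points_b", "points_c"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must have shape (n_frames, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite coordinates")
            arrays.append(arr)
        if not (arrays[0].shape[0] == arrays[1].shape[0] == arrays[2].shape[0]):
            raise ValueError("marker trajectories must have equal lengths")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        for name, arr in zip(("points_a", "points_b", "points_c"), arrays):
            object.__setattr__(self, name, arr)

    @property
    def n_frames(self) -> int:
        return self.points_a.shape[0]


@dataclass(frozen=True)
class AngleTrace:
    """Knee flexion angle series in degrees (0 deg = thigh and shank collinear)."""

    angle_deg: np.ndarray
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        angle = np.asarray(self.angle_deg, dtype=float)
        if angle.ndim != 1:
            raise ValueError("angle_deg must be one-dimensional")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        finite = angle[np.isfinite(angle)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 180 + 1e-9):
            raise ValueError("knee angle must lie in [0, 180] degrees")
        object.__setattr__(self, "angle_deg", angle)

    @property
    def n_frames(self) -> int:
        return self.angle_deg.shape[0]


@dataclass(frozen=True)
class GaitCycleDataset:
    """Stacked time-normalized gait cycles: the regression model's training table.

    ``features`` has shape ``(n_cycles, T, C)`` (AF values per phase point and
    muscle) and ``angles`` shape ``(n_cycles, T)`` (degrees).  All cycles share
    the same number of phase points T (``points_per_cycle``).
    """

    features: np.ndarray
    angles: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        angles = np.asarray(self.angles, dtype=float)
        if feats.ndim != 3:
            raise ValueError("features must have shape (n_cycles, T, C)")
        if angles.shape != feats.shape[:2]:
            raise ValueError("angles must have shape (n_cycles, T)")
        if not np.all(np.isfinite(feats)):
            raise ValueError("features contain non-finite values")
        if angles.size and (angles.min() < -1e-9 or angles.max() > 180 + 1e-9):
            raise ValueError("angles must lie in [0, 180] degrees")
        if len(self.channel_names) != feats.shape[2]:
            raise ValueError("channel_names must match feature columns")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "angles", angles)

    @property
    def n_cycles(self) -> int:
        return self.features.shape[0]

    @property
    def points_per_cycle(self) -> int:
        return self.features.shape[1]

    @property
    def n_channels(self) -> int:
        return self.features.shape[2]

    def pooled(self, cycle_indices=None, phase_stride: int = 1):
        """Flatten selected cycles into an ``(N, C)`` design and length-N targets.

        ``phase_stride`` keeps every k-th phase point; evaluation normally uses
        stride 1 while training may subsample phases for speed.
        """
        if cycle_indices is None:
            cycle_indices = np.arange(self.n_cycles)
        idx = np.asarray(cycle_indices, dtype=int)
        feats = self.features[idx][:, ::phase_stride, :]
        angles = self.angles[idx][:, ::phase_stride]
        return feats.reshape(-1, self.n_channels), angles.reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: ``gc_id, phase, af_<ch>..., angle_deg``."""
        n, t, c = self.features.shape
        frame = pd.DataFrame(
            self.features.reshape(n * t, c),
            columns=[f"af_{ch}" for ch in self.channel_names],
        )
        frame.insert(0, "phase", np.tile(np.arange(t), n))
        frame.insert(0, "gc_id", np.repeat(np.arange(n), t))
        frame["angle_deg"] = self.angles.reshape(-1)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GaitCycleDataset":
        af_cols = [col for col in frame.columns if col.startswith("af_")]
        if not af_cols:
            raise ValueError("no af_<channel> columns found")
        n = frame["gc_id"].nunique()
        t = frame["phase"].nunique()
        if len(frame) != n * t:
            raise ValueError("frame is not a complete gc_id x phase grid")
        frame = frame.sort_values(["gc_id", "phase"])
        feats = frame[af_cols].to_numpy().reshape(n, t, len(af_cols))
        angles = frame["angle_deg"].to_numpy().reshape(n, t)
        names = tuple(col[3:] for col in af_cols)
        return cls(feats, angles, names)
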