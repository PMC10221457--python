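"""Simulate a walking bout and inspect what the generator produced.

The simulator emits three synchronized streams: raw five-channel sEMG at
2000 Hz, knee-marker trajectories at 100 Hz, and the ground truth (cycle
boundaries, clean knee angle, muscle activations) that the rest of the
pipeline can be checked against.
"""

import numpy as np

from emgknee import GaitSimConfig, generate_dataset

cfg = GaitSimConfig(n_cycles=10, seed=42)
emg, markers, truth = generate_dataset(cfg)

lengths = np.diff([start for start, _ in truth.cycle_boundaries])
print(f"simulated {cfg.n_cycles} gait cycles")
print(f"  sEMG:    {emg.n_samples} samples x {emg.n_channels} channels "
      f"at {emg.rate_hz:.0f} Hz, channels {', '.join(emg.channel_names)}")
print(f"  markers: {markers.n_frames} frames at {markers.rate_hz:.0f} Hz")
print(f"  cycle length (angle samples): mean {lengths.mean():.1f}, "
      f"sd {lengths.std(ddof=1):.1f}  (target {cfg.cycle_len_mean_samples} "
      f"+/- {cfg.cycle_len_sd_samples})")
print(f"  clean knee angle range: {truth.clean_angle.min():.1f} to "
      f"{truth.clean_angle.max():.1f} deg")

# The knee angle is lowest at heel strike (each cycle boundary) and peaks in
# swing; the activations are phase-locked bursts for each muscle.
start, stop = truth.cycle_boundaries[0]
peak = start + truth.clean_angle[start:stop].argmax()
print(f"  first cycle: heel strike at frame {start}, swing peak "
      f"{truth.clean_angle[peak]:.1f} deg at {100 * (peak - start) / (stop - start):.0f}% "
      "of the cycle")
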