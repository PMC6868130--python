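"""Simulate mobility-switching trajectories and inspect their statistics.

Builds the reference three-state model (fast diffusion D=1.0 μm²/s,
slow diffusion D=0.1 μm²/s, immobile fBm H=0.1 η=0.3; symmetric
switching with stay-probability 0.8) and prints what the simulated
population looks like.
"""

import numpy as np

from dlmss import FbmParams, simulate_dataset, three_state_model

rng = np.random.default_rng(0)
model = three_state_model()
tracks = simulate_dataset(model, FbmParams(), n_tracks=500, rng=rng)

lengths = np.array([len(t) for t in tracks])
labels = np.concatenate([t.labels for t in tracks])
steps = np.concatenate([np.diff(t.positions, axis=0) for t in tracks])
print(f"{len(tracks)} tracks, lengths {lengths.min()}..{lengths.max()} "
      f"(mean {lengths.mean():.1f} frames)")
print("state occupancy:", np.round(np.bincount(labels) / len(labels), 3))
for k, name in ((0, "fast"), (1, "slow"), (2, "immobile")):
    sel = np.concatenate([t.labels[:-1] == k for t in tracks])
    sd = steps[sel].std()
    print(f"  state {k} ({name:8s}): per-coordinate step s.d. {sd:.3f} μm")
# Occupancy ~1/3 per state (symmetric chain); step sizes separate fast
# (≈0.25 μm) from slow (≈0.08 μm), while the immobile state is tiny
# anti-correlated jitter (≈0.024 μm).
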