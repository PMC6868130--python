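"""Splitting labeled trajectories into same-mobility tracklets.

A tracklet is a maximal run of displacement steps carrying one mobility
label.  Runs are taken over step labels (step t is labeled by point t,
the classifier's convention); the tracklet for a step run [s..e] spans
points [s..e+1], so the point on a label boundary belongs to both
adjacent tracklets and no displacement step is ever lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .mss import MssConfig, MssResult, estimate_mss

__all__ = ["TrackletRecord", "split_tracklets", "filter_for_mss", "estimate_tracklet_mss"]

#: Tracklets must span strictly more than this many frames to enter
#: MSS clustering (short tracklets give unreliable regressions).
MSS_MIN_FRAMES = 11


@dataclass
class TrackletRecord:
    """One same-label segment of a parent trajectory."""

    track_id: str
    tracklet_id: int
    start_frame: int
    positions: np.ndarray  # (n_frames, 2), boundary points shared with neighbors
    label: int
    S_mss: float | None = None
    D: float | None = None
    included_in_clustering: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1


def split_tracklets(
    positions: np.ndarray,
    labels: np.ndarray,
    track_id: str = "0",
) -> list[TrackletRecord]:
    """Split one labeled trajectory into maximal same-label tracklets.

    ``labels`` may be per-point (length T) or per-step (length T−1);
    per-point labels are reduced to step labels by the step-t←point-t
    convention.  The union of the tracklets' step intervals covers the
    track exactly once: step counts sum to T−1.
    """
    positions = np.asarray(positions, dtype=float)
    labels = np.asarray(labels, dtype=int)
    T = len(positions)
    if len(labels) == T:
        step_labels = labels[:-1]
    elif len(labels) == T - 1:
        step_labels = labels
    else:
        raise ValidationError(
            f"labels length {len(labels)} matches neither points ({T}) nor steps ({T - 1})"
        )
    if T < 2:
        raise ValidationError("need at least 2 positions to form tracklets")

    boundaries = np.flatnonzero(np.diff(step_labels)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(step_labels)]])
    out = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        out.append(
            TrackletRecord(
                track_id=track_id,
                tracklet_id=i,
                start_frame=int(s),
                positions=positions[s : e + 1],
                label=int(step_labels[s]),
            )
        )
    return out


def estimate_tracklet_mss(
    tracklets: list[TrackletRecord],
    cfg: MssConfig = MssConfig(),
    min_frames: int = MSS_MIN_FRAMES,
) -> list[TrackletRecord]:
    """Attach MSS estimates to tracklets long enough to support them.

    Tracklets with fewer than ``min_frames`` frames, or whose regression
    yields a negative D or negative S_MSS (unstable fits), keep their
    class label but are excluded from clustering
    (``included_in_clustering=False``); they inherit their class's
    aggregate properties downstream.
    """
    for t in tracklets:
        if t.n_frames < min_frames:
            t.included_in_clustering = False
            continue
        res: MssResult = estimate_mss(t.positions, cfg)
        t.S_mss = None if np.isnan(res.S_mss) else float(res.S_mss)
        t.D = None if np.isnan(res.D) else float(res.D)
        t.included_in_clustering = bool(res.stable)
    return tracklets


def filter_for_mss(
    tracklets: list[TrackletRecord], min_frames: int = MSS_MIN_FRAMES
) -> list[TrackletRecord]:
    """The subset of tracklets eligible for MSS clustering.

    Keeps tracklets spanning at least ``min_frames`` frames whose MSS
    estimates (if already computed) are stable.  The default threshold
    of 11 frames implements "more than ten time frames".
    """
    out = []
    for t in tracklets:
        if t.n_frames < min_frames:
            continue
        if t.S_mss is None and t.D is None:
            out.append(t)  # length-eligible, MSS not yet attached
        elif t.included_in_clustering:
            out.append(t)
    return out
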