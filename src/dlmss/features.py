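"""Per-time-step feature extraction and fixed-length training windows.

Each displacement step t (between points t and t+1) is described by the
step length, the centered coordinates of the two flanking points, and a
set of normalized higher-order lag distances that provide multi-scale
context (the lag-k distance ‖p(t+k) − p(t)‖ / k, with k shrunk near the
end of the track).  Coordinates are centered on the centroid of the
featurized stretch, which makes the features exactly translation
invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, TooShortError, ValidationError
from .trajsim import LabeledTrajectory

__all__ = ["FeatureConfig", "LabeledWindow", "featurize", "make_windows", "n_features"]


@dataclass(frozen=True)
class FeatureConfig:
    """Feature layout shared between training and inference.

    window_len
        Length of a training window in displacement steps (default 25).
    avg_orders
        Lags k of the higher-order average distances (default (2, 3, 4)).
    center_coords
        Express flanking coordinates relative to the centroid of the
        featurized stretch (default True).
    """

    window_len: int = 25
    avg_orders: tuple[int, ...] = (2, 3, 4)
    center_coords: bool = True

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ParameterError(f"window_len must be >= 2, got {self.window_len}")
        if any(k < 2 for k in self.avg_orders):
            raise ParameterError("all avg_orders must be >= 2")
        object.__setattr__(self, "avg_orders", tuple(self.avg_orders))


@dataclass
class LabeledWindow:
    """A fixed-length feature/label pair cut from one simulated track."""

    features: np.ndarray  # (window_len, F)
    labels: np.ndarray  # (window_len,)
    source_track: str = ""
    offset: int = 0

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValidationError("features and labels must have equal length")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("window features must be finite")


def n_features(cfg: FeatureConfig) -> int:
    """Feature dimension implied by the configuration."""
    return 5 + len(cfg.avg_orders)


def featurize(positions: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Per-step feature matrix of shape (T−1, F) for T positions.

    Row t holds: step length ‖p(t+1) − p(t)‖; the (centered) x, y of
    point t and point t+1; and, for each k in ``avg_orders``, the
    normalized lag distance ‖p(t+k') − p(t)‖ / k' with k' the largest
    available lag ≤ k.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValidationError(f"positions must be (T, 2), got {positions.shape}")
    T = len(positions)
    if T < 2:
        raise TooShortError(f"need at least 2 positions to featurize, got {T}")

    centered = positions - positions.mean(axis=0) if cfg.center_coords else positions
    steps = np.diff(positions, axis=0)
    d = np.hypot(steps[:, 0], steps[:, 1])

    cols = [d, centered[:-1, 0], centered[:-1, 1], centered[1:, 0], centered[1:, 1]]
    t = np.arange(T - 1)
    for k in cfg.avg_orders:
        kk = np.minimum(k, T - 1 - t)  # shrink the lag near the track end
        disp = positions[t + kk] - positions[t]
        cols.append(np.hypot(disp[:, 0], disp[:, 1]) / kk)
    return np.column_stack(cols)


def make_windows(
    traj: LabeledTrajectory, cfg: FeatureConfig = FeatureConfig()
) -> list[LabeledWindow]:
    """Cut one labeled track into non-overlapping training windows.

    Window j covers displacement steps [j·W, (j+1)·W); each window is
    featurized (and centered) on its own stretch of positions, and the
    label of step t is the label of point t.  A trailing remainder
    shorter than one window is discarded; tracks shorter than a window
    yield an empty list.
    """
    W = cfg.window_len
    T = len(traj.positions)
    out: list[LabeledWindow] = []
    for off in range(0, (T - 1) - W + 1, W):
        pos = traj.positions[off : off + W + 1]
        out.append(
            LabeledWindow(
                features=featurize(pos, cfg),
                labels=traj.labels[off : off + W],
                source_track=traj.track_id,
                offset=off,
            )
        )
    return out
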