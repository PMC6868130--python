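"""File formats, configuration and the end-to-end analysis pipeline.

Trajectory tables are plain CSV with a header — one localization per
row: ``track_id, frame, x, y`` plus optional ``true_label`` /
``pred_label`` columns.  Internal canonical units are μm and seconds;
pixel-unit inputs are converted at the I/O boundary via ``pixel_size``.
Output files carry provenance (tool version, seed, config hash) as
``#``-prefixed comment lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import FormatError
from .mobility import MobilitySummary, summarize_classes
from .mss import MssConfig
from .segmenter import SegmenterModel
from .tracklets import (
    MSS_MIN_FRAMES,
    TrackletRecord,
    estimate_tracklet_mss,
    split_tracklets,
)

__all__ = [
    "Trajectory",
    "RunConfig",
    "read_trajectories",
    "write_trajectories",
    "write_tracklets",
    "read_tracklets",
    "summary_to_dict",
    "write_summary",
    "run_pipeline",
]

REQUIRED_COLUMNS = ("track_id", "frame", "x", "y")


@dataclass
class Trajectory:
    """One particle track: frames and 2D positions in μm."""

    track_id: str
    frames: np.ndarray  # (T,) int, strictly increasing, no gaps
    positions: np.ndarray  # (T, 2) float, μm
    true_labels: np.ndarray | None = None
    pred_labels: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class RunConfig:
    """Nested run configuration with a master seed and unit declarations."""

    seed: int = 0
    pixel_size: float | None = None  # μm per pixel; None = data already in μm
    frame_interval: float = 0.032  # s
    simulate: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    mss: dict = field(default_factory=dict)
    analyze: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config sections/keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance_lines(seed: int | None = None, config_hash: str | None = None) -> str:
    parts = [f"# dlmss {__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if config_hash is not None:
        parts.append(f"# config: {config_hash}")
    return "\n".join(parts) + "\n"


def read_trajectories(
    path: str | Path,
    pixel_size: float | None = None,
    column_map: dict[str, str] | None = None,
    split_gaps: bool = True,
) -> list[Trajectory]:
    """Read a trajectory CSV into per-track objects.

    ``column_map`` renames foreign column layouts onto the canonical
    ones, e.g. ``{"trajectory": "track_id"}`` for Spot-On style tables.
    Tracks are sorted by frame; a gap in the frame sequence splits the
    track into independent pieces with suffixed ids (interpolating
    across gaps would bias displacement statistics).
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trajectory table lacks required columns {missing}")
    if not np.all(np.isfinite(df[["x", "y"]].to_numpy(dtype=float))):
        raise FormatError("non-finite coordinates in trajectory table")
    out: list[Trajectory] = []
    for tid, g in df.groupby("track_id", sort=False):
        frames = g["frame"].to_numpy(dtype=int)
        order = np.argsort(frames, kind="stable")
        frames = frames[order]
        if np.any(np.diff(frames) == 0):
            raise FormatError(f"track {tid!r} has duplicate frames")
        pos = g[["x", "y"]].to_numpy(dtype=float)[order]
        if pixel_size is not None:
            pos = pos * pixel_size
        tl = g["true_label"].to_numpy(dtype=int)[order] if "true_label" in g else None
        pl = g["pred_label"].to_numpy(dtype=int)[order] if "pred_label" in g else None

        gaps = np.flatnonzero(np.diff(frames) != 1) + 1
        if len(gaps) and not split_gaps:
            raise FormatError(f"track {tid!r} has frame gaps")
        pieces = np.split(np.arange(len(frames)), gaps)
        for j, idx in enumerate(pieces):
            out.append(
                Trajectory(
                    track_id=str(tid) if len(pieces) == 1 else f"{tid}.{j}",
                    frames=frames[idx],
                    positions=pos[idx],
                    true_labels=tl[idx] if tl is not None else None,
                    pred_labels=pl[idx] if pl is not None else None,
                )
            )
    return out


def write_trajectories(
    path: str | Path,
    trajectories: list[Trajectory],
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write tracks to the canonical CSV layout (μm, one point per row)."""
    rows = []
    for tr in trajectories:
        rec: dict[str, np.ndarray] = {
            "track_id": np.repeat(tr.track_id, len(tr)),
            "frame": tr.frames,
            "x": tr.positions[:, 0],
            "y": tr.positions[:, 1],
        }
        if tr.true_labels is not None:
            rec["true_label"] = tr.true_labels
        if tr.pred_labels is not None:
            rec["pred_label"] = tr.pred_labels
        rows.append(pd.DataFrame(rec))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=list(REQUIRED_COLUMNS)
    )
    with open(path, "w") as fh:
        fh.write(_provenance_lines(seed, config_hash))
        df.to_csv(fh, index=False, float_format="%.9f")


def labeled_to_trajectory(labeled, frame0: int = 0) -> Trajectory:
    """Adapter: a simulated LabeledTrajectory as an I/O Trajectory."""
    return Trajectory(
        track_id=str(labeled.track_id),
        frames=np.arange(frame0, frame0 + len(labeled)),
        positions=labeled.positions,
        true_labels=labeled.labels,
    )


def write_tracklets(
    path: str | Path,
    tracklets: list[TrackletRecord],
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "track_id": [t.track_id for t in tracklets],
            "tracklet_id": [t.tracklet_id for t in tracklets],
            "start_frame": [t.start_frame for t in tracklets],
            "n_frames": [t.n_frames for t in tracklets],
            "label": [t.label for t in tracklets],
            "S_mss": [t.S_mss if t.S_mss is not None else np.nan for t in tracklets],
            "D": [t.D if t.D is not None else np.nan for t in tracklets],
            "included_in_clustering": [t.included_in_clustering for t in tracklets],
        }
    )
    with open(path, "w") as fh:
        fh.write(_provenance_lines(seed, config_hash))
        df.to_csv(fh, index=False)


def read_tracklets(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def summary_to_dict(summary: MobilitySummary) -> dict:
    out: dict = {"per_class": {}}
    for lab, cs in summary.per_class.items():
        out["per_class"][str(lab)] = {
            "mean_S_mss": cs.mean_S_mss,
            "mean_D": cs.mean_D,
            "n_tracklets": cs.n_tracklets,
            "n_retained": cs.n_retained,
            "fraction_of_tracklets": cs.fraction_of_tracklets,
            "fraction_of_time_points": cs.fraction_of_time_points,
        }
    if summary.transition_matrix is not None:
        out["transition_matrix"] = np.asarray(summary.transition_matrix).tolist()
    if summary.dwell_stats is not None:
        out["dwell_mean_frames"] = {
            str(lab): st["mean"] for lab, st in summary.dwell_stats.items()
        }
    return out


def write_summary(
    path: str | Path,
    summary: MobilitySummary,
    seed: int | None = None,
    config_hash: str | None = None,
    extra: dict | None = None,
) -> None:
    doc = {
        "tool": f"dlmss {__version__}",
        "seed": seed,
        "config": config_hash,
        **summary_to_dict(summary),
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    trajectories: list[Trajectory],
    model: SegmenterModel,
    mss_config: MssConfig | None = None,
    mss_min_frames: int = MSS_MIN_FRAMES,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    config_hash: str | None = None,
):
    """Segment → split into tracklets → MSS → filter → summarize.

    Returns ``(trajectories, tracklets, summary)`` with predicted labels
    attached; when ``out_dir`` is given, also writes the segmented
    trajectory CSV, the tracklet CSV and the summary JSON.  When tracks
    carry ground-truth labels, the summary gains a per-step accuracy.
    """
    mss_config = mss_config or MssConfig()
    all_tracklets: list[TrackletRecord] = []
    label_sequences = []
    n_correct = 0
    n_steps = 0
    for tr in trajectories:
        if len(tr) < 2:
            continue
        tr.pred_labels = model.predict_points(tr.positions)
        label_sequences.append(tr.pred_labels[:-1])  # step labels
        if tr.true_labels is not None:
            agree = tr.pred_labels[:-1] == tr.true_labels[:-1]
            n_correct += int(np.sum(agree))
            n_steps += len(agree)
        all_tracklets.extend(
            split_tracklets(tr.positions, tr.pred_labels, track_id=tr.track_id)
        )
    estimate_tracklet_mss(all_tracklets, mss_config, min_frames=mss_min_frames)
    if all_tracklets:
        summary = summarize_classes(all_tracklets, label_sequences=label_sequences)
    else:
        import logging

        logging.getLogger(__name__).warning("no usable trajectories; empty outputs")
        summary = MobilitySummary(per_class={})
    extra = {}
    if n_steps:
        extra["step_accuracy_vs_truth"] = n_correct / n_steps
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_trajectories(out_dir / "segmented.csv", trajectories, seed, config_hash)
        write_tracklets(out_dir / "tracklets.csv", all_tracklets, seed, config_hash)
        write_summary(out_dir / "summary.json", summary, seed, config_hash, extra=extra)
    return trajectories, all_tracklets, summary
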