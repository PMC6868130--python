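"""Mobility-class summaries, KDE maps and condition comparisons.

Cluster membership in S_MSS–D space is simply the classifier's label —
no unsupervised clustering is performed.  Per-class means are computed
over the tracklets retained for MSS analysis, while class fractions are
computed over all tracklets (and over all time points), so short or
unstable tracklets still contribute to the population composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDataError, ComparabilityError, ParameterError
from .tracklets import TrackletRecord

__all__ = [
    "ClassStats",
    "MobilitySummary",
    "KdeMap",
    "summarize_classes",
    "scott_bandwidth",
    "kde_map",
    "compare_conditions",
    "empirical_transition_matrix",
    "dwell_times",
]


@dataclass
class ClassStats:
    label: int
    mean_S_mss: float | None
    mean_D: float | None
    n_tracklets: int
    n_retained: int
    fraction_of_tracklets: float
    fraction_of_time_points: float


@dataclass
class MobilitySummary:
    """Aggregate statistics per mobility class for one dataset/condition."""

    per_class: dict[int, ClassStats]
    transition_matrix: np.ndarray | None = None
    dwell_stats: dict[int, dict] | None = None

    @property
    def labels(self) -> list[int]:
        return sorted(self.per_class)


def summarize_classes(
    tracklets: list[TrackletRecord],
    label_sequences: list[np.ndarray] | None = None,
) -> MobilitySummary:
    """Per-class means, fractions and (optionally) switching statistics.

    ``label_sequences`` — per-track label sequences (point- or
    step-level) — enable the empirical class-transition matrix and
    dwell-time statistics.
    """
    if not tracklets:
        raise DegenerateDataError("no tracklets to summarize")
    labels = sorted({t.label for t in tracklets})
    n_total = len(tracklets)
    points_total = sum(t.n_steps for t in tracklets)
    per_class: dict[int, ClassStats] = {}
    for lab in labels:
        mine = [t for t in tracklets if t.label == lab]
        retained = [t for t in mine if t.included_in_clustering and t.S_mss is not None]
        per_class[lab] = ClassStats(
            label=lab,
            mean_S_mss=float(np.mean([t.S_mss for t in retained])) if retained else None,
            mean_D=float(np.mean([t.D for t in retained])) if retained else None,
            n_tracklets=len(mine),
            n_retained=len(retained),
            fraction_of_tracklets=len(mine) / n_total,
            fraction_of_time_points=sum(t.n_steps for t in mine) / points_total,
        )
    transition = None
    dwell = None
    if label_sequences is not None:
        transition = empirical_transition_matrix(label_sequences, labels)
        dwell = dwell_times(label_sequences, labels)
    return MobilitySummary(per_class=per_class, transition_matrix=transition, dwell_stats=dwell)


def empirical_transition_matrix(
    label_sequences: list[np.ndarray], labels: list[int] | None = None
) -> np.ndarray:
    """Row-stochastic matrix of empirical class-switch frequencies."""
    if labels is None:
        labels = sorted({int(v) for seq in label_sequences for v in np.asarray(seq)})
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for seq in label_sequences:
        seq = np.asarray(seq, dtype=int)
        for a, b in zip(seq[:-1], seq[1:]):
            counts[index[a], index[b]] += 1
    rows = counts.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return counts / rows


def dwell_times(
    label_sequences: list[np.ndarray], labels: list[int] | None = None
) -> dict[int, dict]:
    """Per-class dwell statistics: lengths of maximal constant-label runs."""
    if labels is None:
        labels = sorted({int(v) for seq in label_sequences for v in np.asarray(seq)})
    runs: dict[int, list[int]] = {lab: [] for lab in labels}
    for seq in label_sequences:
        seq = np.asarray(seq, dtype=int)
        bounds = np.flatnonzero(np.diff(seq)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(seq)]])
        for s, e in zip(starts, ends):
            runs[int(seq[s])].append(int(e - s))
    return {
        lab: {
            "mean": float(np.mean(r)) if r else float("nan"),
            "n_runs": len(r),
            "lengths": np.array(r, dtype=int),
        }
        for lab, r in runs.items()
    }


def scott_bandwidth(n: int, d: int) -> float:
    """Scott's-rule kernel bandwidth n^(−1/(d+4)) for n points in d dims."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if d < 1:
        raise ParameterError(f"d must be >= 1, got {d}")
    return float(n) ** (-1.0 / (d + 4))


@dataclass
class KdeMap:
    """Gaussian-kernel density over (S_MSS, D) tracklet points."""

    s_grid: np.ndarray  # (ns,) S_MSS axis
    d_grid: np.ndarray  # (nd,) D axis (log10 μm²/s when log_d)
    density: np.ndarray  # (ns, nd), integrates to ~1 over the grid
    bandwidth: float
    log_d: bool = True


def kde_map(
    points: np.ndarray,
    grid_size: int = 128,
    log_d: bool = True,
    pad: float = 0.25,
) -> KdeMap:
    """Kernel density estimate of tracklets in S_MSS–D space.

    A Gaussian product kernel with the scalar Scott bandwidth is applied
    on per-dimension standardized coordinates (S_MSS and D have
    incommensurate units); the density is then mapped back so that it
    integrates to one over the displayed grid.  The D axis is taken in
    log10 by default because mobility classes span decades.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 2:
        raise DegenerateDataError("kde needs at least two (S_mss, D) points")
    s = points[:, 0].copy()
    d = np.log10(points[:, 1]) if log_d else points[:, 1].copy()
    xy = np.column_stack([s, d])
    mu = xy.mean(axis=0)
    sd = xy.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateDataError("kde needs spread in both dimensions")
    z = (xy - mu) / sd
    bw = scott_bandwidth(len(points), 2)

    span_s = s.max() - s.min()
    span_d = d.max() - d.min()
    s_grid = np.linspace(s.min() - pad * span_s, s.max() + pad * span_s, grid_size)
    d_grid = np.linspace(d.min() - pad * span_d, d.max() + pad * span_d, grid_size)
    zs = (s_grid - mu[0]) / sd[0]
    zd = (d_grid - mu[1]) / sd[1]
    # separable Gaussian kernel evaluated on the standardized grid
    ks = np.exp(-0.5 * ((zs[:, None] - z[None, :, 0]) / bw) ** 2)
    kd = np.exp(-0.5 * ((zd[:, None] - z[None, :, 1]) / bw) ** 2)
    dens = ks @ kd.T / (len(points) * 2 * np.pi * bw**2 * sd[0] * sd[1])
    return KdeMap(s_grid=s_grid, d_grid=d_grid, density=dens, bandwidth=bw, log_d=log_d)


@dataclass
class ConditionDelta:
    label: int
    delta_fraction: float
    delta_mean_S_mss: float | None
    delta_mean_D: float | None


def compare_conditions(
    summary_a: MobilitySummary, summary_b: MobilitySummary
) -> dict[int, ConditionDelta]:
    """Per-class changes (b − a) in fraction and cluster means.

    Conditions must share the same class labels; no statistical test is
    attached — the comparison is descriptive.
    """
    if summary_a.labels != summary_b.labels:
        raise ComparabilityError(
            f"class sets differ: {summary_a.labels} vs {summary_b.labels}"
        )
    out = {}
    for lab in summary_a.labels:
        a, b = summary_a.per_class[lab], summary_b.per_class[lab]
        ds = (
            b.mean_S_mss - a.mean_S_mss
            if (a.mean_S_mss is not None and b.mean_S_mss is not None)
            else None
        )
        dd = (
            b.mean_D - a.mean_D
            if (a.mean_D is not None and b.mean_D is not None)
            else None
        )
        out[lab] = ConditionDelta(
            label=lab,
            delta_fraction=b.fraction_of_tracklets - a.fraction_of_tracklets,
            delta_mean_S_mss=ds,
            delta_mean_D=dd,
        )
    return out
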