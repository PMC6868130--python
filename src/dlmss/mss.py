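"""Moment-scaling-spectrum (MSS) analysis of trajectories.

For a trajectory x(t), the p-th displacement moment at lag τ,
``⟨|x|^p⟩(τ) = mean over t of ‖x(t+τ) − x(t)‖^p``, scales as τ^γ_p.
The exponents γ_p as a function of moment order p form the moment
scaling spectrum; its slope S_MSS classifies the motion type:

* S_MSS = 0.5 — pure diffusion,
* 0 < S_MSS < 0.5 — restricted (subdiffusive) motion,
* 0.5 < S_MSS < 1.0 — directed (superdiffusive) motion.

The diffusion constant D comes from the log-log fit of the second
moment against lag time in seconds, with the fitted line evaluated at
the first lag τ₁: D = m̂₂(τ₁)/(4τ₁).  For pure diffusion in 2D this is
the standard ⟨|x|²⟩ = 4Dτ relation; for anomalous motion it is a
generalized transport coefficient at the frame timescale — one
convention valid across motion types.  (Evaluating at the first lag
rather than extrapolating the intercept to τ = 1 s keeps the estimate
nearly unbiased on short tracklets, where intercept noise would
otherwise inflate exp(intercept).)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDataError, LagError, ParameterError

__all__ = [
    "MssConfig",
    "MssResult",
    "empirical_moment",
    "pooled_moment",
    "moment_lags",
    "estimate_gamma",
    "estimate_mss",
]


@dataclass(frozen=True)
class MssConfig:
    """Parameters of the MSS estimation.

    moment_orders
        Moment orders p entering the spectrum (default 1..6).
    max_lag_fraction
        Largest lag used in the log-log fits, as a fraction of the
        number of displacement steps (default 0.1).  Short lag ranges
        are preferred because the empirical log-moment at lags
        comparable to the track length has few effective samples, and
        its downward (Jensen) bias tilts the fitted exponents.
    min_lags
        Lower floor on the number of distinct lags (default 3).
    tau_seconds
        Frame interval in seconds; converts lags to physical time so
        that D comes out in μm²/s.
    """

    moment_orders: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    max_lag_fraction: float = 0.1
    min_lags: int = 3
    tau_seconds: float = 0.032

    def __post_init__(self) -> None:
        if len(self.moment_orders) == 0 or any(p <= 0 for p in self.moment_orders):
            raise ParameterError("moment_orders must be non-empty and positive")
        if not 0.0 < self.max_lag_fraction <= 0.5:
            raise ParameterError(
                f"max_lag_fraction must be in (0, 0.5], got {self.max_lag_fraction}"
            )
        if self.min_lags < 2:
            raise ParameterError(f"min_lags must be >= 2, got {self.min_lags}")
        if self.tau_seconds <= 0:
            raise ParameterError(f"tau_seconds must be > 0, got {self.tau_seconds}")
        object.__setattr__(self, "moment_orders", tuple(self.moment_orders))


@dataclass
class MssResult:
    """Per-tracklet MSS estimates."""

    gamma: dict[int, float]
    S_mss: float
    D: float
    r2_second_moment: float
    stable: bool = True

    @property
    def unstable(self) -> bool:
        return not self.stable


def empirical_moment(positions: np.ndarray, p: float, tau: int) -> float:
    """p-th displacement moment of one track at integer lag ``tau`` (frames).

    The displacement magnitude is the 2D Euclidean norm; the mean runs
    over all T − τ ordered pairs (t, t+τ).
    """
    positions = np.asarray(positions, dtype=float)
    if tau < 1:
        raise LagError(f"tau must be >= 1 frame, got {tau}")
    if len(positions) <= tau:
        raise LagError(f"lag {tau} needs more than {tau} positions, got {len(positions)}")
    disp = positions[tau:] - positions[:-tau]
    r = np.hypot(disp[..., 0], disp[..., 1])
    return float(np.mean(r**p))


def pooled_moment(tracks: list[np.ndarray], p: float, tau: int) -> float:
    """Displacement moment pooled over several tracks.

    The double sum over tracks and pairs is normalized by the total
    number of (t, t+τ) pairs contributed by all tracks long enough.
    """
    total = 0.0
    count = 0
    for pos in tracks:
        pos = np.asarray(pos, dtype=float)
        if len(pos) <= tau:
            continue
        disp = pos[tau:] - pos[:-tau]
        r = np.hypot(disp[:, 0], disp[:, 1])
        total += float(np.sum(r**p))
        count += len(r)
    if count == 0:
        raise LagError(f"no track long enough for lag {tau}")
    return total / count


def moment_lags(n_positions: int, cfg: MssConfig) -> np.ndarray:
    """Lags (frames) entering the log-log fits for a track of given length."""
    n_steps = n_positions - 1
    max_lag = max(cfg.min_lags, int(cfg.max_lag_fraction * n_steps))
    max_lag = min(max_lag, n_steps)  # cannot exceed the number of steps
    if max_lag < cfg.min_lags:
        raise LagError(
            f"track with {n_positions} positions supports only {max_lag} lags, "
            f"need at least {cfg.min_lags}"
        )
    return np.arange(1, max_lag + 1)


def _log_moments(positions: np.ndarray, p: float, lags: np.ndarray, tau_seconds: float):
    m = np.array([empirical_moment(positions, p, int(t)) for t in lags])
    if np.any(m <= 0):
        raise DegenerateDataError(
            f"zero displacement moment at order p={p} (stationary points)"
        )
    return np.log(lags * tau_seconds), np.log(m)


def estimate_gamma(
    positions: np.ndarray, p: float, cfg: MssConfig = MssConfig()
) -> float:
    """Scaling exponent γ_p: OLS slope of log moment vs log lag."""
    positions = np.asarray(positions, dtype=float)
    lags = moment_lags(len(positions), cfg)
    lx, ly = _log_moments(positions, p, lags, cfg.tau_seconds)
    slope, _ = np.polyfit(lx, ly, 1)
    return float(slope)


def _d_from_fit(slope, intercept, lx, ly, tau_seconds):
    """D from the fitted second-moment line evaluated at the first lag."""
    log_tau1 = np.log(tau_seconds)
    m2_tau1 = np.exp(slope * log_tau1 + intercept)
    D = float(m2_tau1 / (4.0 * tau_seconds))
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return D, r2


def estimate_mss(positions: np.ndarray, cfg: MssConfig = MssConfig()) -> MssResult:
    """Full MSS estimate for one tracklet: γ_p spectrum, S_MSS and D.

    S_MSS is the least-squares slope of γ_p versus p constrained through
    the origin (γ₀ = 0 holds identically, since the zeroth moment is 1).
    A result with negative D or negative S_MSS is flagged unstable; such
    tracklets are excluded from clustering downstream.
    """
    positions = np.asarray(positions, dtype=float)
    lags = moment_lags(len(positions), cfg)

    gamma: dict[int, float] = {}
    D = np.nan
    r2 = np.nan
    stable = True
    try:
        for p in cfg.moment_orders:
            lx, ly = _log_moments(positions, p, lags, cfg.tau_seconds)
            slope, intercept = np.polyfit(lx, ly, 1)
            gamma[p] = float(slope)
            if p == 2:
                D, r2 = _d_from_fit(slope, intercept, lx, ly, cfg.tau_seconds)
        if 2 not in cfg.moment_orders:
            # D always comes from the second moment, even if p=2 is not in
            # the requested spectrum orders.
            lx, ly = _log_moments(positions, 2, lags, cfg.tau_seconds)
            slope, intercept = np.polyfit(lx, ly, 1)
            D, r2 = _d_from_fit(slope, intercept, lx, ly, cfg.tau_seconds)
    except DegenerateDataError:
        return MssResult(gamma={}, S_mss=np.nan, D=np.nan, r2_second_moment=np.nan, stable=False)

    orders = np.array(list(gamma.keys()), dtype=float)
    gammas = np.array(list(gamma.values()), dtype=float)
    # through-origin fit, anchored by the exact point (p=0, γ=0)
    S_mss = float(np.sum(orders * gammas) / np.sum(orders**2))

    if not np.isfinite(D) or D < 0 or S_mss < 0:
        stable = False
    return MssResult(gamma=gamma, S_mss=S_mss, D=D, r2_second_moment=r2, stable=stable)
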