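"""Simulation of mobility-switching 2D particle trajectories.

Trajectories alternate between motion states according to a first-order
Markov chain.  Two kinds of state are supported:

* ``brownian`` — pure diffusion with diffusion constant ``D`` (μm²/s);
  each displacement coordinate is drawn i.i.d. from N(0, 2Dτ).
* ``fbm`` — fractional Brownian motion with Hurst exponent ``H``; by
  default increments are exact fractional Gaussian noise (Cholesky factor
  of the exact increment covariance applied to an i.i.d. normal stream),
  with every displacement scaled by a factor ``eta``.  A finite-memory
  moving-average construction is available as an alternative
  (``FbmParams(method="ma")``).

Track lengths are exponentially distributed (rounded up, floored at a
minimum length) so that the simulated population mimics the wide length
spread of real single-particle-tracking experiments.  All randomness flows
through a single ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import ParameterError, ValidationError

__all__ = [
    "MotionState",
    "SwitchingModel",
    "FbmParams",
    "LabeledTrajectory",
    "three_state_model",
    "sample_track_length",
    "sample_state_sequence",
    "simulate_brownian_steps",
    "fbm_kernel",
    "simulate_fbm_steps",
    "simulate_track",
    "simulate_dataset",
]


@dataclass(frozen=True)
class MotionState:
    """One mobility class of the switching model.

    Parameters
    ----------
    label
        Integer class id emitted as the per-step ground-truth label.
    kind
        ``"brownian"`` (parameterized by ``D``) or ``"fbm"``
        (parameterized by ``H`` and ``eta``).
    D
        Diffusion constant in μm²/s (brownian states).
    H
        Hurst exponent in (0, 1) (fbm states); 0.5 is pure diffusion,
        below 0.5 subdiffusive, above 0.5 superdiffusive.
    eta
        Dimensionless displacement scaling applied to fbm increments.
    """

    label: int
    kind: Literal["brownian", "fbm"]
    D: float | None = None
    H: float | None = None
    eta: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "brownian":
            if self.D is None or self.D < 0:
                raise ParameterError(f"brownian state needs D >= 0, got {self.D}")
        elif self.kind == "fbm":
            if self.H is None or not 0.0 < self.H < 1.0:
                raise ParameterError(f"fbm state needs 0 < H < 1, got {self.H}")
            if self.eta is None or self.eta <= 0:
                raise ParameterError(f"fbm state needs eta > 0, got {self.eta}")
        else:
            raise ParameterError(f"unknown state kind {self.kind!r}")


@dataclass(frozen=True)
class FbmParams:
    """How fractional-Brownian increments are generated.

    ``method="exact"`` (default) draws exact fractional Gaussian noise:
    the lower Cholesky factor of the exact increment covariance is
    applied to an i.i.d. standard-normal stream (one draw per emitted
    step).  This reproduces the fBm autocovariance at every lag, which
    matters for recovering the Hurst exponent from moment scaling.

    ``method="ma"`` uses a causal finite-memory moving-average of a
    white-noise stream: ``n`` subintervals per frame and a memory
    horizon of ``M`` frames, the power-law kernel integrated exactly
    over each subinterval.  This construction is cheap and streaming
    but underestimates the anti-correlation of strongly subdiffusive
    increments (H well below 0.5) at finite ``n``, ``M``.
    """

    n: int = 5
    M: int = 100
    method: Literal["exact", "ma"] = "exact"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError(f"n must be >= 1, got {self.n}")
        if self.M < 2:
            raise ParameterError(f"M must be >= 2, got {self.M}")
        if self.method not in ("exact", "ma"):
            raise ParameterError(f"unknown fbm method {self.method!r}")


def _validate_transition_matrix(Pi: np.ndarray, n_states: int | None = None) -> np.ndarray:
    Pi = np.asarray(Pi, dtype=float)
    if Pi.ndim != 2 or Pi.shape[0] != Pi.shape[1]:
        raise ValidationError(f"transition matrix must be square, got shape {Pi.shape}")
    if n_states is not None and Pi.shape[0] != n_states:
        raise ValidationError(
            f"transition matrix is {Pi.shape[0]}x{Pi.shape[0]} but model has {n_states} states"
        )
    if np.any(Pi < 0) or np.any(Pi > 1):
        raise ValidationError("transition probabilities must lie in [0, 1]")
    if not np.allclose(Pi.sum(axis=1), 1.0, rtol=0, atol=1e-12):
        raise ValidationError("every row of the transition matrix must sum to 1")
    return Pi


@dataclass(frozen=True)
class SwitchingModel:
    """A set of motion states plus the Markov dynamics that mix them."""

    states: tuple[MotionState, ...]
    Pi: np.ndarray
    lambda_len: float = 1.0 / 50.0  # rate of the exponential track-length law, 1/frames
    tau: float = 0.032  # frame interval, s
    min_len: int = 25  # shortest emitted track, frames

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        Pi = _validate_transition_matrix(self.Pi, len(self.states))
        object.__setattr__(self, "Pi", Pi)
        if self.lambda_len <= 0:
            raise ParameterError(f"lambda_len must be > 0, got {self.lambda_len}")
        if self.tau <= 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")
        labels = [s.label for s in self.states]
        if labels != list(range(len(labels))):
            raise ValidationError("state labels must be 0..K-1 in order")


@dataclass
class LabeledTrajectory:
    """Ordered 2D positions (μm) with one ground-truth state id per point."""

    positions: np.ndarray  # (T, 2) float
    labels: np.ndarray  # (T,) int
    track_id: str = "0"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.positions) != len(self.labels):
            raise ValidationError("positions and labels must have equal length")

    def __len__(self) -> int:
        return len(self.positions)


def three_state_model(
    lambda_len: float = 1.0 / 50.0, tau: float = 0.032, min_len: int = 25
) -> SwitchingModel:
    """The reference three-state model used to train the classifier.

    State 0: fast diffusion, D = 1.0 μm²/s.
    State 1: slow diffusion, D = 0.1 μm²/s.
    State 2: immobile, fBm with H = 0.1 scaled by η = 0.3.
    Symmetric switching: stay with probability 0.8, switch to either
    other state with probability 0.1.
    """
    states = (
        MotionState(label=0, kind="brownian", D=1.0),
        MotionState(label=1, kind="brownian", D=0.1),
        MotionState(label=2, kind="fbm", H=0.1, eta=0.3),
    )
    Pi = np.array(
        [
            [0.8, 0.1, 0.1],
            [0.1, 0.8, 0.1],
            [0.1, 0.1, 0.8],
        ]
    )
    return SwitchingModel(states=states, Pi=Pi, lambda_len=lambda_len, tau=tau, min_len=min_len)


def sample_track_length(
    lambda_len: float, min_len: int, rng: np.random.Generator
) -> int:
    """Draw a track length (frames) from Exp(lambda_len), floored at ``min_len``.

    The continuous draw is rounded up to an integer number of frames;
    draws below ``min_len`` are re-sampled from the tail (equivalently,
    by memorylessness, shifted by ``min_len``).
    """
    if lambda_len <= 0:
        raise ParameterError(f"lambda_len must be > 0, got {lambda_len}")
    for _ in range(1000):
        length = math.ceil(rng.exponential(scale=1.0 / lambda_len))
        if length >= min_len:
            return length
    # Pathologically large lambda: essentially all mass below the floor.
    return int(min_len)


def sample_state_sequence(
    Pi: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    init: int | None = None,
) -> np.ndarray:
    """Sample a Markov state sequence of length ``n_steps`` from matrix ``Pi``.

    The initial state is uniform over states unless ``init`` is given.
    """
    Pi = _validate_transition_matrix(Pi)
    if n_steps < 1:
        raise ParameterError(f"n_steps must be >= 1, got {n_steps}")
    k = Pi.shape[0]
    cum = np.cumsum(Pi, axis=1)
    out = np.empty(n_steps, dtype=np.int64)
    if init is None:
        state = int(rng.integers(k))
    else:
        if not 0 <= init < k:
            raise ValidationError(f"init state {init} outside 0..{k - 1}")
        state = int(init)
    out[0] = state
    u = rng.random(n_steps - 1)
    for t in range(1, n_steps):
        state = int(np.searchsorted(cum[state], u[t - 1], side="right"))
        if state >= k:  # guard against u == 1.0 rounding
            state = k - 1
        out[t] = state
    return out


def simulate_brownian_steps(
    D: float, tau: float, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. Brownian displacements: each coordinate ~ N(0, 2Dτ)."""
    if D < 0:
        raise ParameterError(f"D must be >= 0, got {D}")
    if tau <= 0:
        raise ParameterError(f"tau must be > 0, got {tau}")
    sigma = math.sqrt(2.0 * D * tau)
    return rng.normal(0.0, sigma, size=(n_steps, 2))


def fbm_kernel(H: float, fbm: FbmParams) -> np.ndarray:
    """Moving-average weights of the finite-memory fBm increment.

    Returns the length ``n*M`` weight vector ``w`` (oldest noise sample
    first) such that the increment at frame t is
    ``Σ_j w[j] ξ[n*t + j]`` over a white-noise stream ξ.  The power-law
    kernel ``s^(H-1/2)`` is integrated exactly over each subinterval
    (endpoint sampling converges too slowly near the s→0 singularity
    for H < 1/2).  At H = 0.5 the memory weights vanish and the
    increment reduces to a unit-variance Gaussian.
    """
    if not 0.0 < H < 1.0:
        raise ParameterError(f"H must be in (0, 1), got {H}")
    n, M = fbm.n, fbm.M
    a = H + 0.5
    w = np.empty(n * M, dtype=float)
    # Recent block (j = n(M-1)..nM-1 zero-based), i = nM - j counts back
    # from the current frame: integral of s^(H-1/2) over [i-1, i].
    i_recent = np.arange(1, n + 1, dtype=float)
    w[n * M - i_recent.astype(int)] = (i_recent**a - (i_recent - 1) ** a) / a
    # Memory block (j = 0..n(M-1)-1), i = n(M-1) - j: difference of the
    # same integral shifted by one frame (n subintervals).
    i_mem = np.arange(1, n * (M - 1) + 1, dtype=float)
    w[n * (M - 1) - i_mem.astype(int)] = (
        (n + i_mem) ** a - (n + i_mem - 1) ** a - (i_mem**a - (i_mem - 1) ** a)
    ) / a
    return (float(n) ** -H / math.gamma(H + 0.5)) * w


# Reference diffusion constant (μm²/s) whose r.m.s. frame step defines
# the physical unit of the dimensionless fBm increments in the switching
# simulator.  With τ = 0.032 s the immobile state's per-frame jitter is
# η·sqrt(2·0.1·τ) ≈ 0.024 μm — the scale of single-molecule
# localization error (~17 nm per coordinate), an order of magnitude
# below the slow diffusive state in MSS D, as an immobile class must be.
FBM_REFERENCE_D = 0.1

# Cached Cholesky factors of exact fGn covariances, keyed by (H, size).
_FGN_CHOL_CACHE: dict[tuple[float, int], np.ndarray] = {}
_FGN_CACHE_MAX = 2048


def fgn_covariance(H: float, n_lags: int) -> np.ndarray:
    """Exact unit-variance fractional-Gaussian-noise autocovariance γ(0..n_lags-1)."""
    k = np.arange(n_lags, dtype=float)
    return 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))


def _fgn_cholesky_factor(H: float, n_steps: int) -> np.ndarray:
    """Lower Cholesky factor of the exact fGn covariance, cached.

    Cache entries are powers of two so short runs of many lengths share
    one factor (the leading block of a Toeplitz Cholesky factor is the
    factor of the leading submatrix).
    """
    size = 64
    while size < n_steps:
        size *= 2
    key = (round(float(H), 12), size)
    factor = _FGN_CHOL_CACHE.get(key)
    if factor is None:
        from scipy.linalg import toeplitz

        factor = np.linalg.cholesky(toeplitz(fgn_covariance(H, size)))
        _FGN_CHOL_CACHE[key] = factor
    return factor[:n_steps, :n_steps]


def _fgn_hosking(H: float, xi: np.ndarray) -> np.ndarray:
    """Exact fGn by the Hosking (Durbin–Levinson) recursion, O(N) memory.

    Used for sequences too long for a dense Cholesky factor; consumes
    exactly one standard-normal draw per emitted sample, like the
    Cholesky route.
    """
    n = len(xi)
    gamma = fgn_covariance(H, n)
    x = np.empty(n)
    v = gamma[0]
    x[0] = math.sqrt(v) * xi[0]
    phi = np.empty(0)
    for t in range(1, n):
        if t == 1:
            kappa = gamma[1] / gamma[0]
        else:
            kappa = (gamma[t] - phi @ gamma[t - 1 : 0 : -1]) / v
        phi = np.concatenate([phi - kappa * phi[::-1], [kappa]])
        v *= 1.0 - kappa**2
        x[t] = phi @ x[t - 1 :: -1] + math.sqrt(v) * xi[t]
    return x


def _fbm_1d(
    kernel: np.ndarray, n: int, n_steps: int, rng: np.random.Generator,
    xi: np.ndarray | None = None,
) -> np.ndarray:
    """One coordinate of fBm increments by convolving a noise stream."""
    need = n * n_steps + len(kernel)
    if xi is None:
        xi = rng.standard_normal(need)
    else:
        xi = np.asarray(xi, dtype=float)
        if len(xi) < need:
            raise ParameterError(f"injected noise stream too short: {len(xi)} < {need}")
    windows = np.lib.stride_tricks.sliding_window_view(xi, len(kernel))
    return windows[n : n * n_steps + 1 : n] @ kernel


def simulate_fbm_steps(
    H: float,
    fbm: FbmParams,
    eta: float,
    n_steps: int,
    rng: np.random.Generator,
    xi_x: np.ndarray | None = None,
    xi_y: np.ndarray | None = None,
    step_unit: float = 1.0,
) -> np.ndarray:
    """Fractional-Brownian displacements, (n_steps, 2) in μm.

    x and y use independent noise streams; every emitted displacement is
    multiplied by ``eta * step_unit``.  ``step_unit`` converts the
    dimensionless unit-variance fractional noise into physical
    displacement units; the switching simulator passes the r.m.s. frame
    step of a reference ``FBM_REFERENCE_D`` diffuser, so that ``eta``
    reads as relative jitter.
    ``xi_x``/``xi_y`` allow injecting a fixed noise stream (testing
    hook); the construction is linear in the noise, so an all-zero
    stream yields all-zero displacements.
    """
    if n_steps < 1:
        raise ParameterError(f"n_steps must be >= 1, got {n_steps}")
    if eta <= 0:
        raise ParameterError(f"eta must be > 0, got {eta}")
    if not 0.0 < H < 1.0:
        raise ParameterError(f"H must be in (0, 1), got {H}")
    if fbm.method == "exact":
        if n_steps > _FGN_CACHE_MAX:
            dx = _fgn_hosking(H, _take_noise(n_steps, rng, xi_x))
            dy = _fgn_hosking(H, _take_noise(n_steps, rng, xi_y))
        else:
            factor = _fgn_cholesky_factor(H, n_steps)
            dx = factor @ _take_noise(n_steps, rng, xi_x)
            dy = factor @ _take_noise(n_steps, rng, xi_y)
    else:
        kernel = fbm_kernel(H, fbm)
        dx = _fbm_1d(kernel, fbm.n, n_steps, rng, xi_x)
        dy = _fbm_1d(kernel, fbm.n, n_steps, rng, xi_y)
    return eta * step_unit * np.column_stack([dx, dy])


def _take_noise(
    n: int, rng: np.random.Generator, xi: np.ndarray | None
) -> np.ndarray:
    if xi is None:
        return rng.standard_normal(n)
    xi = np.asarray(xi, dtype=float)
    if len(xi) < n:
        raise ParameterError(f"injected noise stream too short: {len(xi)} < {n}")
    return xi[:n]


def _steps_for_labels(
    labels: np.ndarray,
    model: SwitchingModel,
    fbm: FbmParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Displacements for a label sequence; step t is driven by labels[t].

    fBm noise history is maintained within a run of consecutive fbm
    steps and reset each time the track re-enters the fbm state.
    """
    n_steps = len(labels)
    steps = np.empty((n_steps, 2), dtype=float)
    # iterate maximal runs of constant label
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n_steps]])
    for s, e in zip(starts, ends):
        state = model.states[labels[s]]
        if state.kind == "brownian":
            steps[s:e] = simulate_brownian_steps(state.D, model.tau, e - s, rng)
        else:
            # unit-variance fractional noise expressed in μm via the
            # r.m.s. frame step of the reference diffuser
            unit = math.sqrt(2.0 * FBM_REFERENCE_D * model.tau)
            steps[s:e] = simulate_fbm_steps(
                state.H, fbm, state.eta, e - s, rng, step_unit=unit
            )
    return steps


def simulate_track(
    model: SwitchingModel,
    fbm: FbmParams,
    rng: np.random.Generator,
    track_id: str = "0",
    n_frames: int | None = None,
    init: int | None = None,
) -> LabeledTrajectory:
    """Simulate one labeled switching trajectory starting at the origin."""
    if n_frames is None:
        n_frames = sample_track_length(model.lambda_len, model.min_len, rng)
    labels = sample_state_sequence(model.Pi, n_frames, rng, init=init)
    steps = _steps_for_labels(labels[:-1], model, fbm, rng)
    positions = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return LabeledTrajectory(positions=positions, labels=labels, track_id=track_id)


def simulate_dataset(
    model: SwitchingModel,
    fbm: FbmParams,
    n_tracks: int,
    rng: np.random.Generator,
) -> list[LabeledTrajectory]:
    """Simulate ``n_tracks`` labeled trajectories (training-style dataset)."""
    return [
        simulate_track(model, fbm, rng, track_id=str(i)) for i in range(n_tracks)
    ]
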