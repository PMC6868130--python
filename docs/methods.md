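# Methods

## Model overview

A trajectory is a sequence of 2D localizations x(t) ∈ ℝ², one per
frame (frame interval τ, canonical units μm and seconds). The method
has two uncoupled stages:

1. **Per-step classification.** A bidirectional LSTM assigns one of
   K = 3 mobility labels to every displacement step. It is trained
   exclusively on simulated switching trajectories, so no annotated
   real data is needed.
2. **Tracklet characterization.** Maximal same-label runs
   ("tracklets") are characterized by the slope of the moment scaling
   spectrum (S_MSS) and a diffusion constant (D); per-class aggregates
   (means, fractions, switching matrix, dwell times, KDE maps)
   summarize a dataset.

The key assumption is that the simulated training classes span the
motion phenomenology of the real data (free diffusion at two speeds,
plus apparent immobility); the classifier then transfers because the
features are translation-invariant and capture local displacement
statistics rather than absolute geometry.

## Trajectory simulator

**Switching.** States follow a first-order Markov chain over frames
with row-stochastic transition matrix Π; the reference model uses
p_stay = 0.8, p_switch = 0.1 to each other state, which makes dwell
times geometric with mean 5 frames and a uniform stationary
distribution. Track lengths are Exp(λ) with λ = 1/50 frames⁻¹
(re-sampled below the floor; rounded up to whole frames), floored at
min_len = 25 so every training track yields at least one window. λ is
not a measured quantity; 1/50 gives a length distribution comparable
to a few training windows per track and is configurable.

**Brownian states.** Each displacement coordinate is i.i.d.
N(0, 2Dτ). Reference states: D = 1.0 (label 0, "fast") and D = 0.1
μm²/s (label 1, "slow"); τ = 0.032 s (a typical EMCCD frame interval;
the simulation τ need not match the data's).

**Immobile state (label 2).** A bound molecule's apparent motion is
dominated by localization error, which produces strongly
anti-persistent apparent steps. We model it as fractional Brownian
motion with Hurst exponent H = 0.1, whose increments (fractional
Gaussian noise, fGn) have lag-1 autocorrelation
0.5·(2^{2H} − 2) ≈ −0.43 and MSD ∼ τ^{2H}.

*Generation.* The default generator draws **exact** fGn: the lower
Cholesky factor of the exact increment covariance
γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) is applied to an i.i.d.
standard-normal stream, one draw per emitted step (factors are cached
per (H, length); sequences beyond the cache cap use the Hosking
recursion, which is also exact). An alternative finite-memory
moving-average construction (`FbmParams(method="ma")`, parameters n
subintervals/frame and memory M frames, power-law kernel integrated
exactly over each subinterval) is retained for streaming use, but it
underestimates the anti-correlation of strongly subdiffusive
increments at any practical (n, M) — measured apparent γ₂ ≈ 0.26
instead of 2H = 0.2 at H = 0.1 — which is why it is not the default:
the exact generator is required for S_MSS to recover H within ±0.05.
Within a track, the fGn history persists across consecutive immobile
steps and is reset whenever the track re-enters the immobile state
(a switch represents a changed physical attachment).

*Scale.* fGn is dimensionless; the scaling factor η = 0.3 needs a
physical unit. We use the r.m.s. frame step of a reference diffuser
with D_ref = 0.1 μm²/s (the slow state), giving per-coordinate jitter
η·√(2·D_ref·τ) ≈ 0.024 μm ≈ 17 nm localization error per coordinate —
a realistic precision for bright organic dyes, and it places the
immobile cluster an order of magnitude below the slow state in D, as
an immobile class must sit. The unit is exposed as
`trajsim.FBM_REFERENCE_D`. (Tying η to the unit-variance noise
directly would give 0.3 μm steps — *larger* than the fast state's,
which neither resembles immobility nor permits reliable
classification.)

## Features and windows

For step t (between points t and t+1): step length ‖Δx_t‖; the x, y
of both flanking points, centered on the centroid of the featurized
stretch (training windows are centered per window, inference per
trajectory); and normalized lag distances ‖x(t+k′) − x(t)‖/k′ for
k ∈ {2, 3, 4} with k′ shrunk near the track end. Centering makes the
features exactly translation invariant; the lag distances add
multi-scale context that separates persistent from anti-persistent
motion. Per-feature z-scoring statistics are computed on the training
set and frozen into the saved model. Training uses non-overlapping
25-step windows (trailing remainders discarded); inference featurizes
the full sequence and never windows.

## Classifier and training

One bidirectional LSTM layer (200 hidden units per direction,
orthogonal recurrent initialization, forget bias 1) feeds a per-step
dense softmax. Implemented directly in NumPy (forward, BPTT, Adam);
gradients are verified against finite differences in the test suite.
Training: categorical cross-entropy, Adam (base rate 7·10⁻³, cosine
decay to a tenth over the epoch budget, global gradient-norm clip 5),
batch size 256, early stopping on validation loss (patience 10) with
best-weights restoration. Repeated random splits of the simulated
window pool (10 splits of 10000/5000/5000 at full scale) estimate the
accuracy spread. Per-split seeds derive deterministically from one
master seed; the same seed reproduces the same data, splits and
weights.

Problem sizes used by the shipped tests and the acceptance script are
a reduced protocol — 2000/1000/1000 windows, one split, 20 epochs —
chosen so a complete run finishes in about a minute on one CPU; it
reaches ≈0.885 test / ≈0.905 train per-step accuracy. Most residual
errors lie on the one or two steps flanking each mobility switch,
where the label is genuinely ambiguous at 5-frame dwells.

## MSS estimation

Per tracklet, the empirical moment ⟨|x|^p⟩(τ) (2D Euclidean
displacement magnitude; all T − τ ordered pairs; a pooled multi-track
variant normalizes by the total pair count) is computed for p = 1..6
at integer lags τ = 1..max(3, ⌊0.1·(T−1)⌋) frames. γ_p is the OLS
slope of log-moment versus log-lag; S_MSS is the least-squares slope
of γ_p versus p constrained through the origin (γ₀ = 0 identically).

Numerical choices:

* **Lag range 10%** of the steps (floor 3): log-moments at lags
  comparable to the tracklet length have few effective samples and a
  downward Jensen bias that tilts the exponents; with a 1/3 lag range
  the mean Brownian S_MSS comes out ≈0.45 instead of ≈0.49.
* **D from the fitted second-moment line evaluated at the first lag**,
  D = m̂₂(τ₁)/(4τ₁): for pure diffusion this is the 2D closed form
  ⟨|x|²⟩ = 4Dτ; evaluating at τ₁ (instead of exponentiating the
  intercept at τ = 1 s) avoids a ≈35% convexity inflation on short
  tracklets.
* Zero moments (stationary points) and fits with negative D or
  negative S_MSS mark the tracklet *unstable*; it keeps its class
  label but is excluded from clustering.

## Tracklets

Runs are taken over step labels (step t carries the label of point t,
matching the classifier's output; a point-level labeling assigns the
last step's label to the final point). The tracklet for a step run
[s..e] spans points [s..e+1]: boundary points belong to both adjacent
tracklets, so the step intervals tile the track exactly (step counts
sum to T−1) and every tracklet has ≥ 2 points. Only tracklets of more
than ten frames (≥ 11, configurable) with stable fits enter
clustering; shorter ones still count toward class fractions and
inherit their class's aggregate properties.

## Mobility summaries

Cluster assignment is the class label — no unsupervised clustering.
Per-class means are over retained tracklets; fractions (of tracklets
and of time points) are over all tracklets. Label sequences yield the
empirical class-switching matrix and dwell-time statistics. KDE maps
use a Gaussian product kernel with the scalar Scott bandwidth
n^(−1/(d+4)) on per-dimension standardized coordinates (S_MSS and D
have incommensurate units), jointly over all classes; the D axis is
log₁₀ by default because classes span decades. Sub-clustering is
supported only as re-running the analysis on one class's subset.
Condition comparison reports per-class Δfraction and Δmeans with no
attached test.

## What the simulations do and do not show

The simulator reproduces switching statistics, two diffusive speeds
and an anti-persistent immobile state, but not localization noise on
the *mobile* states, motion blur, blinking/gap artifacts, drift, or 3D
effects. Passing tests therefore demonstrate correctness of the
machinery and parameter recovery under the generative model, not
tracking-artifact robustness. Known limitations: D estimates on
high-frame-rate data are inflated by localization error (no correction
is applied); accuracy at state switches is bounded by the ambiguity of
single boundary steps; very short tracklets inherit class properties
rather than individual estimates.
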