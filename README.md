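# dlmss

Mobility analysis of single-particle tracking (SPT) trajectories:
a recurrent neural network segments each trajectory, time step by time
step, into *tracklets* of consistent motion, and moment-scaling-spectrum
(MSS) analysis then characterizes every mobility class by its motion
type and diffusion constant.

## Who this is for

Live-cell SPT experiments (nuclear proteins, membrane receptors,
viruses, ...) yield thousands of particle trajectories whose molecules
*switch* between behaviors — e.g. a DNA-repair protein alternating
between free diffusion and chromatin-bound immobility. Classical MSD
analysis assumes one motion type per track and misses these switches.
`dlmss` is for researchers who have tracking output (a CSV of
per-frame coordinates) and want, per dataset: the mobility classes
present, their motion type and diffusion constant, the fraction of
particles in each class, and how those fractions shift between
conditions (e.g. ± ionizing radiation).

## The method

**Segmentation.** A bidirectional LSTM (200 hidden units per
direction, per-step softmax over 3 classes) is trained purely on
simulated trajectories that switch between a fast diffusive state
(D = 1.0 μm²/s), a slow diffusive state (D = 0.1 μm²/s) and an
immobile state (fractional Brownian motion with Hurst exponent
H = 0.1, scale factor η = 0.3). Switching follows a Markov chain with
stay-probability 0.8 per frame; track lengths are exponential. The
trained network labels every time step of a trajectory of any length.
No deep-learning framework is required — the network (forward pass,
backpropagation through time, Adam) is implemented in NumPy.

**Tracklet characterization.** Maximal same-label runs become
tracklets. For each tracklet the displacement moments

    ⟨|x|^p⟩(τ) = mean over t of ‖x(t+τ) − x(t)‖^p  ∼  τ^γ_p,  p = 1..6

are fitted in log-log space; the slope S_MSS of γ_p versus p is the
moment scaling spectrum slope (0.5 = pure diffusion, < 0.5 restricted,
> 0.5 directed; for fBm, S_MSS ≈ H), and D is taken from the
second-moment fit via the 2D relation ⟨|x|²⟩ = 4Dτ. Tracklets longer
than ten frames with stable fits are placed in S_MSS–D space; cluster
membership is simply the network's class label. Per-class means,
fractions, switching matrices, dwell times and Gaussian-KDE density
maps (Scott's-rule bandwidth n^(−1/(d+4))) summarize each dataset.

## Worked example

`python examples/mss_calibration.py` estimates S_MSS and D on motions
with known ground truth:

```
ballistic line:    S_MSS = 1.000 (expect 1.0)
Brownian D=1.0:    mean S_MSS = 0.488 (expect 0.5), mean D = 1.006 μm²/s
fBm H=0.1 η=0.3:   mean S_MSS = 0.098 (expect ≈0.1)
```

`python examples/train_classifier.py` trains the classifier at reduced
scale (2000/1000/1000 windows of 25 frames, 20 epochs, about a minute
on one CPU):

```
per-step accuracy: train 0.908, val 0.894, test 0.888
```

`python examples/segment_and_analyze.py` runs the whole pipeline on
fresh simulated data and recovers the generating parameters per class:

```
class 0 (fast    ): mean S_MSS 0.458, mean D 1.0028 μm²/s, fraction 0.331
class 1 (slow    ): mean S_MSS 0.429, mean D 0.0960 μm²/s, fraction 0.380
class 2 (immobile): mean S_MSS 0.179, mean D 0.0080 μm²/s, fraction 0.290
```

i.e. the two diffusive classes sit at S_MSS ≈ 0.5 with D ≈ 1.0 and
0.1 μm²/s, and the immobile class at low S_MSS with D another order of
magnitude down. `examples/compare_conditions.py` shows how a changed
switching matrix moves class *fractions* while the class *means* stay
put — the signature of a population redistributing over unchanged
mobility states.

Real data enters as CSV (`track_id, frame, x, y`; pixel units and
foreign column names are converted at the boundary):

```
dlmss train --model-out model.npz
dlmss pipeline --model model.npz --input tracks.csv --out-dir analysis --plots
```

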