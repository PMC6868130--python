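"""Compare mobility summaries of two conditions.

Two simulated populations share identical motion states but different
switching dynamics (the second favors the immobile state, as DNA-damage
induction does for a repair protein).  The per-class fraction shifts
reflect the changed state occupancy while the cluster means stay put.
"""

import numpy as np

from dlmss import FbmParams, compare_conditions, simulate_dataset, summarize_classes, three_state_model
from dlmss.tracklets import estimate_tracklet_mss, split_tracklets
from dlmss.trajsim import SwitchingModel


def summary(model, seed):
    tracks = simulate_dataset(model, FbmParams(), 1000, np.random.default_rng(seed))
    tracklets, seqs = [], []
    for t in tracks:
        tracklets.extend(split_tracklets(t.positions, t.labels, track_id=t.track_id))
        seqs.append(t.labels[:-1])
    estimate_tracklet_mss(tracklets)
    return summarize_classes(tracklets, label_sequences=seqs)


untreated = three_state_model()
# treatment: switching biased toward the immobile state (label 2)
treated = SwitchingModel(
    states=untreated.states,
    Pi=np.array([[0.70, 0.10, 0.20],
                 [0.10, 0.70, 0.20],
                 [0.05, 0.05, 0.90]]),
    lambda_len=untreated.lambda_len, tau=untreated.tau, min_len=untreated.min_len,
)

s_a, s_b = summary(untreated, 0), summary(treated, 1)
for lab, d in sorted(compare_conditions(s_a, s_b).items()):
    print(f"class {lab}: Δfraction {d.delta_fraction:+.3f}, "
          f"ΔS_MSS {d.delta_mean_S_mss:+.3f}, ΔD {d.delta_mean_D:+.4f}")
# The immobile fraction rises at the expense of both diffusive classes,
# while the per-class (S_MSS, D) means barely move — the signature of a
# population redistributing over unchanged mobility states.
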