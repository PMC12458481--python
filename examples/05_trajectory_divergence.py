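"""State-space divergence between cued and self-paced trajectories.

Condition-averaged population activity is projected into a shared 3-PC
basis; the per-sample Euclidean distance between the two trajectories is
compared with a 100-shuffle trial-label null.  A planted pre-press context
bump (−0.5 ± 0.3 s) should push the distance out of the null band inside
that window only, while the grand-average subtraction control stays flat
because the bump is mean-zero across neurons.
"""

import numpy as np

import leverpop as lp
from leverpop.scenarios import exchangeable_session

events, rec, truth = exchangeable_session(seed=21, n_neurons=40,
                                          divergence_amplitude=0.35)
traces = lp.preprocess_session(rec)
tens = lp.build_tensor(traces, events, alignment="press", window=(-2.0, 2.0))

res = lp.trajectory_analysis(tens, n_shuffles=100, seed=0)
nsd = res.null_distances.std(axis=0, ddof=1)
excess = (res.distance - res.null_mean) / nsd
t = res.time

print(f"planted divergence window: {truth.divergence_window} s relative to press")
for t0, t1 in ((-2.0, -0.9), (-0.8, -0.2), (0.0, 2.0)):
    sel = (t >= t0) & (t <= t1)
    print(f"  {t0:+.1f}..{t1:+.1f} s: max excess {excess[sel].max():5.1f} null SD, "
          f"control max {res.mean_diff_control[sel].max():.3f} z")
print("-> the distance excess peaks inside the planted window, where the")
print("   grand-average control stays near zero: the divergence there is a")
print("   population-pattern effect, not a mean-rate effect.  (Post-press,")
print("   frame-discretisation jitter of the steep transient rise inflates")
print("   both curves slightly; averaging replicates removes it.)")
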