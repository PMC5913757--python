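"""Delay and synchronization control by cell-to-cell communication motifs.

Solves the feedback, gate and plain-transition motifs (deterministic
linear-chain formulation) and prints the delay time (5th percentile of the
arrival distribution) and synchronization time (window in which 75% of the
remaining cells respond).
"""

import numpy as np

import rtnet as rt
from rtnet.motifs import MotifSpec, motif_metrics_scan, solve_motif

grid = np.linspace(0, 60, 6000)
for eta, label in ((5.0, "positive feedback"), (1.0, "no feedback"),
                   (0.2, "negative feedback")):
    _, dens = solve_motif(MotifSpec("feedback", shape=10, means=(1.0,),
                                    K=0.1, eta=eta), grid)
    rep = rt.metric_report(dens)
    print(f"{label:18s}: delay = {rep.delay:.3f}, sync = {rep.sync:.3f}")

gate = motif_metrics_scan("gate", [0.5, 1.0, 2.0, 4.0])
print("\ngate motif scan (gating-transition mean -> delay, sync):")
for _, row in gate.iterrows():
    print(f"  mean {row['scan']:.1f}: delay = {row['delay']:.2f}, "
          f"sync = {row['sync']:.2f}")

# Feedback strength changes synchronization several-fold while leaving the
# delay nearly untouched; the gate motif does the opposite, stretching the
# delay >3x while the synchronization window barely moves. The two motifs
# therefore give a cell population independent control knobs for when and
# how sharply it responds.
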