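"""Delay-induced persistence detection.

A cell-state transition proceeds only while a stimulus is present.  With
the measured IL-2 secretion-onset law (gamma, mean 6.3 hr, CV 0.4) the
activated fraction discriminates a 1 hr from a 2 hr stimulus far more
sharply than the mean-matched single-step model; a gate motif scaled to a
3-time-unit delay rejects a 3-unit stimulus yet fully responds to a 5-unit
one.
"""

import numpy as np

import rtnet as rt
from rtnet.persistence import (
    StimulusWindow,
    fold_increase,
    gated_activation_gamma,
    persistence_comparison,
)

il2 = rt.gamma_from_moments(6.3, 0.4)
single = rt.GammaRT(1.0, 1.0 / 6.3)
grid = np.linspace(0, 50, 2000)
for name, law in (("response-time model", il2), ("single-step model", single)):
    short = gated_activation_gamma(law, StimulusWindow(1.0), grid)
    long = gated_activation_gamma(law, StimulusWindow(2.0), grid)
    print(f"{name:19s}: fold increase 1h->2h stimulus = "
          f"{fold_increase(short, long):.2f}")

print()
for motif in ("gate", "transition"):
    tab = persistence_comparison(motif, target_delay=3.0, durations=[3.0, 5.0])
    acts = {row["duration"]: row["max_activation_pct"]
            for _, row in tab.iterrows()}
    print(f"{motif:10s} motif (delay 3): stimulus 3 -> {acts[3.0]}% "
          f"activated, stimulus 5 -> {acts[5.0]}%")

# The delayed, synchronized gamma law turns a 2x longer stimulus into a
# >5x response, while the memoryless single-step law manages less than 2x.
# Among delay-inducing circuits, only the gate motif combines full
# activation for the long stimulus with rejection of the short one.
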