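# rtnet — response-time modeling of cell-to-cell communication networks

Cells do not change state the way single molecules react.  An observable
cell-state change — the onset of cytokine secretion, receptor
upregulation, differentiation — is the output of a multi-step
intracellular network, and the time it takes is a random variable whose
distribution across a population is rarely exponential.  `rtnet` treats
those intracellular networks as black boxes summarized by **response-time
distributions**: an *n*-step uniform irreversible chain with overall rate
λ has the gamma first-passage law

    ψ_n(t) = γ(α, β; t) = t^(α−1) e^(−βt) β^α / Γ(α),   α = n,  β = nλ,

with mean α/β and CV 1/√α, and many realistic intracellular models
(cascades, parallel chains, reversible chains, heterogeneous populations)
remain well approximated by a gamma with an effective, generally
non-integer shape α.

On top of this abstraction the package simulates whole **communication
networks**: populations of cells moving between discrete states with
gamma-distributed waiting times ψ_ij whose parameters may depend on the
fraction of cells in another state S_l,

    ψ_ij(S_l, t−τ) = γ(α_ij(S_l), β_ij(S_l); t−τ),

with feedback couplings β(S_l) = β_base (K + η S_l)/(K + S_l), gate
couplings β(S_l) = β_base S_l/(K + S_l), and branching probabilities
p_ij.  Two solvers are provided: a deterministic linear-chain ODE
formulation (each integer-shape gamma expanded into α exponential
substeps of rate αβ) and a stochastic generalized Gillespie engine that
replaces constant propensities with elapsed-time-dependent hazards
γ_i(τ) = ψ_i(τ)/φ_i(τ) and therefore handles non-integer shapes and
closed-loop couplings.  Arrival-time distributions are scored by three
measures: **delay** (5th percentile), **synchronization time** (window in
which 75% of the remaining cells respond), and **bimodality** (RMS
residual of the best single-gamma fit).

Who it is for: systems biologists and immunologists who want to analyze
or design cytokine-scale signaling circuits from measurable
input-to-output timing data, without a full kinetic model of every
intracellular step.

## Worked example: persistence detection

A transition that only proceeds while a stimulus is present turns a
delayed, synchronized response-time law into a persistence detector.
`examples/persistence_detection.py` compares the measured IL-2
secretion-onset law (gamma, mean 6.3 hr, CV 0.4) with the mean-matched
single-step (exponential) model, then scales two delay-inducing motifs to
a common arrival delay of 3 time units:

```
$ python examples/persistence_detection.py
response-time model: fold increase 1h->2h stimulus = 33.15
single-step model  : fold increase 1h->2h stimulus = 1.85

gate       motif (delay 3): stimulus 3 -> 5.0% activated, stimulus 5 -> 100.0%
transition motif (delay 3): stimulus 3 -> 5.0% activated, stimulus 5 -> 42.0%
```

The gamma law amplifies a 2× longer stimulus into a 33× larger maximal
response where the memoryless exponential manages 1.85×; and among
delay-matched circuits only the gate motif (a transition gated by the
converted fraction of a helper population) reaches 100% activation for
the long stimulus while still rejecting the short one at the
delay-defining 5% level.

The other scripts in `examples/` demonstrate, one capability each:
intracellular first-passage laws and heterogeneity
(`intracellular_response_times.py`), independent control of delay and
synchronization by gate/feedback motifs
(`motif_delay_synchronization.py`), feedforward-loop bimodality
(`feedforward_bimodality.py`), the bimodal IFN-γ secretion-onset case
study (`ifng_onset_models.py`), and the closed-loop Th/Treg IL-2
competition model (`il2_competition.py`).

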