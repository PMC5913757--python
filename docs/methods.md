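# Methods

## Model overview and assumptions

`rtnet` models a population of cells as a semi-Markov process on discrete
cell states.  The waiting time of a transition i→j is a gamma law
γ(α_ij, β_ij; t) whose parameters may depend on the fraction of cells in
a coupling state S_l; branching probabilities p_ij (Σ_j p_ij = 1 per
source state) select among competing transitions.  The framework assumes
a well-stirred population — couplings see only population fractions, not
positions — so spatial gradients of diffusible messengers are outside its
scope.  Each transition's gamma law abstracts a multi-step intracellular
cascade; the gamma arises exactly as the first-passage law of a uniform
irreversible chain and empirically as a good fit for cascades, parallel
chains, reversible chains and heterogeneous single-cell populations.

### Rate convention

A chain of n steps with nominal rate λ uses per-step rate nλ, so that its
mean first-passage time is 1/λ for every n and its law is γ(n, nλ).
Equivalently, in motif specifications each transition is parameterized by
its *mean* m = 1/β, and the linear-chain expansion of γ(α, β) uses α
substeps of rate αβ.  This mean-preserving convention makes models with
different step numbers directly comparable (the single-step comparison
model is the α = 1 member of the same family) and is used consistently in
every module.

## Intracellular models (`rtnet.intracellular`)

Six master-equation motifs: single step, irreversible chain, parallel
irreversible chains (m molecules racing; first-order statistic
f_m = m ψ (1−∫ψ)^{m−1}), reversible chain (per-step backward rate nk,
mirroring the forward convention; the final state is absorbing), kinase
cascade (x_i ∈ [0,1] separately normalized, receptor held active), and a
crosstalk chain with a shortcut reaction from intermediate l to the final
state at rate λ as printed (per-step rate for the shortcut is exposed as
configuration).  Response-time densities are the flux into the absorbing
state, dx_n/dt, computed from the solver-reported derivative (LSODA,
rtol 1e-10, atol 1e-12) and renormalized on the grid; a grid capturing
less than 99.9% of the mass raises.

Cell-to-cell heterogeneity draws each cell's λ once from a log-normal
with σ² = ln(1+CV²), μ = ln(mean) − σ²/2.  Sampling strategies: exact
per-cell closed-form draws for single/irreversible/parallel chains
(distribution-identical to per-cell stochastic simulation), vectorized
Gillespie jump simulation for reversible and crosstalk chains, and a
λ-quantile mixture with inverse-CDF sampling for the cascade, which is a
deterministic per-cell ODE rather than a jump process.

## Stochastic engine (`rtnet.engine`)

The generalized Gillespie scheme replaces constant propensities with
hazards γ_i(τ) = ψ_i(τ)/φ_i(τ) of the elapsed waiting time.  Each step
computes all active hazards, draws the waiting time from
Exp(Σ_k γ_k(t_k)) and the firing channel with probability
γ_i(t_i)/Σ_k γ_k(t_k).  Whenever that frozen-hazard approximation is
invalid an exact step is taken instead: the next-event time solves
θ(τ) = Π_k φ_k(t_k+τ)/φ_k(t_k) = u (adaptive doubling bracket from 1% of
the fastest mean, then Brent to rtol 1e-8) and the channel is drawn with
weights γ_i(t_i+τ).  Exact stepping triggers (a) when every active hazard
is zero — in particular at t = 0, where gamma laws with α > 1 have zero
hazard — and (b) when the expected approximate wait 1/Σγ_k exceeds 10% of
the fastest active law's mean.  Guard (b) matters during the low-hazard
ramp-up: hazards grow steeply through every law's left tail, and a frozen
hazard there overshoots the next event by multiples of the law's mean,
avalanching the whole population; the guard depends only on the current
state, so it introduces no rejection bias.  Validation: a single
γ(10,10) transition at 5000 cells reproduces the analytic arrival CDF to
KS < 0.01, and all coupled motifs match their deterministic linear-chain
solutions within Monte-Carlo error.

### Couplings and time-varying parameters

Couplings re-evaluate after every event; fractions change only at events,
so hazards are piecewise-constant between events and the average-rate
step is well-posed.  When a coupling changes a transition's rate
mid-wait, the cell's accumulated waiting is carried as the integrated
intensity x = ∫ rate(t) dt since state entry, and the hazard is
rate·h(x; α, 1) with h the unit-rate gamma hazard.  This is exactly the
first-passage law of a linear chain whose substep rates are modulated in
time (the number of completed substeps is an inhomogeneous Poisson
count), reduces to the ordinary gamma hazard for constant rate, and
freezes progress while a gate coupling holds the rate at zero.  The naive
alternative — re-evaluating the whole elapsed time under the new law —
makes a 5× rate increase instantly re-interpret a cell's wait as far past
the fast law's mean and fires the entire population at once, in gross
disagreement with the ODE formulation; a progress-reset mode
(`coupling_clock_reset`) is retained for comparison.  If a coupled law's
shape changes between events (IL-2 competition), the accumulated standard
progress is kept under the new shape.

A `Coupling.pool_fraction` renormalizes the coupled state's raw
population fraction to a subpopulation, so two-population motifs (gate:
helper pool + target pool, each a unit population in the ODE form) mean
the same thing in both solvers.

### Branching and RNG stream

A cell entering a state draws its branch (target transition) immediately
per p_ij and commits to that transition's law; this is the semi-Markov
kernel Q_ij(t) = p_ij ψ_ij(t).  With branch-specific laws the waiting
time depends on the branch, so commitment must precede the time draw.
One seeded `numpy` generator drives everything; per event the stream
order is: waiting-time draw, channel draw, then any branch draws at state
entry.  Identical seed and configuration give byte-identical event logs.

## Linear-chain motifs (`rtnet.motifs`)

Integer-shape motifs (transition, double transition, feedback, gate,
feedforward) expand into ODE systems and are solved deterministically
(LSODA, rtol 1e-10).  Couplings read the aggregate macro-state fraction —
chain substructure is invisible to them.  Non-integer shapes are refused
here and routed to the stochastic engine, mirroring where each
formulation is exact.

Feedforward peak analysis (exponential steps, competing rates a, b, c):
the eigen-solution S_2(t) = k1 e^{−(a+c)t} + k2 e^{−bt} + 1 with
k1 = (b−c)/(a−b+c), k2 = −a/(a−b+c) makes the arrival density a
two-exponential sum whose derivative has at most one zero — never two
peaks.  In the degenerate case b = a+c the density is
e^{−(a+c)t}(c + a(a+c)t) with an interior maximum at
t* = (a−c)/(a(a+c)), existing only for a > c (for a = 2c this equals
c/(a(a+c))).  Peak counting on numeric curves uses strict local maxima
with a relative prominence floor of 1e-3 of the curve maximum to suppress
solver ripple.

The multi-step feedforward motif is parameterized by the *route*
timescale separation: the indirect route's total mean (split evenly over
its two legs) relative to the direct route's mean.  Separation 1 makes
the two routes' arrival peaks coincide (single peak); separation 5 with
shape 10 produces clear bimodality.  With per-leg means fixed at the
direct mean instead, the indirect peak sits at twice the direct peak and
the two remain formally distinct even at "equal velocities", which is why
the route-level parameterization is the one exposed.

## Measures (`rtnet.metrics`)

Delay: the 5% quantile of the cumulative arrival curve (monotone
interpolation; empirical curves integrated by the trapezoid rule).
Synchronization: the minimal τ with
[F(t_delay+τ) − F(t_delay)]/[1 − F(t_delay)] ≥ d, default d = 0.75 (the
future-lifetime expression is parenthesized in the standard
residual-lifetime form, the only reading that is a probability).
Bimodality: the RMS residual of a nonlinear-least-squares single-gamma
fit to the density curve.  Fitting is density least squares (moment-based
start, parameters bounded below at 1e-6, tolerances 1e-14), chosen over
maximum likelihood because the residual itself is the bimodality
statistic; this is a convention, and CDF-based or likelihood fits would
order the same comparisons.

## Persistence detection (`rtnet.persistence`)

Stimulus-gated activation: A(t) = F(min(t, t_d)) for a response-time law
with CDF F and an on/off stimulus of duration t_d ("maximal activity" is
the plateau value; activation is frozen whenever the stimulus is off).
The motif comparison scales only the slow (gating) transition's mean,
holding the downstream transition at mean 1, by bisection until the
arrival delay equals the target (tolerance 1e-4 time units).  The delay
is measured on the best-fit gamma summarizing the motif — the
response-time abstraction the gated model actually uses — so a stimulus
exactly as long as the delay activates exactly 5% by construction; the
raw solved arrival curve differs by fit bias (≈6% instead of 5% for the
gate motif) and is available via `delay_of="curve"`.  Activated
percentages are reported rounded to the nearest integer.

## IFN-γ onset case study (`rtnet.cytokine_onset`)

Differentiation paths are encoded as initial pools (IL-2+, direct IFN-γ+,
indirect IFN-γ+; defaults 0.25/0.40/0.35, the remainder inert), making
branch fractions independent of the response-time laws.  Model 1's
indirect path uses the early IFN-γ law with its rate gated by the IL-2+
fraction; model 2 inserts a CD25-upregulation gamma step before it.  The
gate argument is the IL-2+ fraction normalized to its pool (a fully
converted IL-2 pool saturates the interaction), and the interaction
strength maps to the gate's half-saturation K (default 0.1; results are
insensitive over at least 0.03–0.3).  Degradation of secreting pools
defaults to 0 with a configuration hook.  Simulations use the stochastic
engine (the laws have non-integer shapes) with 5000 cells; pooled arrival
distributions are normalized per branch (a cell on an IFN-γ-bound path
arrives with certainty).

Input laws: IL-2 onset directly from its summary moments (mean 6.3 hr,
CV 0.4 → α = 6.25, β ≈ 0.992/hr).  The early IFN-γ law and the CD25 law
come from the synthetic-fixture generator: a two-gamma mixture (means
6.3/13.8 hr, CVs 0.30/0.25, weights 0.55/0.45; overall mean ≈ 9.6 hr,
inter-peak dip near 10 hr) is cut at its dip and renormalized, then
gamma-fitted — the cut-and-renormalize procedure biases the recovered
early mean upward by ~6% because some late-component mass lies below the
dip; and a normalized cumulative upregulation curve (gamma, mean 7.5 hr,
CV 0.4) is fitted by a gamma CDF.  The CD25 mean is a package default
chosen so the CD25 step dominates the indirect path's delay, placing the
late arrival wave clearly after the early one; it is a modeling default,
not a measured value.

## IL-2 competition case study (`rtnet.il2_competition`)

Receptor ODE (R surface receptors, C complexes, E internalized
complexes; complex-induced synthesis v(C) = v0 + v1 C³/(K³+C³)) solved at
fixed IL-2 with the printed constants (k_on = 112 /nM/h, k_iR = 0.64/h,
k_off = 0.83/h, k_rec = 9/h, k_iC = 1.7/h, k_deg = 5/h, K = 1000
molecules/cell; Th v0/v1 = 150/3000, Treg 1000/8000 molecules/cell/h),
starting from the IL-2-free steady state R = v0/k_iR.  The complex curve
after a 1 hr burn-in, baseline-subtracted and normalized to its final
value, is identified with the cumulative activation response-time law and
fitted by a gamma CDF.  Across a logarithmic grid of 8 concentrations
(0.005–50 nM) the fitted (α, β) are compressed into the interpolating
forms α(c) = C_α + (K_α/c)^n and β(c) = V_β c/(K_β + c).  Note the raw
fits are not monotone in c with these constants — the complex-induced
synthesis switch only fires above a threshold concentration — so the
monotone interpolator forms smooth over them; the interpolated α is
capped at 1000 as c → 0, where β → 0 blocks the transition anyway.

Extracellular balance:
[IL-2] = qσf_Th / (k_on(R_Th σf_Th A_Th + R_Treg σf_Treg A_Treg) + 4πDρ/Vol),
production over consumption by receptors on active cells plus diffusive
escape.  Units: receptor terms convert molecules/cell × cells/µl to nM
via ×10¹⁵/N_A; the escape term 4πDρ (µm³/s, D = 10 µm²/s, ρ = 5 µm)
converts to 1/h via ×3600/Vol(µm³), giving 2.26×10⁻³/h for Vol = 1 µl.
The secretion rate q (default 1000 molecules/cell/h) and cell density σ
(default 2000 cells/µl) are configuration values chosen to put the
zero-activation concentration near 0.7 nM, inside the interpolator grid;
they are package defaults, not published constants.  The closed-loop
simulation (2000 cells, Th and Treg combined) re-evaluates the balance
after every activation event and updates both cell types' (α, β) through
the interpolators; a milieu with q = 0 blocks every transition and ends
as a no-activation run rather than an error.

## Synthetic fixtures (`rtnet.synth`) — what they do and do not emulate

The generator produces (i) seeded gamma onset-time samples from summary
moments, (ii) two-gamma bimodal mixtures with a controllable inter-peak
dip, and (iii) noiseless normalized cumulative upregulation curves — each
with its ground-truth parameters stored alongside, enabling
parameter-recovery tests.  They emulate the *shape* features of measured
onset-time data (single-peaked gamma-like distributions, a bimodal
mixture with a dip, saturating upregulation) but not measurement noise,
finite flow-cytometry gating effects, censoring, or day-to-day batch
variation; passing tests therefore demonstrate correctness of the
inference and simulation machinery under the stated generative
assumptions, not robustness to real assay artifacts.

## Numerical choices and problem sizes

ODE solves: LSODA, rtol 1e-10/atol 1e-12 (receptor model 1e-8/1e-10).
Empirical densities live on uniform grids, default extent mean + 8 SD;
oracle comparisons at 1e-6 sup-norm use longer, finer grids so tail
truncation and trapezoid renormalization stay below the comparison scale.
Simulation sizes follow the study conditions: 20000 cells for
heterogeneous intracellular sampling, 5000 for the IFN-γ models, 2000 for
the competition model; engine-vs-ODE agreement tests use 3000–4000 cells
with quantile-time comparisons (robust to steep avalanche fronts where
pointwise CDF differences conflate tiny horizontal offsets with large
vertical ones).

## Known limitations

No spatial structure; couplings act through population fractions only
(per-cell/intracellular feedback is not implemented — intercellular
coupling is the stronger effect and the one the engine's average-rate
scheme is built for).  The linear-chain solver requires integer shapes.
Only gamma, exponential and empirical waiting-time laws are supported
(normal and multi-exponential onset summaries are documented but not
modeled); fitting is uncensored density least squares.  The engine's
average-rate step is an O(1/N) approximation — accurate for thousands of
cells, exact stepping is available (`force_exact`) but quadratic-cost in
practice.
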