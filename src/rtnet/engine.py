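"""Semi-Markov population simulation of cell-to-cell communication networks.

Cells occupy discrete states and change state after gamma-distributed
waiting times; couplings make a transition's gamma parameters depend on the
current fraction of the population in some other state, and branching
probabilities p_ij select among competing transitions out of a state.

The stochastic engine is a generalized Gillespie algorithm: the constant
propensities of the classic algorithm are replaced by hazard rates
gamma_i(tau) = psi_i(tau)/phi_i(tau), where tau is the time a cell has
already spent waiting, psi is the waiting-time density and phi its
survival.  At each step an average rate over the N active processes,
gammabar = N^-1 sum_k gamma_k(t_k), drives an exponential time draw
(N*gammabar * exp(-N*gammabar*tau)), and the firing channel is selected
with probability gamma_i(t_i)/(N*gammabar).  This approximation is valid
for large cell numbers; whenever no active process has a positive hazard
(in particular at the start, where every clock is 0 and gamma laws with
shape > 1 have hazard 0), an exact step is taken instead: the next-event
time solves

    theta(tau | {t_k}) = prod_k phi_k(t_k + tau) / phi_k(t_k) = u

for a uniform random u, and the channel is drawn with weights
gamma_i(t_i + tau) / sum_k gamma_k(t_k + tau).

Couplings are re-evaluated after every event; population fractions change
only at events, so hazards are piecewise-constant in the fractions between
events.  Per-cell clocks reset on state entry.  When a coupling changes a
transition's rate mid-wait, the cell's accumulated waiting is carried as
the integrated intensity x = int rate(t) dt since state entry, and the
hazard is rate * h(x; shape, 1) — the time-inhomogeneous gamma law that is
exactly the first-passage distribution of a linear chain with modulated
substep rates.  For a constant rate this is the ordinary gamma hazard at
x = rate * tau; a progress-reset mode is available for comparison but off
by default.

RNG stream order: the branch (target transition) of a cell is drawn when
the cell enters a state; each simulation step then draws the waiting time
and the firing channel.  One seeded generator drives the whole simulation,
so identical seed + configuration gives identical event logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .distributions import EmpiricalRT, GammaRT

__all__ = [
    "CellState",
    "Coupling",
    "TransitionSpec",
    "CommunicationNetwork",
    "PopulationTrajectory",
    "DeadlockError",
    "coupling_feedback",
    "coupling_gate",
    "simulate",
    "exact_step",
    "arrival_distribution",
]

_HAZARD_CAP = 1e12


class DeadlockError(RuntimeError):
    """All active processes have permanently zero hazard."""


def coupling_feedback(frac: float, beta_base: float, K: float, eta: float) -> float:
    """Feedback rate law beta(S_l) = beta_base * (K + eta*S_l) / (K + S_l).

    eta > 1: positive feedback (rate grows with the coupled fraction);
    eta < 1: negative feedback; eta = 1: neutral (constant beta_base).
    """
    frac = np.asarray(frac, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("fraction must lie in [0, 1]")
    if beta_base <= 0 or K <= 0 or eta <= 0:
        raise ValueError("beta_base, K and eta must be positive")
    return beta_base * (K + eta * frac) / (K + frac)


def coupling_gate(frac: float, beta_base: float, K: float) -> float:
    """Gate (positive-interaction) rate law beta(S_l) = beta_base*S_l/(K+S_l).

    Zero at S_l = 0 (transition blocked until the coupled state is
    populated), half-saturated at S_l = K, saturating toward beta_base.
    """
    frac = np.asarray(frac, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("fraction must lie in [0, 1]")
    if beta_base <= 0 or K <= 0:
        raise ValueError("beta_base and K must be positive")
    return beta_base * frac / (K + frac)


@dataclass(frozen=True)
class CellState:
    name: str
    is_absorbing: bool = False


@dataclass(frozen=True)
class Coupling:
    """Dependence of a transition's rate on a coupled state's fraction.

    ``pool_fraction`` renormalizes the coupled state's population fraction
    to a subpopulation: with a helper pool occupying half the cells, the
    fully-converted helper state reaches a raw fraction of 0.5, and
    pool_fraction = 0.5 maps that to a coupling argument of 1 (matching
    the two-population motif formulation where each pool is a unit
    population).
    """

    state: str
    function: Literal["feedback", "gate"]
    K: float
    eta: float = 1.0
    beta_base: float | None = None  # default: the transition law's rate
    pool_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.function not in ("feedback", "gate"):
            raise ValueError(f"unknown coupling function {self.function!r}")
        if not (0.0 < self.pool_fraction <= 1.0):
            raise ValueError("pool_fraction must lie in (0, 1]")

    def rate(self, frac: float, base: float) -> float:
        frac = min(frac / self.pool_fraction, 1.0)
        beta0 = self.beta_base if self.beta_base is not None else base
        if self.function == "feedback":
            return float(coupling_feedback(frac, beta0, self.K, self.eta))
        return float(coupling_gate(frac, beta0, self.K))


@dataclass
class TransitionSpec:
    """One cell-state transition with its waiting-time law.

    ``law`` is the base gamma law; ``coupling`` (optional) modulates its
    rate by the fraction of cells in another state; ``law_fn`` (optional)
    overrides both with an arbitrary map from the population-fraction dict
    to (shape, rate) — used for response-time laws driven by a computed
    milieu quantity.  A (shape, rate) with rate <= 0 means the transition
    is currently blocked (hazard 0).
    """

    source: str
    target: str
    law: GammaRT | None = None
    coupling: Coupling | None = None
    branch_prob: float = 1.0
    law_fn: Callable[[dict[str, float]], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.law is None and self.law_fn is None:
            raise ValueError(f"transition {self.source}->{self.target} needs a law")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must lie in [0, 1]")

    def params(self, fractions: dict[str, float]) -> tuple[float, float]:
        """Current (shape, rate) given population fractions."""
        if self.law_fn is not None:
            return self.law_fn(fractions)
        shape, rate = self.law.shape, self.law.rate
        if self.coupling is not None:
            rate = self.coupling.rate(fractions[self.coupling.state], rate)
        return shape, rate


@dataclass
class CommunicationNetwork:
    """Validated network of cell states and gamma-governed transitions."""

    states: Sequence[CellState]
    transitions: Sequence[TransitionSpec]
    initial: dict[str, float]

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError("state names must be unique")
        self._index = {n: i for i, n in enumerate(names)}
        absorbing = {s.name for s in self.states if s.is_absorbing}
        by_source: dict[str, list[TransitionSpec]] = {}
        for tr in self.transitions:
            for endpoint in (tr.source, tr.target):
                if endpoint not in self._index:
                    raise ValueError(f"transition references unknown state {endpoint!r}")
            if tr.source in absorbing:
                raise ValueError(f"absorbing state {tr.source!r} has an outgoing transition")
            if tr.coupling is not None and tr.coupling.state not in self._index:
                raise ValueError(f"coupling references unknown state {tr.coupling.state!r}")
            by_source.setdefault(tr.source, []).append(tr)
        for src, trs in by_source.items():
            total = sum(t.branch_prob for t in trs)
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(
                    f"branch probabilities out of state {src!r} sum to {total:g}, not 1"
                )
        bad_init = set(self.initial) - set(names)
        if bad_init:
            raise ValueError(f"initial occupancy references unknown states {sorted(bad_init)}")
        if not np.isclose(sum(self.initial.values()), 1.0, atol=1e-9):
            raise ValueError("initial occupancy fractions must sum to 1")
        self._out = {src: trs for src, trs in by_source.items()}

    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    def outgoing(self, state: str) -> list[TransitionSpec]:
        return self._out.get(state, [])


@dataclass
class PopulationTrajectory:
    """Event log and derived occupancy curves of one simulation."""

    events: pd.DataFrame  # columns: cell, time, source, target
    n_cells: int
    seed: int
    state_names: list[str]
    initial_states: np.ndarray  # state name per cell at t = 0
    t_end: float

    def first_arrival_times(self, state: str) -> np.ndarray:
        """Sorted first-arrival times of cells into ``state``."""
        ev = self.events
        hits = ev[ev["target"] == state].drop_duplicates("cell", keep="first")
        return np.sort(hits["time"].to_numpy())

    def occupancy(self, t_grid: np.ndarray) -> pd.DataFrame:
        """Fraction of cells in each state at each grid time."""
        t_grid = np.asarray(t_grid, dtype=float)
        counts = {name: np.zeros(t_grid.size) for name in self.state_names}
        init_counts = pd.Series(self.initial_states).value_counts()
        for name in self.state_names:
            counts[name] += init_counts.get(name, 0)
        # apply events as +/- step functions via searchsorted
        ev = self.events.sort_values("time")
        for name in self.state_names:
            t_in = ev.loc[ev["target"] == name, "time"].to_numpy()
            t_out = ev.loc[ev["source"] == name, "time"].to_numpy()
            counts[name] += np.searchsorted(t_in, t_grid, side="right")
            counts[name] -= np.searchsorted(t_out, t_grid, side="right")
        return pd.DataFrame(counts, index=t_grid) / self.n_cells

    def events_to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# core stepping
# ---------------------------------------------------------------------------

def _gamma_logsf(x: np.ndarray, shape) -> np.ndarray:
    """log of the regularized upper incomplete gamma (gamma survival)."""
    with np.errstate(divide="ignore"):
        return np.log(special.gammaincc(shape, x))


def _hazards_std(shape, rate, x) -> np.ndarray:
    """Gamma hazards rate * psi_std(x)/phi_std(x) at standardized elapsed
    progress x (integrated rate since state entry); hot path, vectorized
    via scipy.special.  Reduces to the ordinary gamma(shape, rate) hazard
    at x = rate * tau for constant rate."""
    x = np.asarray(x, dtype=float)
    rate_arr = np.broadcast_to(np.asarray(rate, dtype=float), x.shape)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        log_h_std = (special.xlogy(np.asarray(shape) - 1.0, x) - x
                     - special.gammaln(shape) - _gamma_logsf(x, shape))
        h = rate_arr * np.exp(log_h_std)
    h = np.where(rate_arr > 0, h, 0.0)
    h = np.where(np.isfinite(h), h, _HAZARD_CAP)
    return np.minimum(h, _HAZARD_CAP)


def exact_step(clocks: np.ndarray, laws: Sequence[tuple[float, float]],
               rng: np.random.Generator, t_max: float = np.inf,
               initial_h: float | None = None,
               standardized: bool = False) -> tuple[float, int]:
    """Exact semi-Markov step: next waiting time and firing channel.

    Solves theta(tau | {t_k}) = prod_k phi_k(t_k + tau)/phi_k(t_k) = u for
    a uniform u by adaptive bracketing (initial step doubled until the root
    is enclosed) followed by Brent root-finding to relative tolerance 1e-8,
    then draws the channel with weights gamma_i(t_i + tau).

    ``laws`` is one (shape, rate) pair per active process; rate <= 0 marks
    a blocked process (survival identically 1).  ``clocks`` are elapsed
    waiting times; with ``standardized=True`` they are instead the
    integrated-rate progress variables x_k = int rate dt used by the
    simulation loop under time-varying couplings (identical for constant
    rates, where x = rate * tau).  Raises :class:`DeadlockError` if every
    process is blocked, and RuntimeError if the root lies beyond ``t_max``.
    """
    clocks = np.asarray(clocks, dtype=float)
    shapes = np.array([l[0] for l in laws])
    rates = np.array([l[1] for l in laws])
    live = rates > 0
    if not live.any():
        raise DeadlockError("all active processes are blocked (zero hazard forever)")

    a = shapes[live]
    rt = rates[live]
    x0 = clocks[live] if standardized else rt * clocks[live]
    base = _gamma_logsf(x0, a)

    u = rng.uniform()
    log_u = np.log(u)

    def g(tau: float) -> float:
        return float(np.sum(_gamma_logsf(x0 + rt * tau, a) - base)) - log_u

    # adaptive bracketing: start near 1% of the fastest mean waiting time
    if initial_h is None:
        initial_h = 0.01 * float(np.min(a / rt))
    h = initial_h
    lo = 0.0
    while g(h) > 0:
        lo = h
        h *= 2.0
        if h > 100 * max(t_max, 1.0) and t_max != np.inf:
            raise RuntimeError("exact step: no event before the simulation horizon")
        if h > 1e12:
            raise DeadlockError("exact step: survival does not decay")
    tau = optimize.brentq(g, lo, h, rtol=1e-8)

    weights = np.zeros(len(laws))
    weights[live] = _hazards_std(a, rt, x0 + rt * tau)
    total = weights.sum()
    if total <= 0:
        # degenerate: hazard numerically zero at the root; pick among live
        weights[live] = 1.0
        total = weights.sum()
    channel = int(np.searchsorted(np.cumsum(weights) / total, rng.uniform()))
    return float(tau), channel


def simulate(network: CommunicationNetwork, n_cells: int, t_max: float,
             seed: int, force_exact: bool = False,
             coupling_clock_reset: bool = False,
             on_deadlock: str = "raise") -> PopulationTrajectory:
    """Simulate a population of ``n_cells`` cells through the network.

    Cells are allocated to initial states by largest-remainder rounding of
    the initial occupancy fractions.  Returns the full event log plus
    bookkeeping; see the module docstring for the algorithm.

    Under couplings each cell carries an integrated-rate progress variable
    x = int rate(t) dt since state entry; its waiting-time law is the
    unit-rate gamma in x (exactly the first-passage law of a linear chain
    whose substep rates are modulated in time), so for constant rates the
    ordinary gamma law is recovered and a blocked transition (rate 0)
    simply freezes.

    ``force_exact`` uses the exact step everywhere (validation mode);
    ``coupling_clock_reset`` zeroes a cell's accumulated progress whenever
    its transition's parameters change (off by default: progress is
    retained).  ``on_deadlock`` chooses between raising a
    :class:`DeadlockError` naming the blocked states when every active
    hazard is permanently zero (default) and ``"stop"``, which ends the
    simulation there (for models where a fully blocked population is a
    legitimate outcome, e.g. no stimulus at all).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    if on_deadlock not in ("raise", "stop"):
        raise ValueError("on_deadlock must be 'raise' or 'stop'")
    rng = np.random.default_rng(seed)
    state_names = network.state_names
    idx_of = {n: i for i, n in enumerate(state_names)}

    # deterministic initial allocation (largest remainder)
    targets = np.array([network.initial.get(n, 0.0) for n in state_names])
    raw = targets * n_cells
    counts = np.floor(raw).astype(int)
    remainder = n_cells - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1
    cell_state = np.repeat(np.arange(len(state_names)), counts)
    initial_states = np.array([state_names[i] for i in cell_state])

    transitions = list(network.transitions)
    tr_index = {id(tr): i for i, tr in enumerate(transitions)}

    # per-cell commitment: index into `transitions`, or -1 if none
    committed = np.full(n_cells, -1, dtype=np.int64)
    progress = np.zeros(n_cells)  # integrated rate since state entry
    state_counts = np.bincount(cell_state, minlength=len(state_names)).astype(float)

    def draw_branch(state_idx: int) -> int:
        outs = network.outgoing(state_names[state_idx])
        if not outs:
            return -1
        if len(outs) == 1:
            return tr_index[id(outs[0])]
        probs = np.array([t.branch_prob for t in outs])
        j = int(np.searchsorted(np.cumsum(probs), rng.uniform()))
        j = min(j, len(outs) - 1)
        return tr_index[id(outs[j])]

    for c in range(n_cells):
        committed[c] = draw_branch(cell_state[c])

    events_cell: list[int] = []
    events_time: list[float] = []
    events_src: list[str] = []
    events_tgt: list[str] = []

    t = 0.0
    prev_params = [None] * len(transitions)
    while True:
        active = np.flatnonzero(committed >= 0)
        if active.size == 0 or t >= t_max:
            break
        fractions = {n: state_counts[i] / n_cells for i, n in enumerate(state_names)}

        # current law parameters per transition; optional progress reset
        params = [None] * len(transitions)
        kinds = np.unique(committed[active])
        for k in kinds:
            params[k] = transitions[k].params(fractions)
            if (coupling_clock_reset and prev_params[k] is not None
                    and params[k] != prev_params[k]):
                progress[committed == k] = 0.0
        prev_params = params

        x_act = progress[active]
        haz = np.zeros(active.size)
        rate_act = np.zeros(active.size)
        groups: dict[int, np.ndarray] = {}
        for k in kinds:
            mask = committed[active] == k
            groups[k] = mask
            shape_k, rate_k = params[k]
            rate_act[mask] = max(rate_k, 0.0)
            if rate_k > 0:
                haz[mask] = _hazards_std(shape_k, rate_k, x_act[mask])
        total = haz.sum()

        # the average-rate step freezes hazards at their current values; in
        # the low-hazard ramp-up (left tail of every law) the expected wait
        # then grossly overshoots the true next-event time.  Trust the
        # approximation only when the expected wait is short against the
        # fastest law's mean; otherwise take an exact step.
        live_means = [params[k][0] / params[k][1] for k in kinds
                      if params[k][1] > 0]
        freshness = 0.1 * min(live_means) if live_means else 0.0

        if total > 0 and total * freshness >= 1.0 and not force_exact:
            # average-rate approximate step
            tau = rng.exponential(1.0 / total)
            pick = int(np.searchsorted(np.cumsum(haz) / total, rng.uniform()))
            pick = min(pick, active.size - 1)
        else:
            laws = [None] * active.size
            for k, mask in groups.items():
                for j in np.flatnonzero(mask):
                    laws[j] = params[k]
            try:
                tau, pick = exact_step(x_act, laws, rng, t_max=t_max - t,
                                       standardized=True)
            except RuntimeError as exc:
                if isinstance(exc, DeadlockError):
                    if on_deadlock == "stop":
                        break
                    blocked = sorted({state_names[cell_state[c]] for c in active})
                    raise DeadlockError(
                        f"simulation deadlocked: all hazards zero in states {blocked}"
                    ) from exc
                break  # no event before horizon: stop at t_max

        t += tau
        if t > t_max:
            break
        progress[active] += rate_act * tau  # rates constant within the step
        cell = int(active[pick])
        k = committed[cell]
        tr = transitions[k]
        src_idx, tgt_idx = idx_of[tr.source], idx_of[tr.target]
        events_cell.append(cell)
        events_time.append(t)
        events_src.append(tr.source)
        events_tgt.append(tr.target)
        state_counts[src_idx] -= 1
        state_counts[tgt_idx] += 1
        cell_state[cell] = tgt_idx
        progress[cell] = 0.0
        committed[cell] = draw_branch(tgt_idx)

    events = pd.DataFrame({
        "cell": np.array(events_cell, dtype=np.int64),
        "time": np.array(events_time, dtype=float),
        "source": events_src,
        "target": events_tgt,
    })
    return PopulationTrajectory(events=events, n_cells=n_cells, seed=seed,
                                state_names=state_names,
                                initial_states=initial_states, t_end=min(t, t_max))


def arrival_distribution(traj: PopulationTrajectory, state: str,
                         normalize_mode: str = "full",
                         bins: int | np.ndarray = 60
                         ) -> tuple[EmpiricalRT, float]:
    """Histogram density of first-arrival times into ``state``.

    normalize_mode:
      - ``"full"``: density integrates to 1 (conditional on arrival);
      - ``"none"`` / ``"per_branch"``: density integrates to the reached
        fraction of the whole population.  Under branching, cells that
        arrive via a branch do so with the branch's pool fraction, so the
        per-branch convention (each path's arrivals scaled to its fraction
        of cells) coincides with the raw reached-fraction scaling.

    Returns the density and the reached fraction.  Raises if no cell
    arrived.
    """
    times = traj.first_arrival_times(state)
    if times.size == 0:
        raise ValueError(f"no cell arrived in state {state!r}")
    reached = times.size / traj.n_cells
    hist, edges = np.histogram(times, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if normalize_mode == "full":
        emp = EmpiricalRT(centers, hist, is_normalized=False).normalized()
    elif normalize_mode in ("none", "per_branch"):
        emp = EmpiricalRT(centers, hist * reached, is_normalized=False)
    else:
        raise ValueError(f"unknown normalize_mode {normalize_mode!r}")
    return emp, reached
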