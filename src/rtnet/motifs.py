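"""Deterministic linear-chain formulation of communication network motifs.

A gamma-distributed cell-state transition with integer shape ``alpha`` and
nominal rate ``beta`` (mean 1/beta) is exactly equivalent to ``alpha``
sequential exponential substeps of rate ``alpha*beta`` (the linear chain
trick).  This turns each motif into a system of ordinary differential
equations for population fractions, solved deterministically; couplings
(feedback, gate) enter as substep rates that depend on the aggregate
fraction of cells in the coupled macro-state — the chain substructure is
invisible to couplings.

Motifs (one or two unit populations of cells):

- ``transition``:        S0 --gamma--> Sa
- ``double_transition``: S0 --gamma--> S1 --gamma--> Sa
- ``feedback``:          S0 --gamma--> Sa with beta(S_a) = beta*(K+eta*Sa)/(K+Sa)
- ``gate``:              helper A0 --gamma--> A1; target B0 --gamma--> Ba
                         with beta(A1) = beta * A1/(K+A1)
- ``feedforward``:       S0 splits (p01/p02) into a direct route S0->Sa and
                         an indirect route S0->S1->Sa; with multi-step
                         kinetics and timescale separation between routes
                         the arrival density becomes bimodal.

Non-integer shapes are outside this module's scope (use the stochastic
engine); the split mirrors where each formulation is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .distributions import EmpiricalRT
from .engine import coupling_feedback, coupling_gate

__all__ = [
    "MotifSpec",
    "MasterMatrix",
    "expand_motif",
    "solve_motif",
    "feedforward_peak_count",
    "feedforward_numeric_peak_count",
    "feedforward_degenerate_peak_time",
    "feedforward_motif_rt",
    "count_peaks",
    "motif_metrics_scan",
]

MOTIFS = ("transition", "double_transition", "feedback", "gate", "feedforward")

#: relative prominence floor for peak counting, suppressing solver ripple
_PEAK_PROMINENCE = 1e-3


@dataclass(frozen=True)
class MotifSpec:
    """Parameterization of one motif.

    ``shape``: integer gamma shape used for every transition (shape 1 is
    the single-step / exponential comparison model).
    ``means``: average time of each transition in motif order (see module
    docstring); the nominal rate of transition i is 1/means[i].
    ``K``, ``eta``: coupling parameters (gate / feedback).
    ``branch_probs``: (p01, p02) for the feedforward split, summing to 1.
    """

    motif: str
    shape: int = 10
    means: tuple[float, ...] = (1.0,)
    K: float = 0.1
    eta: float = 1.0
    branch_probs: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}")
        if self.shape < 1 or int(self.shape) != self.shape:
            raise ValueError(
                "linear-chain motifs need integer shape >= 1; use the "
                "stochastic engine for non-integer shapes"
            )
        n_means = {"transition": 1, "feedback": 1, "double_transition": 2,
                   "gate": 2, "feedforward": 3}[self.motif]
        if len(self.means) != n_means:
            raise ValueError(f"{self.motif} motif needs {n_means} transition means")
        if any(m <= 0 for m in self.means):
            raise ValueError("transition means must be positive")
        if not np.isclose(sum(self.branch_probs), 1.0):
            raise ValueError("branch probabilities must sum to 1")


@dataclass
class MasterMatrix:
    """Constant-rate master-equation matrix dS/dt = W S (probability-
    conserving: columns sum to zero, off-diagonals nonnegative)."""

    W: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        off = W - np.diag(np.diag(W))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal entries must be nonnegative")
        if not np.allclose(W.sum(axis=0), 0.0, atol=1e-9):
            raise ValueError("columns must sum to zero (probability conservation)")
        self.W = W


@dataclass
class ExpandedMotif:
    """Linear-chain ODE system for one motif."""

    spec: MotifSpec
    y0: np.ndarray
    rhs: callable
    arrival_flux: callable        # y -> d(arrival state)/dt
    macro_fractions: callable     # y -> dict of macro-state fractions
    arrival_label: str


def _chain_flux(y, start, alpha, rate):
    """Flux out of the last substep of a chain stored at y[start:start+alpha]."""
    return rate * y[start + alpha - 1]


def expand_motif(spec: MotifSpec) -> ExpandedMotif:
    """Expand each gamma transition into ``shape`` substeps of rate shape*beta.

    The expansion preserves the transition mean (1/beta) for every shape.
    Couplings read the aggregate macro-state fraction; with eta = 1 the
    feedback motif reduces exactly to the plain transition motif.
    """
    a = spec.shape
    if spec.motif in ("transition", "feedback"):
        beta0 = 1.0 / spec.means[0]

        def beta(y):
            if spec.motif == "transition":
                return beta0
            return float(coupling_feedback(min(max(y[a], 0.0), 1.0), beta0,
                                           spec.K, spec.eta))

        def rhs(t, y):
            r = a * beta(y)
            dy = np.empty_like(y)
            dy[0] = -r * y[0]
            for i in range(1, a):
                dy[i] = r * (y[i - 1] - y[i])
            dy[a] = r * y[a - 1]
            return dy

        y0 = np.zeros(a + 1)
        y0[0] = 1.0
        return ExpandedMotif(
            spec=spec, y0=y0, rhs=rhs,
            arrival_flux=lambda y: a * beta(y) * y[a - 1],
            macro_fractions=lambda y: {"S0": float(np.sum(y[:a])), "Sa": float(y[a])},
            arrival_label="Sa",
        )

    if spec.motif == "double_transition":
        b1, b2 = 1.0 / spec.means[0], 1.0 / spec.means[1]
        r1, r2 = a * b1, a * b2

        def rhs(t, y):
            dy = np.empty_like(y)
            dy[0] = -r1 * y[0]
            for i in range(1, a):
                dy[i] = r1 * (y[i - 1] - y[i])
            dy[a] = r1 * y[a - 1] - r2 * y[a]
            for i in range(a + 1, 2 * a):
                dy[i] = r2 * (y[i - 1] - y[i])
            dy[2 * a] = r2 * y[2 * a - 1]
            return dy

        y0 = np.zeros(2 * a + 1)
        y0[0] = 1.0
        return ExpandedMotif(
            spec=spec, y0=y0, rhs=rhs,
            arrival_flux=lambda y: r2 * y[2 * a - 1],
            macro_fractions=lambda y: {"S0": float(np.sum(y[:a])),
                                       "S1": float(np.sum(y[a:2 * a])),
                                       "Sa": float(y[2 * a])},
            arrival_label="Sa",
        )

    if spec.motif == "gate":
        # helper population substeps y[0:a], completed helper y[a];
        # target population substeps y[a+1 : a+1+a], arrivals y[2a+1]
        b_help = 1.0 / spec.means[0]
        b_base = 1.0 / spec.means[1]
        r_help = a * b_help

        def beta_gate(y):
            frac = min(max(y[a], 0.0), 1.0)
            if frac <= 0.0:
                return 0.0
            return float(coupling_gate(frac, b_base, spec.K))

        def rhs(t, y):
            dy = np.empty_like(y)
            dy[0] = -r_help * y[0]
            for i in range(1, a):
                dy[i] = r_help * (y[i - 1] - y[i])
            dy[a] = r_help * y[a - 1]
            r = a * beta_gate(y)
            o = a + 1
            dy[o] = -r * y[o]
            for i in range(1, a):
                dy[o + i] = r * (y[o + i - 1] - y[o + i])
            dy[o + a] = r * y[o + a - 1]
            return dy

        y0 = np.zeros(2 * a + 2)
        y0[0] = 1.0       # helper pool
        y0[a + 1] = 1.0   # target pool (separate unit population)
        return ExpandedMotif(
            spec=spec, y0=y0, rhs=rhs,
            arrival_flux=lambda y: a * beta_gate(y) * y[2 * a],
            macro_fractions=lambda y: {"A0": float(np.sum(y[:a])),
                                       "A1": float(y[a]),
                                       "B0": float(np.sum(y[a + 1:2 * a + 1])),
                                       "Ba": float(y[2 * a + 1])},
            arrival_label="Ba",
        )

    if spec.motif == "feedforward":
        # indirect pool (p01): S0 -> S1 (means[0]) -> Sa (means[1]);
        # direct pool (p02):   S0 -> Sa (means[2])
        b01, b1a, b0a = (1.0 / m for m in spec.means)
        r01, r1a, r0a = a * b01, a * b1a, a * b0a
        p01, p02 = spec.branch_probs

        def rhs(t, y):
            dy = np.empty_like(y)
            # indirect: substeps of S0 chain [0:a], S1 chain [a:2a]
            dy[0] = -r01 * y[0]
            for i in range(1, a):
                dy[i] = r01 * (y[i - 1] - y[i])
            dy[a] = r01 * y[a - 1] - r1a * y[a]
            for i in range(a + 1, 2 * a):
                dy[i] = r1a * (y[i - 1] - y[i])
            # direct: substeps [2a : 3a]
            o = 2 * a
            dy[o] = -r0a * y[o]
            for i in range(1, a):
                dy[o + i] = r0a * (y[o + i - 1] - y[o + i])
            # arrivals
            dy[3 * a] = r1a * y[2 * a - 1] + r0a * y[3 * a - 1]
            return dy

        y0 = np.zeros(3 * a + 1)
        y0[0] = p01
        y0[2 * a] = p02
        return ExpandedMotif(
            spec=spec, y0=y0, rhs=rhs,
            arrival_flux=lambda y: r1a * y[2 * a - 1] + r0a * y[3 * a - 1],
            macro_fractions=lambda y: {"S0": float(np.sum(y[:a]) + np.sum(y[2 * a:3 * a])),
                                       "S1": float(np.sum(y[a:2 * a])),
                                       "Sa": float(y[3 * a])},
            arrival_label="Sa",
        )

    raise ValueError(spec.motif)


def solve_motif(spec: MotifSpec, t_grid: np.ndarray
                ) -> tuple[pd.DataFrame, EmpiricalRT]:
    """Solve a motif deterministically on ``t_grid``.

    Returns the macro-state occupancy fractions over time and the arrival
    density (d/dt of the arrival state, clipped at 0 and renormalized on
    the grid).  The grid must capture essentially all arrivals.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    ex = expand_motif(spec)
    sol = solve_ivp(ex.rhs, (t_grid[0], t_grid[-1]), ex.y0, t_eval=t_grid,
                    method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"motif solver failed for {spec.motif}: {sol.message}")
    fractions = pd.DataFrame([ex.macro_fractions(sol.y[:, j])
                              for j in range(sol.y.shape[1])], index=t_grid)
    flux = np.array([ex.arrival_flux(sol.y[:, j]) for j in range(sol.y.shape[1])])
    arrived = fractions[ex.arrival_label].iloc[-1]
    if arrived < 0.999:
        raise ValueError(
            f"grid captures only {arrived:.4f} of arrivals; extend t_grid"
        )
    density = EmpiricalRT(t_grid, np.clip(flux, 0.0, None),
                          is_normalized=False).normalized()
    return fractions, density


# ---------------------------------------------------------------------------
# feedforward peak-count oracles (exponential steps)
# ---------------------------------------------------------------------------

def count_peaks(density: np.ndarray, prominence_rel: float = _PEAK_PROMINENCE) -> int:
    """Strict local maxima of a density curve above a relative prominence
    floor (default 1e-3 of the maximum), ignoring the boundary points."""
    density = np.asarray(density, dtype=float)
    peaks, _ = find_peaks(density, prominence=prominence_rel * density.max())
    return int(peaks.size)


def feedforward_master_matrix(a: float, b: float, c: float) -> MasterMatrix:
    """3-state master matrix of the single-step feedforward loop with
    competing rates a (S0->S1), b (S1->S2), c (S0->S2)."""
    W = np.array([[-a - c, 0.0, 0.0],
                  [a, -b, 0.0],
                  [c, b, 0.0]])
    return MasterMatrix(W=W, labels=["S0", "S1", "S2"])


def feedforward_degenerate_peak_time(a: float, c: float) -> float:
    """Peak location of the arrival density in the degenerate case b = a + c.

    The solution is phi(t) = exp(-(a+c)t) * (c + a(a+c)t), whose derivative
    vanishes at t* = (a-c)/(a(a+c)); the density has an interior maximum
    only when a > c (otherwise it decreases monotonically from t = 0).
    """
    return (a - c) / (a * (a + c))


def feedforward_peak_count(a: float, b: float, c: float) -> int:
    """Closed-form count of strict local maxima of the arrival density
    dS2/dt of the single-step (exponential) feedforward loop.

    The eigen-solution of the 3-state master equation gives
    S2(t) = k1*exp(-(a+c) t) + k2*exp(-b t) + 1 with
    k1 = (b-c)/(a-b+c), k2 = -a/(a-b+c) (b != a+c), so the arrival density
    phi(t) = dS2/dt is a two-exponential sum whose derivative has at most
    one zero — the count is always 0 or 1.
    """
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("rates must be positive")
    mu1 = a + c
    mu2 = b
    if np.isclose(mu1, mu2):
        # degenerate b = a+c: phi(t) = exp(-(a+c)t)(c + a(a+c)t), interior
        # maximum at t* = (a-c)/(a(a+c)) iff a > c
        return 1 if a > c else 0
    k1 = (b - c) / (a - b + c)
    k2 = -a / (a - b + c)
    if k1 == 0.0:
        return 0  # b = c: density is a pure decaying exponential
    # phi(t) = -k1*mu1*e^(-mu1 t) - k2*mu2*e^(-mu2 t);
    # phi'(t) = k1*mu1^2 e^(-mu1 t) + k2*mu2^2 e^(-mu2 t) = 0  iff
    # e^((mu2-mu1) t) = -k2 mu2^2 / (k1 mu1^2)
    ratio = -(k2 * mu2**2) / (k1 * mu1**2)
    if ratio <= 0:
        return 0  # phi' never vanishes: density monotone after t=0
    t_star = np.log(ratio) / (mu2 - mu1)
    if t_star <= 0:
        return 0
    # second derivative sign at the critical point decides max vs min
    phi2 = (-k1 * mu1**3 * np.exp(-mu1 * t_star)
            - k2 * mu2**3 * np.exp(-mu2 * t_star))
    return 1 if phi2 < 0 else 0


def feedforward_numeric_peak_count(a: float, b: float, c: float,
                                   t_max: float | None = None,
                                   n_points: int = 4000) -> int:
    """Peak count from numerical integration of the 3-state master equation
    (independent of the closed-form eigen-solution)."""
    mm = feedforward_master_matrix(a, b, c)
    if t_max is None:
        t_max = 12.0 / min(a + c, b)
    t = np.linspace(0.0, t_max, n_points)
    sol = solve_ivp(lambda _t, y: mm.W @ y, (0.0, t_max), [1.0, 0.0, 0.0],
                    t_eval=t, method="LSODA", rtol=1e-10, atol=1e-12)
    phi = np.array([mm.W[2, :2] @ sol.y[:2, j] for j in range(sol.y.shape[1])])
    return count_peaks(phi)


def feedforward_motif_rt(spec: MotifSpec, t_grid: np.ndarray | None = None
                         ) -> tuple[EmpiricalRT, int]:
    """Arrival density of the feedforward motif plus its peak count.

    With multi-step transitions (shape >> 1) and a slow indirect route the
    density is bimodal (2 peaks); single-step transitions give at most one
    peak regardless of timescale separation.
    """
    if spec.motif != "feedforward":
        raise ValueError("spec must be a feedforward motif")
    if t_grid is None:
        horizon = 8.0 * (spec.means[0] + spec.means[1] + spec.means[2])
        t_grid = np.linspace(0.0, horizon, 6000)
    _, density = solve_motif(spec, t_grid)
    return density, count_peaks(density.density)


def feedforward_separation_spec(separation: float, shape: int = 10,
                                direct_mean: float = 1.0,
                                branch_probs: tuple[float, float] = (0.5, 0.5)
                                ) -> MotifSpec:
    """Feedforward spec with a given route-timescale separation.

    ``separation`` is the ratio of the indirect route's total mean
    (S0->S1->Sa, split evenly over its two legs) to the direct route's
    mean.  separation = 1 makes the two routes' arrival peaks coincide
    (a single peak); a large separation with multi-step transitions
    produces a bimodal arrival distribution.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    leg = 0.5 * separation * direct_mean
    return MotifSpec("feedforward", shape=shape, means=(leg, leg, direct_mean),
                     branch_probs=branch_probs)


def motif_metrics_scan(motif: str, scan_values: Sequence[float],
                       shape: int = 10, K: float = 0.1,
                       base_mean: float = 1.0,
                       t_max: float = 60.0, n_points: int = 6000
                       ) -> pd.DataFrame:
    """Delay and synchronization time across a one-parameter motif scan.

    - ``transition``: scan the transition mean (1/beta).
    - ``double_transition``: scan the first transition mean.
    - ``gate``: scan the helper (gating) transition mean.
    - ``feedback``: scan the feedback fold-change eta.

    Returns a DataFrame with columns scan, delay, sync.
    """
    from .metrics import delay_time, synchronization_time

    rows = []
    for v in scan_values:
        if motif == "transition":
            spec = MotifSpec("transition", shape=shape, means=(v,))
        elif motif == "double_transition":
            spec = MotifSpec("double_transition", shape=shape, means=(v, base_mean))
        elif motif == "gate":
            spec = MotifSpec("gate", shape=shape, means=(v, base_mean), K=K)
        elif motif == "feedback":
            spec = MotifSpec("feedback", shape=shape, means=(base_mean,), K=K, eta=v)
        else:
            raise ValueError(f"no scan defined for motif {motif!r}")
        t_grid = np.linspace(0.0, t_max, n_points)
        _, density = solve_motif(spec, t_grid)
        d = delay_time(density)
        s = synchronization_time(density, t_delay=d)
        rows.append({"scan": v, "delay": d, "sync": s})
    return pd.DataFrame(rows)
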