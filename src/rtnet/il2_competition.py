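"""IL-2 competition between helper (Th) and regulatory (Treg) T cells.

Th cells secrete IL-2 and upregulate its high-affinity receptor (CD25)
upon activation; Treg cells express more IL-2 receptors and consume IL-2
without secreting it, so they compete with Th cells for the cytokine.  The
case study closes a response-time model over this competition:

1. A receptor-dynamics ODE (surface receptors R, IL-2/receptor complexes
   C, internalized complexes E, with complex-induced receptor synthesis
   v(C) = v0 + v1*C^3/(K^3+C^3)) is solved at fixed extracellular IL-2.
2. The complex kinetics C(t) — the experimentally accessible CD25
   upregulation readout — are converted into a response-time law: the
   curve after a 1 hr burn-in is baseline-subtracted, normalized, and fit
   by a gamma CDF.
3. Repeating over an IL-2 concentration grid and fitting the interpolating
   forms alpha([IL-2]) = C_a + (K_a/[IL-2])^n (decreasing) and
   beta([IL-2]) = V_b*[IL-2]/(K_b + [IL-2]) (saturating) compresses the
   whole family of response-time laws into five constants per cell type.
4. A well-stirred steady-state balance gives the extracellular IL-2
   concentration from the current activation state:
   [IL-2] = q*sigma*f_Th / (k_on*(R_Th*sigma*f_Th*A_Th +
   R_Treg*sigma*f_Treg*A_Treg) + 4*pi*D*rho/Vol),
   i.e. production over consumption by receptors plus diffusive escape.
5. The population simulation couples everything: after every activation
   event the balance is re-evaluated and both cell types' gamma parameters
   updated through the interpolators, closing the loop.

Units: rates in 1/h, concentrations in nM, D in um^2/s, rho in um, volume
in ul.  Receptor terms are converted to nM via cells/ul x molecules/cell /
Avogadro; the diffusive escape 4*pi*D*rho/Vol is converted to 1/h.  The
secretion rate q and the cell density sigma are not fixed by the receptor
constants; they are configuration values with documented defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .distributions import DistributionFit, EmpiricalRT, GammaRT
from .engine import (
    CellState,
    CommunicationNetwork,
    PopulationTrajectory,
    TransitionSpec,
    simulate,
)

__all__ = [
    "ReceptorModelParams",
    "MilieuParams",
    "Interpolators",
    "solve_receptor_model",
    "receptor_kinetics_to_rt",
    "rt_laws_on_grid",
    "fit_interpolators",
    "il2_balance",
    "simulate_competition",
    "CompetitionResult",
]

AVOGADRO = 6.02214076e23
#: molecules per ul -> nM:  (1e6 ul/L) * (1e9 nM/M) / N_A
_MOLEC_PER_UL_TO_NM = 1e15 / AVOGADRO
#: cap on the interpolated gamma shape at very low IL-2 (alpha diverges as
#: [IL-2] -> 0 while beta -> 0; the law is effectively blocked there anyway)
_ALPHA_CAP = 1e3


@dataclass(frozen=True)
class ReceptorModelParams:
    """IL-2 receptor kinetics constants (defaults: printed model values).

    k_on [1/(nM h)] IL-2/receptor binding; k_iR [1/h] receptor
    internalization; k_off [1/h] unbinding; k_rec [1/h] recycling;
    k_iC [1/h] complex internalization; k_deg [1/h] degradation;
    K [molecules/cell] half-saturation of complex-induced synthesis;
    v0, v1 [molecules/(cell h)] basal and induced synthesis rates
    (Th: 150/3000, Treg: 1000/8000).
    """

    k_on: float = 112.0
    k_iR: float = 0.64
    k_off: float = 0.83
    k_rec: float = 9.0
    k_iC: float = 1.7
    k_deg: float = 5.0
    K: float = 1000.0
    v0: float = 150.0
    v1: float = 3000.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_iR", "k_off", "k_rec", "k_iC", "k_deg", "K",
                     "v0", "v1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def th(cls) -> "ReceptorModelParams":
        return cls()

    @classmethod
    def treg(cls) -> "ReceptorModelParams":
        return cls(v0=1000.0, v1=8000.0)


def solve_receptor_model(params: ReceptorModelParams, il2_conc: float,
                         t_grid: np.ndarray) -> pd.DataFrame:
    """Receptor/complex kinetics at fixed extracellular IL-2 (nM).

    dR/dt = v(C) - (k_on*I + k_iR)*R + k_off*C + k_rec*E
    dC/dt = k_on*R*I - (k_off + k_iC)*C
    dE/dt = k_iC*C - (k_rec + k_deg)*E,  v(C) = v0 + v1*C^3/(K^3 + C^3)

    Initial condition: the IL-2-free steady state R = v0/k_iR, C = E = 0.
    Returns a DataFrame with columns R, C, E indexed by time [h].
    """
    if il2_conc < 0:
        raise ValueError("il2_conc must be nonnegative")
    t_grid = np.asarray(t_grid, dtype=float)
    p = params
    I = il2_conc

    def rhs(t, y):
        R, C, E = y
        v = p.v0 + p.v1 * C**3 / (p.K**3 + C**3)
        return [v - (p.k_on * I + p.k_iR) * R + p.k_off * C + p.k_rec * E,
                p.k_on * R * I - (p.k_off + p.k_iC) * C,
                p.k_iC * C - (p.k_rec + p.k_deg) * E]

    y0 = [p.v0 / p.k_iR, 0.0, 0.0]
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"receptor model solver failed: {sol.message}")
    return pd.DataFrame({"R": sol.y[0], "C": sol.y[1], "E": sol.y[2]},
                        index=t_grid)


def receptor_kinetics_to_rt(t: np.ndarray, C: np.ndarray,
                            burn_in: float = 1.0
                            ) -> tuple[EmpiricalRT, DistributionFit]:
    """Convert a complex-kinetics curve into a response-time law.

    The initial steep rise to a basal level (first ``burn_in`` hours) is
    discarded; the remaining curve is baseline-subtracted and normalized
    to its final value, identified with the cumulative response-time
    distribution of T cell activation, and fit by a gamma CDF.  Returns
    the implied density on the grid and the gamma fit.
    """
    t = np.asarray(t, dtype=float)
    C = np.asarray(C, dtype=float)
    mask = t >= burn_in
    if mask.sum() < 5:
        raise ValueError("curve must extend well beyond the burn-in")
    tt, cc = t[mask], C[mask]
    rise = cc[-1] - cc[0]
    if rise <= 1e-9 * max(abs(cc[-1]), 1.0):
        raise ValueError("flat complex curve after burn-in: no upregulation")
    u = (cc - cc[0]) / rise
    if np.any(np.diff(u) < -1e-3):
        raise ValueError("non-monotone complex curve: cannot be normalized "
                         "into a cumulative response-time distribution")
    u = np.clip(u, 0.0, 1.0)

    fitted = _fit_gamma_cdf(tt, u)
    dens = np.gradient(u, tt)
    emp = EmpiricalRT(tt, np.clip(dens, 0.0, None),
                      is_normalized=False).normalized()
    rmse = float(np.sqrt(np.mean((fitted.cdf(tt) - u) ** 2)))
    return emp, DistributionFit(fitted=fitted, rmse=rmse)


def _fit_gamma_cdf(t: np.ndarray, u: np.ndarray) -> GammaRT:
    from scipy.stats import gamma as gamma_dist

    dens = np.clip(np.gradient(u, t), 0.0, None)
    mass = max(np.trapezoid(dens, t), 1e-12)
    mean = np.trapezoid(t * dens, t) / mass
    var = max(np.trapezoid(t**2 * dens, t) / mass - mean**2, (1e-3 * mean) ** 2)

    def residual(p):
        a, b = p
        return gamma_dist.cdf(t, a=a, scale=1.0 / b) - u

    sol = least_squares(residual, x0=[mean**2 / var, mean / var],
                        bounds=([1e-6, 1e-6], np.inf))
    return GammaRT(shape=float(sol.x[0]), rate=float(sol.x[1]))


def rt_laws_on_grid(params: ReceptorModelParams, il2_grid: np.ndarray,
                    t_max: float = 50.0, n_points: int = 2000,
                    burn_in: float = 1.0) -> pd.DataFrame:
    """Best-fit gamma (alpha, beta) of the activation law per IL-2 level."""
    rows = []
    t_grid = np.linspace(0.0, t_max, n_points)
    for conc in np.asarray(il2_grid, dtype=float):
        traj = solve_receptor_model(params, conc, t_grid)
        _, fit = receptor_kinetics_to_rt(t_grid, traj["C"].to_numpy(),
                                         burn_in=burn_in)
        rows.append({"il2": conc, "alpha": fit.fitted.shape,
                     "beta": fit.fitted.rate, "rmse": fit.rmse})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Interpolators:
    """Five constants summarizing activation laws vs IL-2 concentration.

    alpha([IL-2]) = C_alpha + (K_alpha/[IL-2])^n_hill  (decreasing)
    beta([IL-2])  = V_beta*[IL-2]/(K_beta + [IL-2])    (saturating)
    """

    C_alpha: float
    K_alpha: float
    n_hill: float
    V_beta: float
    K_beta: float

    def __post_init__(self) -> None:
        for name in ("C_alpha", "K_alpha", "n_hill", "V_beta", "K_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def alpha(self, il2: float) -> float:
        if il2 <= 0:
            return _ALPHA_CAP
        return min(self.C_alpha + (self.K_alpha / il2) ** self.n_hill, _ALPHA_CAP)

    def beta(self, il2: float) -> float:
        if il2 <= 0:
            return 0.0
        return self.V_beta * il2 / (self.K_beta + il2)


def fit_interpolators(il2_grid: np.ndarray, alphas: np.ndarray,
                      betas: np.ndarray) -> Interpolators:
    """Least-squares fit of the two interpolating forms to fitted (alpha,
    beta) values on an IL-2 grid (>= 4 concentrations)."""
    il2 = np.asarray(il2_grid, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if il2.size < 4:
        raise ValueError("need at least 4 grid concentrations")

    def res_alpha(p):
        c, k, n = p
        return c + (k / il2) ** n - alphas

    a0 = [max(alphas.min(), 1e-3), np.median(il2), 1.0]
    sol_a = least_squares(res_alpha, x0=a0, bounds=([1e-9, 1e-9, 1e-3], np.inf))

    def res_beta(p):
        v, k = p
        return v * il2 / (k + il2) - betas

    b0 = [max(betas.max(), 1e-6), np.median(il2)]
    sol_b = least_squares(res_beta, x0=b0, bounds=([1e-9, 1e-9], np.inf))
    return Interpolators(C_alpha=float(sol_a.x[0]), K_alpha=float(sol_a.x[1]),
                         n_hill=float(sol_a.x[2]), V_beta=float(sol_b.x[0]),
                         K_beta=float(sol_b.x[1]))


@dataclass(frozen=True)
class MilieuParams:
    """Extracellular milieu of the competition model.

    D [um^2/s] IL-2 diffusion constant; rho [um] cell diameter;
    volume_ul [ul] diffusive volume; sigma [cells/ul] total cell density;
    q [molecules/(cell h)] IL-2 secretion rate per Th cell; f_th, f_treg
    population fractions; R_th, R_treg [molecules/cell] receptor numbers.
    sigma and q are configuration values (defaults: 2000 cells/ul, 1000
    molecules/(cell h)); the rest default to the printed constants.
    """

    D: float = 10.0
    rho: float = 5.0
    volume_ul: float = 1.0
    sigma: float = 2000.0
    q: float = 1000.0
    f_th: float = 0.5
    f_treg: float = 0.5
    R_th: float = 1000.0
    R_treg: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("D", "rho", "volume_ul", "sigma", "R_th", "R_treg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.q < 0:
            raise ValueError("q must be nonnegative")
        for name in ("f_th", "f_treg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def escape_rate_per_h(self) -> float:
        """Diffusive escape 4*pi*D*rho/Vol in 1/h."""
        um3_per_h = 4.0 * np.pi * self.D * self.rho * 3600.0
        return um3_per_h / (self.volume_ul * 1e9)


def il2_balance(milieu: MilieuParams, A_th: float, A_treg: float,
                k_on: float = 112.0) -> float:
    """Steady-state extracellular IL-2 concentration [nM].

    [IL-2] = q*sigma*f_th / (k_on*(R_th*sigma*f_th*A_th +
    R_treg*sigma*f_treg*A_treg) + 4*pi*D*rho/Vol): production by Th cells
    over consumption by receptors on active cells plus diffusive escape.
    Decreasing in each activation fraction and receptor number, linear in
    q and f_th.
    """
    if not (0.0 <= A_th <= 1.0 and 0.0 <= A_treg <= 1.0):
        raise ValueError("activation fractions must lie in [0, 1]")
    production = milieu.q * milieu.sigma * milieu.f_th * _MOLEC_PER_UL_TO_NM  # nM/h
    receptors_nM = (milieu.R_th * milieu.sigma * milieu.f_th * A_th
                    + milieu.R_treg * milieu.sigma * milieu.f_treg * A_treg
                    ) * _MOLEC_PER_UL_TO_NM
    denom = k_on * receptors_nM + milieu.escape_rate_per_h  # 1/h
    return production / denom


@dataclass
class CompetitionResult:
    """Activation kinetics and IL-2 trace of one competition run."""

    trajectory: PopulationTrajectory
    occupancy: pd.DataFrame           # fractions of total population
    activation_th: pd.Series          # active fraction among Th cells
    activation_treg: pd.Series | None
    il2_trace: pd.Series              # [IL-2] (nM) at event times
    milieu: MilieuParams

    def half_activation_time(self, cell_type: str = "th") -> float:
        """First time the active fraction of the given type exceeds 1/2."""
        series = self.activation_th if cell_type == "th" else self.activation_treg
        if series is None:
            raise ValueError(f"no {cell_type} cells in this run")
        above = series[series >= 0.5]
        if above.empty:
            raise ValueError("activation never reaches 50%")
        return float(above.index[0])


def simulate_competition(interp_th: Interpolators,
                         interp_treg: Interpolators,
                         milieu: MilieuParams | None = None,
                         n_cells: int = 2000, t_max: float = 60.0,
                         seed: int = 0) -> CompetitionResult:
    """Closed-loop competition of Th and Treg cells for IL-2.

    ``n_cells`` cells (Th and Treg combined, fractions from ``milieu``)
    each undergo one activation transition whose gamma parameters follow
    the interpolators at the current IL-2 concentration; the concentration
    is recomputed from the activated fractions after every event, so the
    hazards are piecewise-constant between events.
    """
    milieu = milieu or MilieuParams()
    f_th, f_treg = milieu.f_th, milieu.f_treg
    if f_th + f_treg > 1.0 + 1e-9:
        raise ValueError("f_th + f_treg must be <= 1")

    def conc_from_fractions(fr: dict[str, float]) -> float:
        A_th = fr.get("Th_active", 0.0) / f_th if f_th > 0 else 0.0
        A_treg = fr.get("Treg_active", 0.0) / f_treg if f_treg > 0 else 0.0
        return il2_balance(milieu, min(A_th, 1.0), min(A_treg, 1.0))

    def law_th(fr: dict[str, float]) -> tuple[float, float]:
        c = conc_from_fractions(fr)
        return interp_th.alpha(c), interp_th.beta(c)

    def law_treg(fr: dict[str, float]) -> tuple[float, float]:
        c = conc_from_fractions(fr)
        return interp_treg.alpha(c), interp_treg.beta(c)

    states = [CellState("Th_naive"), CellState("Th_active", is_absorbing=True),
              CellState("Treg_naive"),
              CellState("Treg_active", is_absorbing=True)]
    transitions = [
        TransitionSpec("Th_naive", "Th_active", law_fn=law_th),
        TransitionSpec("Treg_naive", "Treg_active", law_fn=law_treg),
    ]
    initial = {"Th_naive": f_th, "Treg_naive": f_treg}
    inert = 1.0 - f_th - f_treg
    if inert > 1e-12:
        states.append(CellState("inert", is_absorbing=True))
        initial["inert"] = inert
    network = CommunicationNetwork(states=states, transitions=transitions,
                                   initial=initial)
    # a milieu without IL-2 production blocks every transition; that is a
    # legitimate no-activation outcome, not an error
    traj = simulate(network, n_cells=n_cells, t_max=t_max, seed=seed,
                    on_deadlock="stop")

    t_grid = np.linspace(0.0, traj.t_end, 400)
    occ = traj.occupancy(t_grid)
    act_th = occ["Th_active"] / f_th if f_th > 0 else occ["Th_active"] * 0.0
    act_treg = occ["Treg_active"] / f_treg if f_treg > 0 else None

    # IL-2 trace at event times (fractions change only at events)
    ev_times = np.concatenate([[0.0], traj.events["time"].to_numpy()])
    occ_ev = traj.occupancy(ev_times)
    conc = [conc_from_fractions(dict(row)) for _, row in occ_ev.iterrows()]
    il2_trace = pd.Series(conc, index=ev_times, name="il2_nM")

    return CompetitionResult(trajectory=traj, occupancy=occ,
                             activation_th=act_th, activation_treg=act_treg,
                             il2_trace=il2_trace, milieu=milieu)
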