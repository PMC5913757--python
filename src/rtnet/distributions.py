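"""Waiting-time distribution algebra for response-time modeling.

Cellular response times — the time from an input stimulus to an observable
cell-state change — are modeled as random variables.  A multi-step
intracellular process of ``n`` identical irreversible steps has a
gamma-distributed response time (the n-fold convolution of exponentials),
which motivates the gamma law as the workhorse parameterization here:

    gamma(alpha, beta; t) = t**(alpha-1) * exp(-beta*t) * beta**alpha / Gamma(alpha)

with shape ``alpha`` (interpretable as a non-integer-valued effective step
number) and rate ``beta``.  ``alpha = 1`` is the exponential (single-step,
Markovian) special case.  Empirical densities on a time grid carry
numerically computed response-time distributions, and least-squares gamma /
exponential fits summarize them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GammaRT",
    "EmpiricalRT",
    "DistributionFit",
    "gamma_density",
    "gamma_from_moments",
    "hazard",
    "convolve_uniform_chain",
    "fit_gamma",
    "fit_exponential",
]

#: survival mass below which the hazard is considered to have exhausted its
#: support; callers treat such transitions as firing immediately.
_SURVIVAL_FLOOR = 1e-300
_HAZARD_CAP = 1e12


class ExhaustedSupportError(FloatingPointError):
    """Raised when a hazard is requested past the numerical support of a law."""


@dataclass(frozen=True)
class GammaRT:
    """Gamma-distributed response-time law with shape ``alpha``, rate ``beta``.

    mean = shape/rate, CV = 1/sqrt(shape).  ``shape == 1`` is the
    exponential law with rate ``beta``.
    """

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and np.isfinite(self.shape)):
            raise ValueError(f"shape must be positive, got {self.shape}")
        if not (self.rate > 0 and np.isfinite(self.rate)):
            raise ValueError(f"rate must be positive, got {self.rate}")

    # -- moments -----------------------------------------------------------
    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def cv(self) -> float:
        return 1.0 / np.sqrt(self.shape)

    @property
    def sd(self) -> float:
        return np.sqrt(self.shape) / self.rate

    @property
    def is_exponential(self) -> bool:
        return np.isclose(self.shape, 1.0)

    # -- distribution functions -------------------------------------------
    def pdf(self, t):
        return stats.gamma.pdf(t, a=self.shape, scale=1.0 / self.rate)

    def logpdf(self, t):
        return stats.gamma.logpdf(t, a=self.shape, scale=1.0 / self.rate)

    def cdf(self, t):
        return stats.gamma.cdf(t, a=self.shape, scale=1.0 / self.rate)

    def sf(self, t):
        return stats.gamma.sf(t, a=self.shape, scale=1.0 / self.rate)

    def logsf(self, t):
        return stats.gamma.logsf(t, a=self.shape, scale=1.0 / self.rate)

    def ppf(self, q):
        return stats.gamma.ppf(q, a=self.shape, scale=1.0 / self.rate)

    def rvs(self, size, rng: np.random.Generator):
        return rng.gamma(shape=self.shape, scale=1.0 / self.rate, size=size)

    def hazard(self, tau):
        """Instantaneous rate psi(tau)/phi(tau), capped at 1e12.

        Constant (= rate) for the exponential case; 0 at tau = 0 for
        shape > 1; tends to ``rate`` as tau -> infinity.
        """
        tau = np.asarray(tau, dtype=float)
        with np.errstate(over="ignore"):
            h = np.exp(self.logpdf(tau) - self.logsf(tau))
        h = np.where(np.isfinite(h), h, _HAZARD_CAP)
        return np.minimum(h, _HAZARD_CAP)[()] if h.ndim == 0 else np.minimum(h, _HAZARD_CAP)

    def default_grid(self, n_points: int = 2001) -> np.ndarray:
        """Uniform grid on [0, mean + 8 sd], the default support window."""
        return np.linspace(0.0, self.mean + 8.0 * self.sd, n_points)

    # -- serialization -----------------------------------------------------
    def to_record(self) -> dict:
        family = "exponential" if self.is_exponential else "gamma"
        return {"family": family, "shape": float(self.shape), "rate": float(self.rate)}

    @classmethod
    def from_record(cls, record: dict) -> "GammaRT":
        family = record.get("family", "gamma")
        if family == "exponential":
            return cls(shape=1.0, rate=float(record["rate"]))
        if family != "gamma":
            raise ValueError(f"unknown distribution family {family!r}")
        return cls(shape=float(record["shape"]), rate=float(record["rate"]))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_record()))

    @classmethod
    def from_json(cls, path) -> "GammaRT":
        return cls.from_record(json.loads(Path(path).read_text()))


def exponential_rt(rate: float) -> GammaRT:
    """Exponential (single-step) law as the shape-1 gamma."""
    return GammaRT(shape=1.0, rate=rate)


@dataclass
class EmpiricalRT:
    """Numerically computed response-time density on a time grid.

    ``times`` must be strictly increasing; ``density`` nonnegative.  When
    ``is_normalized`` the trapezoidal integral of the density is ~1.
    """

    times: np.ndarray
    density: np.ndarray
    is_normalized: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("times must be a 1-D grid with >= 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.density.shape != self.times.shape:
            raise ValueError("density must match the time grid")
        if np.any(self.density < -1e-12):
            raise ValueError("density must be nonnegative")
        self.density = np.clip(self.density, 0.0, None)
        if self.is_normalized:
            total = np.trapezoid(self.density, self.times)
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(
                    f"density marked normalized but integrates to {total:.6g}"
                )

    @property
    def total_mass(self) -> float:
        return float(np.trapezoid(self.density, self.times))

    def normalized(self) -> "EmpiricalRT":
        total = self.total_mass
        if total <= 0:
            raise ValueError("cannot normalize an all-zero density")
        return EmpiricalRT(self.times, self.density / total, is_normalized=True)

    def mean(self) -> float:
        return float(np.trapezoid(self.times * self.density, self.times) / self.total_mass)

    def variance(self) -> float:
        m = self.mean()
        m2 = np.trapezoid(self.times**2 * self.density, self.times) / self.total_mass
        return float(max(m2 - m * m, 0.0))

    def cdf_values(self) -> np.ndarray:
        """Cumulative curve on the grid (trapezoid rule)."""
        from scipy.integrate import cumulative_trapezoid

        return cumulative_trapezoid(self.density, self.times, initial=0.0)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sampling on the grid (linear interpolation)."""
        cdf = self.cdf_values()
        cdf = cdf / cdf[-1]
        u = rng.uniform(size=size)
        return np.interp(u, cdf, self.times)

    # -- serialization -----------------------------------------------------
    def to_csv(self, path) -> None:
        header = "time,density"
        np.savetxt(path, np.column_stack([self.times, self.density]),
                   delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path, is_normalized: bool = True) -> "EmpiricalRT":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(times=data[:, 0], density=data[:, 1], is_normalized=is_normalized)


@dataclass
class DistributionFit:
    """Result of a least-squares density fit: fitted law + RMS residual."""

    fitted: GammaRT
    rmse: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be nonnegative")


# ---------------------------------------------------------------------------
# functional API
# ---------------------------------------------------------------------------

def gamma_density(dist: GammaRT, t):
    """Gamma density t**(a-1) e**(-b t) b**a / Gamma(a); vectorized over t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    return dist.pdf(t)


def gamma_from_moments(mean: float, cv: float) -> GammaRT:
    """Gamma law from (mean, CV): shape = 1/CV**2, rate = shape/mean.

    This is the summary parameterization used for measured onset-time
    distributions (e.g., IL-2 secretion onset: mean 6.3 hr, CV 0.4).
    """
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if cv <= 0:
        raise ValueError(f"cv must be positive, got {cv}")
    shape = 1.0 / cv**2
    return GammaRT(shape=shape, rate=shape / mean)


def hazard(dist, tau):
    """Hazard rate psi(tau)/phi(tau) of a waiting-time law.

    Works for :class:`GammaRT` (closed form) and :class:`EmpiricalRT`
    (grid-based).  Raises :class:`ExhaustedSupportError` where the survival
    has numerically vanished.
    """
    if isinstance(dist, GammaRT):
        tau_arr = np.asarray(tau, dtype=float)
        sf = dist.sf(tau_arr)
        if np.any(sf <= _SURVIVAL_FLOOR):
            raise ExhaustedSupportError("survival numerically zero at requested tau")
        return dist.hazard(tau)
    if isinstance(dist, EmpiricalRT):
        cdf = dist.cdf_values()
        surv = np.clip(1.0 - cdf / max(cdf[-1], 1.0), 0.0, None)
        psi = np.interp(tau, dist.times, dist.density)
        phi = np.interp(tau, dist.times, surv)
        if np.any(np.asarray(phi) <= _SURVIVAL_FLOOR):
            raise ExhaustedSupportError("survival numerically zero at requested tau")
        return psi / phi
    raise TypeError(f"unsupported law type {type(dist).__name__}")


def convolve_uniform_chain(n: int, per_step_rate: float) -> GammaRT:
    """Response-time law of n identical irreversible steps of the given rate.

    The n-fold convolution of exponential(mu) densities is the gamma law
    with shape n and rate mu.
    """
    if n < 1 or int(n) != n:
        raise ValueError(f"n must be a positive integer, got {n}")
    return GammaRT(shape=float(n), rate=per_step_rate)


def _density_lsq_fit(emp: EmpiricalRT, fix_shape: float | None = None) -> DistributionFit:
    if not emp.is_normalized:
        raise ValueError("empirical density must be normalized before fitting")
    if emp.times.size < 5:
        raise ValueError("need at least 5 grid points to fit")
    if np.all(emp.density == 0):
        raise ValueError("cannot fit an all-zero density")

    mean = emp.mean()
    var = emp.variance()
    # moment-based initial guess; variance floor keeps the guess finite for
    # near-degenerate inputs
    var = max(var, (1e-3 * mean) ** 2)
    shape0 = mean**2 / var
    rate0 = mean / var

    t, y = emp.times, emp.density
    if fix_shape is None:
        def residual(params):
            a, b = params
            return stats.gamma.pdf(t, a=a, scale=1.0 / b) - y
        x0 = [shape0, rate0]
        lower = [1e-6, 1e-6]
    else:
        def residual(params):
            (b,) = params
            return stats.gamma.pdf(t, a=fix_shape, scale=1.0 / b) - y
        x0 = [1.0 / mean]
        lower = [1e-6]

    sol = optimize.least_squares(residual, x0=x0, bounds=(lower, np.inf),
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if fix_shape is None:
        fitted = GammaRT(shape=float(sol.x[0]), rate=float(sol.x[1]))
    else:
        fitted = GammaRT(shape=float(fix_shape), rate=float(sol.x[0]))
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return DistributionFit(fitted=fitted, rmse=rmse)


def fit_gamma(emp: EmpiricalRT) -> DistributionFit:
    """Least-squares best-fit gamma to an empirical density curve.

    Nonlinear least squares on the density values on the grid (not maximum
    likelihood), with a moment-based initial guess; parameters bounded below
    at 1e-6.  The RMS residual doubles as the bimodality measure: a bimodal
    curve cannot be matched by a single gamma.
    """
    return _density_lsq_fit(emp)


def fit_exponential(emp: EmpiricalRT) -> DistributionFit:
    """Least-squares best-fit exponential (shape fixed at 1)."""
    return _density_lsq_fit(emp, fix_shape=1.0)


def fit_gamma_to_samples(samples: np.ndarray, n_bins: int = 100) -> DistributionFit:
    """Histogram-estimate a density from samples, then least-squares gamma fit.

    The histogram range is clipped at the 99.5th percentile so that heavy
    tails do not starve the bulk of the distribution of bin resolution.
    """
    samples = np.asarray(samples, dtype=float)
    hi = np.quantile(samples, 0.995)
    hist, edges = np.histogram(samples, bins=n_bins, range=(0.0, hi), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    emp = EmpiricalRT(centers, hist, is_normalized=False).normalized()
    return fit_gamma(emp)
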