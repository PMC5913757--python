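"""Quantitative measures of arrival-time distributions.

Three scalar summaries of how a cell population responds in time:

- **delay time**: the longest time before at most 5% of the population has
  responded — the 5th percentile of the arrival-time distribution.
- **synchronization time**: the minimal time window after the delay in
  which a fraction d (default 75%) of the *remaining* cells responds for
  the first time, defined through the future-lifetime probability
  P(t, tau) = [F(t+tau) - F(t)] / [1 - F(t)].
- **bimodality score**: the RMS residual of the best single-gamma fit to
  the density; a bimodal curve cannot be matched by one gamma, so a large
  residual flags bimodality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .distributions import EmpiricalRT, GammaRT, fit_gamma

__all__ = [
    "MetricReport",
    "UndefinedMetricError",
    "delay_time",
    "synchronization_time",
    "bimodality_score",
    "metric_report",
]


class UndefinedMetricError(ValueError):
    """The requested metric is undefined for this distribution (e.g. the
    cumulative curve never reaches the required fraction)."""


def _cdf_pair(dist) -> tuple[np.ndarray, np.ndarray]:
    """(t, F) arrays for an EmpiricalRT; analytic laws are handled separately."""
    cdf = cumulative_trapezoid(dist.density, dist.times, initial=0.0)
    if dist.is_normalized:
        cdf = np.clip(cdf, 0.0, 1.0)
    return dist.times, cdf


def _quantile(dist, q: float) -> float:
    """Quantile by monotone interpolation of the cumulative curve."""
    if isinstance(dist, GammaRT):
        return float(dist.ppf(q))
    if isinstance(dist, EmpiricalRT):
        t, F = _cdf_pair(dist)
        if F[-1] < q:
            raise UndefinedMetricError(
                f"cumulative curve reaches only {F[-1]:.4f} < requested {q}"
            )
        # strictly increasing envelope for interpolation
        j = np.searchsorted(F, q, side="left")
        if j == 0:
            return float(t[0])
        f0, f1 = F[j - 1], F[j]
        if f1 == f0:
            return float(t[j])
        return float(t[j - 1] + (q - f0) / (f1 - f0) * (t[j] - t[j - 1]))
    raise TypeError(f"unsupported distribution type {type(dist).__name__}")


def delay_time(dist, fraction: float = 0.05) -> float:
    """Delay: the ``fraction`` quantile (default 5%) of the arrival curve.

    Shifting the whole distribution by +c shifts the delay by exactly c.
    Raises :class:`UndefinedMetricError` if the cumulative curve never
    reaches ``fraction``.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0.0:
        return 0.0
    return _quantile(dist, fraction)


def synchronization_time(dist, t_delay: float | None = None,
                         d: float = 0.75) -> float:
    """Minimal tau with P(t_delay, tau) >= d, where P is the future
    lifetime [F(t+tau) - F(t)] / [1 - F(t)].

    For an exponential law this is -ln(1-d)/rate independently of t_delay
    (memorylessness).  Raises :class:`UndefinedMetricError` when less than
    d of the remaining mass is ever reached.
    """
    if not (0.0 <= d < 1.0):
        raise ValueError("d must lie in [0, 1)")
    if d == 0.0:
        return 0.0
    if t_delay is None:
        t_delay = delay_time(dist)
    if isinstance(dist, GammaRT):
        F0 = float(dist.cdf(t_delay))
        target = F0 + d * (1.0 - F0)
        return float(dist.ppf(target)) - t_delay
    if isinstance(dist, EmpiricalRT):
        t, F = _cdf_pair(dist)
        F0 = float(np.interp(t_delay, t, F))
        if F0 >= 1.0:
            raise UndefinedMetricError("distribution fully exhausted at t_delay")
        target = F0 + d * (1.0 - F0)
        if F[-1] < target - 1e-12:
            raise UndefinedMetricError(
                f"cumulative curve reaches only {F[-1]:.4f} < target {target:.4f}"
            )
        return _quantile(dist, min(target, F[-1])) - t_delay
    raise TypeError(f"unsupported distribution type {type(dist).__name__}")


def bimodality_score(emp: EmpiricalRT | GammaRT, n_points: int = 1000) -> float:
    """RMS residual of the best single-gamma fit to the density.

    ~0 for an exact gamma; large for two-peaked curves relative to
    matched single-peaked controls.
    """
    if isinstance(emp, GammaRT):
        grid = emp.default_grid(n_points)
        emp = EmpiricalRT(grid, emp.pdf(grid), is_normalized=False).normalized()
    return fit_gamma(emp).rmse


@dataclass
class MetricReport:
    """Delay, synchronization and bimodality of one arrival distribution."""

    delay: float
    sync: float
    bimodality: float
    fraction_d: float = 0.75
    fraction_delay: float = 0.05

    def __post_init__(self) -> None:
        if self.delay < 0 or self.sync < 0 or self.bimodality < 0:
            raise ValueError("metrics must be nonnegative")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def metric_report(dist, d: float = 0.75, delay_fraction: float = 0.05
                  ) -> MetricReport:
    """All three measures of one (normalized) arrival-time distribution."""
    t_delay = delay_time(dist, fraction=delay_fraction)
    t_sync = synchronization_time(dist, t_delay=t_delay, d=d)
    score = bimodality_score(dist)
    return MetricReport(delay=t_delay, sync=t_sync, bimodality=score,
                        fraction_d=d, fraction_delay=delay_fraction)
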