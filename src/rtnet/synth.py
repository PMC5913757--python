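"""Synthetic onset-time fixtures emulating measured response-time data.

The measured inputs this package's case studies rest on are (i) gamma-
distributed, single-peaked cytokine secretion onset times summarized by
(mean, CV) pairs — e.g. IL-2 secretion onset with mean 6.3 hr and CV 0.4 —
(ii) a bimodal IFN-gamma onset-time distribution whose early component is
recovered by cutting at the inter-peak dip (~10 hr) and renormalizing, and
(iii) a normalized cumulative CD25 (IL-2 receptor alpha chain)
upregulation curve fit by a gamma CDF.  This module generates all three
kinds of fixture with known ground truth, so parameter-recovery can be
tested, and real measurements are emulated rather than redistributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .distributions import EmpiricalRT, GammaRT, gamma_from_moments

__all__ = [
    "FixtureSpec",
    "generate_onset_samples",
    "bimodal_mixture_density",
    "truncate_at_dip",
    "cumulative_upregulation_curve",
]

FixtureKind = Literal["onset_samples", "bimodal_mixture", "cumulative_upregulation"]


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one synthetic fixture.

    kinds:
      - ``onset_samples``: n gamma draws with the given mean/CV.
      - ``bimodal_mixture``: n draws from a two-gamma mixture (means, cvs,
        weights), emulating bimodal secretion onset.
      - ``cumulative_upregulation``: noiseless monotone curve, a gamma CDF
        normalized to its maximum on the grid.
    """

    kind: FixtureKind
    means: tuple[float, ...] = (6.3,)
    cvs: tuple[float, ...] = (0.4,)
    weights: tuple[float, ...] = (1.0,)
    n: int = 1000
    seed: int = 0
    t_max: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("onset_samples", "bimodal_mixture",
                             "cumulative_upregulation"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if len(self.means) != len(self.cvs) or len(self.means) != len(self.weights):
            raise ValueError("means, cvs and weights must have equal length")
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def components(self) -> list[GammaRT]:
        return [gamma_from_moments(m, cv) for m, cv in zip(self.means, self.cvs)]


def generate_onset_samples(spec: FixtureSpec) -> tuple[pd.DataFrame, dict]:
    """Seeded samples plus the ground-truth parameter record.

    Returns a one-column DataFrame (``onset_time``) and a dict holding the
    true component laws and weights, for parameter-recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    laws = spec.components
    if spec.kind == "onset_samples":
        if len(laws) != 1:
            raise ValueError("onset_samples takes a single (mean, cv)")
        samples = laws[0].rvs(spec.n, rng)
    elif spec.kind == "bimodal_mixture":
        comp = rng.choice(len(laws), size=spec.n, p=list(spec.weights))
        draws = np.column_stack([law.rvs(spec.n, rng) for law in laws])
        samples = draws[np.arange(spec.n), comp]
    else:
        raise ValueError("cumulative_upregulation has no samples; use "
                         "cumulative_upregulation_curve")
    truth = {
        "components": [law.to_record() for law in laws],
        "weights": list(spec.weights),
        "means": list(spec.means),
        "cvs": list(spec.cvs),
        "seed": spec.seed,
    }
    return pd.DataFrame({"onset_time": samples}), truth


def bimodal_mixture_density(spec: FixtureSpec, n_points: int = 2000
                            ) -> EmpiricalRT:
    """Analytic mixture density on a grid (deterministic fixture)."""
    laws = spec.components
    t_max = spec.t_max
    if t_max is None:
        t_max = max(law.mean + 6.0 * law.sd for law in laws)
    t = np.linspace(0.0, t_max, n_points)
    density = sum(w * law.pdf(t) for w, law in zip(spec.weights, laws))
    return EmpiricalRT(t, density, is_normalized=False).normalized()


def truncate_at_dip(emp: EmpiricalRT, search_window: tuple[float, float]
                    ) -> tuple[EmpiricalRT, float]:
    """Cut a bimodal density at its inter-peak dip and renormalize.

    The dip is the minimum of the density inside ``search_window``; the
    early component is the renormalized density on [0, dip].  Returns the
    truncated density and the dip time.
    """
    lo, hi = search_window
    mask = (emp.times >= lo) & (emp.times <= hi)
    if not mask.any():
        raise ValueError("search window contains no grid points")
    idx = np.flatnonzero(mask)[np.argmin(emp.density[mask])]
    dip_time = float(emp.times[idx])
    truncated = EmpiricalRT(emp.times[: idx + 1], emp.density[: idx + 1],
                            is_normalized=False).normalized()
    return truncated, dip_time


def cumulative_upregulation_curve(mean: float, cv: float,
                                  t_grid: np.ndarray | None = None
                                  ) -> tuple[np.ndarray, np.ndarray, GammaRT]:
    """Monotone upregulation curve normalized to its maximum.

    Emulates a measured receptor-upregulation time course: the cumulative
    curve of a gamma law, scaled so the maximum on the grid is 1.  Returns
    (t, curve, true law).
    """
    law = gamma_from_moments(mean, cv)
    if t_grid is None:
        t_grid = np.linspace(0.0, law.mean + 5.0 * law.sd, 500)
    curve = law.cdf(t_grid)
    curve = curve / curve.max()
    return np.asarray(t_grid, dtype=float), curve, law
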