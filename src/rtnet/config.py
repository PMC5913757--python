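"""YAML network configuration: schema, validation, presets.

A network config describes cell states, gamma-governed transitions (with
optional couplings and branch probabilities), the initial occupancy and a
simulation block.  Example::

    states:
      - {name: S0}
      - {name: Sa, absorbing: true}
    transitions:
      - source: S0
        target: Sa
        law: {family: gamma, mean: 1.0, cv: 0.316}
        coupling: {state: Sa, function: feedback, K: 0.1, eta: 5.0}
        branch_prob: 1.0
    initial: {S0: 1.0}
    simulation: {n_cells: 1000, t_max: 20.0, seed: 1, engine: stochastic}

Laws are given either as (shape, rate) or as (mean, cv).  Validation is
explicit and names the offending field path in every error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .distributions import GammaRT, gamma_from_moments
from .engine import CellState, CommunicationNetwork, Coupling, TransitionSpec

__all__ = ["NetworkConfig", "load_config", "save_config", "PRESETS"]

_STATE_KEYS = {"name", "absorbing"}
_TRANSITION_KEYS = {"source", "target", "law", "coupling", "branch_prob"}
_LAW_KEYS = {"family", "shape", "rate", "mean", "cv"}
_COUPLING_KEYS = {"state", "function", "K", "eta", "beta_base", "pool_fraction"}
_SIM_KEYS = {"n_cells", "t_max", "seed", "engine"}
_TOP_KEYS = {"states", "transitions", "initial", "simulation"}


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field path."""


def _check_keys(mapping: dict, allowed: set, path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")


def _parse_law(raw: dict, path: str) -> GammaRT:
    _check_keys(raw, _LAW_KEYS, path)
    family = raw.get("family", "gamma")
    try:
        if "mean" in raw or "cv" in raw:
            if family == "exponential":
                return GammaRT(shape=1.0, rate=1.0 / float(raw["mean"]))
            return gamma_from_moments(float(raw["mean"]), float(raw["cv"]))
        if family == "exponential":
            return GammaRT(shape=1.0, rate=float(raw["rate"]))
        return GammaRT(shape=float(raw["shape"]), rate=float(raw["rate"]))
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class NetworkConfig:
    """Parsed, validated network configuration."""

    states: list[CellState]
    transitions: list[TransitionSpec]
    initial: dict[str, float]
    n_cells: int = 1000
    t_max: float = 20.0
    seed: int = 0
    engine: str = "stochastic"

    def build(self) -> CommunicationNetwork:
        """Construct (and re-validate) the communication network."""
        return CommunicationNetwork(states=self.states,
                                    transitions=self.transitions,
                                    initial=self.initial)

    def to_dict(self) -> dict:
        states = [{"name": s.name, **({"absorbing": True} if s.is_absorbing else {})}
                  for s in self.states]
        transitions = []
        for tr in self.transitions:
            rec: dict = {"source": tr.source, "target": tr.target,
                         "law": tr.law.to_record()}
            if tr.coupling is not None:
                c = tr.coupling
                rec["coupling"] = {"state": c.state, "function": c.function,
                                   "K": c.K}
                if c.function == "feedback":
                    rec["coupling"]["eta"] = c.eta
                if c.beta_base is not None:
                    rec["coupling"]["beta_base"] = c.beta_base
                if c.pool_fraction != 1.0:
                    rec["coupling"]["pool_fraction"] = c.pool_fraction
            if tr.branch_prob != 1.0:
                rec["branch_prob"] = tr.branch_prob
            transitions.append(rec)
        return {
            "states": states,
            "transitions": transitions,
            "initial": dict(self.initial),
            "simulation": {"n_cells": self.n_cells, "t_max": self.t_max,
                           "seed": self.seed, "engine": self.engine},
        }


def _parse_config(raw: dict) -> NetworkConfig:
    if not isinstance(raw, dict):
        raise ConfigError("top level: expected a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    for key in ("states", "transitions", "initial"):
        if key not in raw:
            raise ConfigError(f"top level: missing required key {key!r}")

    states = []
    for i, s in enumerate(raw["states"]):
        path = f"states[{i}]"
        if isinstance(s, str):
            s = {"name": s}
        _check_keys(s, _STATE_KEYS, path)
        if "name" not in s:
            raise ConfigError(f"{path}: missing name")
        states.append(CellState(name=str(s["name"]),
                                is_absorbing=bool(s.get("absorbing", False))))
    names = {s.name for s in states}

    transitions = []
    for i, t in enumerate(raw["transitions"]):
        path = f"transitions[{i}]"
        _check_keys(t, _TRANSITION_KEYS, path)
        for key in ("source", "target", "law"):
            if key not in t:
                raise ConfigError(f"{path}: missing required key {key!r}")
        for endpoint in ("source", "target"):
            if t[endpoint] not in names:
                raise ConfigError(f"{path}.{endpoint}: unknown state {t[endpoint]!r}")
        law = _parse_law(t["law"], f"{path}.law")
        coupling = None
        if "coupling" in t and t["coupling"] is not None:
            c = t["coupling"]
            cpath = f"{path}.coupling"
            _check_keys(c, _COUPLING_KEYS, cpath)
            if c.get("state") not in names:
                raise ConfigError(f"{cpath}.state: unknown state {c.get('state')!r}")
            try:
                coupling = Coupling(state=c["state"], function=c["function"],
                                    K=float(c["K"]), eta=float(c.get("eta", 1.0)),
                                    beta_base=(float(c["beta_base"])
                                               if "beta_base" in c else None),
                                    pool_fraction=float(c.get("pool_fraction", 1.0)))
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"{cpath}: {exc}") from exc
        transitions.append(TransitionSpec(source=t["source"], target=t["target"],
                                          law=law, coupling=coupling,
                                          branch_prob=float(t.get("branch_prob", 1.0))))

    # per-source branch probability audit with a named state in the error
    by_source: dict[str, float] = {}
    for tr in transitions:
        by_source[tr.source] = by_source.get(tr.source, 0.0) + tr.branch_prob
    for src, total in by_source.items():
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ConfigError(
                f"transitions out of state {src!r}: branch probabilities sum "
                f"to {total:g}, expected 1"
            )

    initial = {str(k): float(v) for k, v in raw["initial"].items()}
    for name in initial:
        if name not in names:
            raise ConfigError(f"initial: unknown state {name!r}")
    if not np.isclose(sum(initial.values()), 1.0, atol=1e-9):
        raise ConfigError(f"initial: fractions sum to {sum(initial.values()):g}, expected 1")

    sim = raw.get("simulation", {}) or {}
    _check_keys(sim, _SIM_KEYS, "simulation")
    engine = sim.get("engine", "stochastic")
    if engine not in ("stochastic", "linear_chain"):
        raise ConfigError(f"simulation.engine: unknown engine {engine!r}")

    cfg = NetworkConfig(states=states, transitions=transitions, initial=initial,
                        n_cells=int(sim.get("n_cells", 1000)),
                        t_max=float(sim.get("t_max", 20.0)),
                        seed=int(sim.get("seed", 0)), engine=engine)
    cfg.build()  # full structural validation
    return cfg


def load_config(path) -> NetworkConfig:
    """Load and validate a YAML network configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    return _parse_config(raw)


def save_config(cfg: NetworkConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


#: Named parameter presets used throughout the package: the motif defaults
#: (shape 10, K = 0.1, unit base rate, feedback fold-changes 5 / 0.2, even
#: feedforward split), the measured onset-time summaries (mean, CV), and
#: the IL-2 receptor model constants for Th and Treg cells.
PRESETS: dict[str, dict] = {
    "motif_defaults": {
        "shape": 10, "K": 0.1, "beta_base": 1.0,
        "eta_positive": 5.0, "eta_negative": 0.2,
        "branch_probs": (0.5, 0.5),
    },
    "il2_onset": {"mean": 6.3, "cv": 0.4, "unit": "hr"},
    "tnfa_onset": {"mean": 3.6, "cv": 0.5, "unit": "hr"},
    "ifng_onset_overall": {"mean": 9.6, "cv": 0.4, "unit": "hr",
                           "note": "bimodal; summary moments only"},
    "il2_receptor_th": {
        "k_on": 112.0, "k_iR": 0.64, "k_off": 0.83, "k_rec": 9.0,
        "k_iC": 1.7, "k_deg": 5.0, "K": 1000.0, "v0": 150.0, "v1": 3000.0,
    },
    "il2_receptor_treg": {
        "k_on": 112.0, "k_iR": 0.64, "k_off": 0.83, "k_rec": 9.0,
        "k_iC": 1.7, "k_deg": 5.0, "K": 1000.0, "v0": 1000.0, "v1": 8000.0,
    },
    "il2_milieu": {
        "D_um2_per_s": 10.0, "rho_um": 5.0, "volume_ul": 1.0,
        "R_th": 1000.0, "R_treg": 2000.0,
    },
}
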