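"""Computational experiments on fitted cluster models.

Three experiment families probe how robust the fitted dynamics are:

* assumption scaling — re-estimate under down/up-scaled assumption
  relations (0.2x / 5x) and compare cancer trajectories and their
  saturation times;
* perturbation envelopes — pointwise min/max cancer trajectories under
  independent multiplicative perturbation of the sensitive parameters;
* initial-condition sweeps — simulate a cluster's parameters from many
  patient initial states and measure the spread of the terminal states.

"Time of reaching steady state" is operationalized as the first time the
cancer trajectory enters — and stays within — 5% of its terminal value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import (
    AssumptionSet,
    EstimationFailure,
    EstimationOptions,
    KnownDeathRates,
    apply_scale,
    default_assumptions,
    default_known_rates,
    estimate,
)
from .ode import Trajectory, simulate
from .profiles import ClusterProfile
from .state import PARAM_INDEX, STATE_INDEX, ParameterSet, SimulationConfig

__all__ = [
    "AssumptionScan",
    "Envelope",
    "SweepReport",
    "initial_condition_sweep",
    "perturbation_envelope",
    "scan_assumptions",
    "time_to_steady",
]

C_IDX = STATE_INDEX["C"]


def time_to_steady(traj: Trajectory, band: float = 0.05,
                   variable: str = "C") -> float:
    """First time the trajectory enters and remains within ``band`` of its
    terminal value."""
    i = STATE_INDEX[variable]
    y = traj.states[:, i]
    terminal = y[-1]
    tol = band * abs(terminal) if terminal != 0 else band
    outside = np.abs(y - terminal) > tol
    if not outside.any():
        return float(traj.time[0])
    last_out = np.max(np.nonzero(outside)[0])
    if last_out + 1 >= len(y):
        return float("inf")
    return float(traj.time[last_out + 1])


@dataclass
class AssumptionScan:
    """Trajectories and saturation times over (cluster, relation, scale)."""

    runs: pd.DataFrame               # cluster, label, scale, t95, final_C, ok
    trajectories: dict[tuple[str, str, float], Trajectory]
    failures: list[tuple[str, str, float, str]] = field(default_factory=list)

    def time_to_steady(self, cluster: str, label: str, scale: float) -> float:
        row = self.runs[
            (self.runs.cluster == str(cluster))
            & (self.runs.label == label)
            & (self.runs.scale == scale)
        ]
        return float(row["t95"].iloc[0])


def scan_assumptions(
    profiles: list[ClusterProfile],
    labels: tuple[str, ...] = ("kill_split_tc_vs_ifng", "death_split_natural_vs_ifng", "growth_split_adipocyte_vs_il6", "m_act_ifng_vs_il10", "m_act_estrogen_vs_il10", "m_act_th_vs_il10"),
    scales: tuple[float, ...] = (0.2, 1.0, 5.0),
    *,
    assumptions: AssumptionSet | None = None,
    known: KnownDeathRates | None = None,
    options: EstimationOptions | None = None,
    cfg: SimulationConfig | None = None,
) -> AssumptionScan:
    """Re-estimate and re-simulate every (cluster, relation, scale) combination.

    Estimation failures flag the combination and the scan continues.
    """
    assumptions = assumptions if assumptions is not None else default_assumptions()
    known = known or default_known_rates()
    cfg = cfg or SimulationConfig()
    rows = []
    trajs: dict[tuple[str, str, float], Trajectory] = {}
    failures = []
    for profile in profiles:
        for label in labels:
            for scale in scales:
                key = (str(profile.cluster), label, float(scale))
                try:
                    rep = estimate(profile, apply_scale(assumptions, label, scale),
                                   known, options)
                    traj = simulate(rep.params, profile.initial.values, cfg,
                                    require_convergence=True)
                except EstimationFailure as exc:
                    failures.append((*key, str(exc)))
                    rows.append((*key, np.nan, np.nan, False))
                    continue
                trajs[key] = traj
                rows.append((*key, time_to_steady(traj),
                             float(traj.final_state[C_IDX]), True))
    runs = pd.DataFrame(
        rows, columns=["cluster", "label", "scale", "t95", "final_C", "ok"]
    )
    return AssumptionScan(runs, trajs, failures)


@dataclass
class Envelope:
    time: np.ndarray
    base: np.ndarray        # base cancer trajectory
    lower: np.ndarray
    upper: np.ndarray
    draws: int
    fraction: float
    perturbed: tuple[str, ...]

    def contains_base(self) -> bool:
        return bool(
            np.all(self.lower <= self.base + 1e-9 * np.abs(self.base))
            and np.all(self.upper >= self.base - 1e-9 * np.abs(self.base))
        )


def perturbation_envelope(
    params: ParameterSet,
    init,
    sensitive: list[str],
    fraction: float = 0.10,
    n_draws: int = 200,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
) -> Envelope:
    """Pointwise min/max cancer trajectory under multiplicative perturbation.

    Each listed parameter is independently scaled by a factor drawn
    uniformly from [1 - fraction, 1 + fraction] for every draw.
    """
    if n_draws < 2:
        raise ValueError("at least 2 draws are required")
    for name in sensitive:
        if name not in PARAM_INDEX:
            raise KeyError(f"unknown parameter {name!r}")
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    base = simulate(params, init, cfg)
    c_base = base.states[:, C_IDX]
    lower = c_base.copy()
    upper = c_base.copy()
    for _ in range(n_draws):
        factors = rng.uniform(1.0 - fraction, 1.0 + fraction, size=len(sensitive))
        perturbed = params.replace(**{
            name: params[name] * f for name, f in zip(sensitive, factors)
        })
        traj = simulate(perturbed, init, cfg)
        c = np.interp(base.time, traj.time, traj.states[:, C_IDX])
        lower = np.minimum(lower, c)
        upper = np.maximum(upper, c)
    return Envelope(base.time.copy(), c_base, lower, upper,
                    n_draws, fraction, tuple(sensitive))


@dataclass
class SweepReport:
    terminal: pd.DataFrame          # one row per initial state (17 columns)
    spread: float                   # max pairwise relative distance
    converged: pd.Series

    def max_relative_spread(self) -> float:
        return self.spread


def initial_condition_sweep(
    params: ParameterSet,
    initial_states,
    cfg: SimulationConfig | None = None,
) -> SweepReport:
    """Simulate one parameter set from many initial states.

    Reports terminal states, convergence flags and the maximum pairwise
    relative spread of the terminal states (infinity-norm over variables,
    relative to the mean terminal value of each variable).
    """
    initial_states = list(initial_states)
    if len(initial_states) < 2:
        raise ValueError("at least 2 initial states are required")
    cfg = cfg or SimulationConfig()
    finals, flags = [], []
    for x0 in initial_states:
        traj = simulate(params, x0, cfg, require_convergence=True)
        finals.append(traj.final_state)
        flags.append(traj.converged)
    F = np.array(finals)
    mean = F.mean(axis=0)
    mean[mean == 0] = 1.0
    rel = F / mean
    spread = float(np.max(rel.max(axis=0) - rel.min(axis=0)))
    from .state import STATE_NAMES
    return SweepReport(
        pd.DataFrame(F, columns=list(STATE_NAMES)),
        spread,
        pd.Series(flags, name="converged"),
    )
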