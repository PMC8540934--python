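"""Model/Results interface over the estimation and analysis machinery.

Typical use mirrors statsmodels: construct a model from data, fit it,
inspect the results object.

>>> from tme import TumorImmuneModel
>>> model = TumorImmuneModel.from_cluster("1")       # reference profile
>>> res = model.fit()
>>> print(res.summary())                             # estimates, diagnostics
>>> traj = res.simulate(require_convergence=True)    # dynamics from X0
>>> report = res.global_sensitivity(n_nodes=33)      # ranked parameters
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bifurcation as _bif
from . import sensitivity as _sens
from .clustering import extract_profiles
from .estimation import (
    AssumptionSet,
    EstimationOptions,
    EstimationReport,
    KnownDeathRates,
    default_assumptions,
    default_known_rates,
    estimate,
)
from .ode import (
    Trajectory,
    nondimensionalize,
    simulate,
    steady_state_residual,
    total_cells,
)
from .profiles import ClusterProfile, study_profiles
from .state import PARAM_NAMES, ParameterSet, SimulationConfig

__all__ = ["TumorImmuneModel", "TumorImmuneResults"]


class TumorImmuneModel:
    """A cluster-specific tumor–immune ODE model to be fitted to a
    steady-state profile.

    Parameters
    ----------
    profile
        The cluster profile supplying initial conditions, the steady-state
        constraint and scale maxima.
    assumptions, known_rates, options
        Estimation configuration; package defaults when omitted.
    """

    def __init__(
        self,
        profile: ClusterProfile,
        assumptions: AssumptionSet | None = None,
        known_rates: KnownDeathRates | None = None,
        options: EstimationOptions | None = None,
    ) -> None:
        self.profile = profile
        self.assumptions = assumptions if assumptions is not None else default_assumptions()
        self.known_rates = known_rates or default_known_rates()
        self.options = options or EstimationOptions()

    @classmethod
    def from_cluster(cls, cluster: str | int = "1", **kwargs) -> "TumorImmuneModel":
        """Build from one of the five shipped reference cluster profiles."""
        for profile in study_profiles():
            if profile.cluster == str(cluster):
                return cls(profile, **kwargs)
        raise KeyError(f"no reference cluster {cluster!r} (available: 1-5)")

    @classmethod
    def from_cohort(
        cls,
        states: pd.DataFrame,
        labels,
        cluster: str | int,
        small_pct: float = 10.0,
        large_pct: float = 90.0,
        **kwargs,
    ) -> "TumorImmuneModel":
        """Build from a clustered cohort of per-patient model states."""
        profiles = extract_profiles(states, labels, small_pct, large_pct)
        for profile in profiles:
            if profile.cluster == str(cluster):
                return cls(profile, **kwargs)
        raise KeyError(f"cluster {cluster!r} not present in labels")

    def fit(self) -> "TumorImmuneResults":
        report = estimate(self.profile, self.assumptions, self.known_rates,
                          self.options)
        return TumorImmuneResults(self, report)

    def scaled(self, label: str, factor: float) -> "TumorImmuneModel":
        """A copy of the model with one assumption relation rescaled."""
        return TumorImmuneModel(
            self.profile, self.assumptions.scaled(label, factor),
            self.known_rates, self.options,
        )


@dataclass
class TumorImmuneResults:
    """Fitted parameters plus diagnostics, simulation and analysis."""

    model: TumorImmuneModel
    report: EstimationReport

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> ParameterSet:
        return self.report.params

    @property
    def profile(self) -> ClusterProfile:
        return self.model.profile

    @property
    def residual(self) -> float:
        return self.report.residual

    def fixed_point_residual(self) -> float:
        """||F(X_inf, theta)|| / ||X_inf|| of the fitted set."""
        return steady_state_residual(self.profile.steady.values, self.params)

    def nondimensional_params(self) -> ParameterSet:
        return nondimensionalize(self.params, self.profile.scale_max.values)

    # -- simulation --------------------------------------------------------
    def simulate(
        self,
        init=None,
        cfg: SimulationConfig | None = None,
        *,
        require_convergence: bool = False,
    ) -> Trajectory:
        """Integrate the fitted system (default: from the profile's initial
        conditions)."""
        x0 = self.profile.initial.values if init is None else init
        return simulate(self.params, x0, cfg,
                        require_convergence=require_convergence)

    # -- sensitivity -------------------------------------------------------
    def local_sensitivity(self, *, nondimensional: bool = True) -> np.ndarray:
        return _sens.local_sensitivity(
            self.params, self.profile.steady.values,
            nondimensional=nondimensional,
        )

    def global_sensitivity(
        self,
        labels: tuple[str, ...] | None = None,
        n_nodes: int = 33,
        measure: str = "arc_length",
    ) -> "_sens.SensitivityReport":
        labels = labels or ("kill_split_tc_vs_ifng", "death_split_natural_vs_ifng", "growth_split_adipocyte_vs_il6", "m_act_ifng_vs_il10", "m_act_estrogen_vs_il10", "m_act_th_vs_il10")
        neighborhoods = [
            _sens.neighborhood_integral(
                self.profile, label,
                assumptions=self.model.assumptions,
                known=self.model.known_rates,
                options=self.model.options,
                n_nodes=n_nodes,
                measure=measure,
                base_params=self.params,
            )
            for label in labels
        ]
        return _sens.global_sensitivity(
            neighborhoods, self.params, self.profile,
            metadata={"n_nodes_requested": n_nodes},
        )

    # -- bifurcation -------------------------------------------------------
    def frozen_states(self) -> dict[str, float]:
        ss = self.profile.steady
        return {k: ss[k] for k in ("IL6", "A", "Tc", "Ig")}

    def bifurcation(self, param: str, grid=None) -> "_bif.BifurcationCurve":
        return _bif.cancer_equilibria(self.params, self.frozen_states(),
                                      param, grid)

    def threshold(self, param: str) -> float | None:
        return _bif.threshold(self.params, self.frozen_states(), param)

    # -- presentation ------------------------------------------------------
    def summary(self, top: int = 12) -> str:
        """Plain-text summary of the fit."""
        p = self.params
        prov = pd.Series(p.provenance)
        counts = prov.value_counts()
        ss = self.profile.steady
        lines = [
            "Tumor-immune steady-state model",
            "=" * 64,
            f"cluster:               {self.profile.cluster}",
            f"solve mode:            {self.report.mode}",
            f"system rank:           {self.report.rank}",
            f"linear residual:       {self.report.residual:.3e}",
            f"fixed-point residual:  {self.fixed_point_residual():.3e}",
            f"parameters:            {len(PARAM_NAMES)} "
            f"({counts.get('estimated', 0)} estimated, "
            f"{counts.get('half_life', 0)} half-life, "
            f"{counts.get('configured', 0)} configured)",
            f"steady-state cancer:   {ss['C']:.4g} cells",
            f"steady-state total:    {total_cells(ss.values):.4g} cells",
            "-" * 64,
            f"{'parameter':<16}{'value':>14}  provenance",
        ]
        shown = [
            "lambda_C", "lambda_CIL6", "lambda_CA",
            "delta_CTc", "delta_CIg", "delta_C",
            "lambda_A", "delta_A", "alpha_NC", "C0", "A0", "E0",
        ][:top]
        for name in shown:
            lines.append(
                f"{name:<16}{p[name]:>14.6g}  {p.provenance.get(name, '-')}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)
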