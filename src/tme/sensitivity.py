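"""Steady-state sensitivity analysis.

Local sensitivities follow from implicit differentiation of F(X*, theta) = 0:

    s = dX*/dtheta = -(dF/dX)^{-1} (dF/dtheta),

with both Jacobians evaluated analytically from the term table of the ODE
system.  Global sensitivities aggregate the local ones over neighborhoods
generated by rescaling each assumption relation of the estimation: for
every quadrature node on a log-spaced scale grid the parameters are
re-estimated (the steady state stays pinned to the cluster data), the
local sensitivity is recomputed, and the neighborhood integral

    S_ik = int_{Omega_k} s_i(theta) dtheta

is evaluated as a line integral along the induced parameter path (the
plain scale measure is available via ``measure='scale'``).  Neighborhood
weights decrease with the relative distance of the re-estimated set from
the base set, w ~ exp(-d), normalized per parameter; the global index is
S_i = sum_k w_ik S_ik.

For numerical conditioning all of this runs on the nondimensionalized
system (states divided by their scale maxima); dimensional local
sensitivities are available from the same objects.
"""

from __future__ import annotations

import warnings
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
from .ode import (
    parameter_jacobian,
    scale_factors,
    state_jacobian,
    steady_state_residual,
    total_cells_gradient,
)
from .profiles import ClusterProfile
from .state import PARAM_NAMES, STATE_INDEX, ParameterSet

__all__ = [
    "NeighborhoodIntegral",
    "SensitivityReport",
    "gauss_legendre_nodes",
    "global_sensitivity",
    "local_sensitivity",
    "neighborhood_integral",
    "output_sensitivities",
]

OUTPUTS = ("cancer", "total_cells")


def local_sensitivity(
    params: ParameterSet,
    x_star,
    *,
    nondimensional: bool = False,
    residual_tol: float = 1e-6,
    cond_max: float = 1e12,
) -> np.ndarray:
    """Sensitivity matrix dX*/dtheta (17 x 75) at a steady state.

    With ``nondimensional=True`` the matrix refers to the rescaled states
    and rates (using ``params.scales``).
    """
    x = np.asarray(x_star, dtype=float)
    res = steady_state_residual(x, params)
    if res > residual_tol:
        raise ValueError(
            f"x_star is not a steady state of params (relative residual {res:.2e})"
        )
    J = state_jacobian(x, params)
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > cond_max:
        raise np.linalg.LinAlgError(
            f"state Jacobian is numerically singular (condition number {cond:.2e})"
        )
    Jp = parameter_jacobian(x, params)
    s = -np.linalg.solve(J, Jp)
    if nondimensional:
        scales = params.scales
        if scales is None:
            raise ValueError("parameter set carries no scale maxima")
        f = scale_factors(scales)
        s = s / scales[:, None] / f[None, :]
    return s


def output_sensitivities(s: np.ndarray) -> dict[str, np.ndarray]:
    """Rows of interest: the cancer steady state and total cells."""
    return {
        "cancer": s[STATE_INDEX["C"]].copy(),
        "total_cells": total_cells_gradient() @ s,
    }


def gauss_legendre_nodes(a: float, b: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre nodes/weights on [a, b]."""
    xs, ws = np.polynomial.legendre.leggauss(int(n))
    return 0.5 * (b - a) * xs + 0.5 * (a + b), 0.5 * (b - a) * ws


@dataclass
class NeighborhoodIntegral:
    """Integrated sensitivities over one assumption-scaling neighborhood."""

    label: str
    scales: np.ndarray                        # retained quadrature nodes
    S: dict[str, np.ndarray]                  # output -> per-parameter S_ik (75)
    distance: float                           # mean relative distance to base
    measure: str
    skipped: list[float] = field(default_factory=list)


def neighborhood_integral(
    profile: ClusterProfile,
    label: str,
    *,
    assumptions: AssumptionSet | None = None,
    known: KnownDeathRates | None = None,
    options: EstimationOptions | None = None,
    scale_range: tuple[float, float] = (0.01, 100.0),
    n_nodes: int = 33,
    measure: str = "arc_length",
    base_params: ParameterSet | None = None,
) -> NeighborhoodIntegral:
    """Re-estimate along one assumption's scale grid and integrate s_i.

    Nodes are Gauss–Legendre on log10(scale) over ``scale_range``.  A node
    whose re-estimation fails is skipped with a warning.
    """
    if measure not in ("arc_length", "scale"):
        raise ValueError("measure must be 'arc_length' or 'scale'")
    assumptions = assumptions if assumptions is not None else default_assumptions()
    known = known or default_known_rates()
    options = options or EstimationOptions()
    if base_params is None:
        base_params = estimate(profile, assumptions, known, options).params
    scales_vec = profile.scale_max.values
    f = scale_factors(scales_vec)
    base_nd = base_params.values * f
    base_norm = np.linalg.norm(base_nd)

    lo, hi = np.log10(scale_range[0]), np.log10(scale_range[1])
    nodes, weights = gauss_legendre_nodes(lo, hi, n_nodes)

    x_star = profile.steady.values
    sens: list[dict[str, np.ndarray] | None] = []
    thetas: list[np.ndarray | None] = []
    skipped: list[float] = []
    for u in nodes:
        factor = 10.0 ** u
        try:
            rep = estimate(profile, apply_scale(assumptions, label, factor),
                           known, options)
            s = local_sensitivity(rep.params, x_star, nondimensional=True)
            sens.append(output_sensitivities(s))
            thetas.append(rep.params.values * f)
        except (EstimationFailure, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"neighborhood {label!r}: node scale={factor:.3g} skipped ({exc})",
                RuntimeWarning,
                stacklevel=2,
            )
            sens.append(None)
            thetas.append(None)
            skipped.append(factor)

    keep = [i for i, s in enumerate(sens) if s is not None]
    if not keep:
        raise EstimationFailure(
            f"every node of neighborhood {label!r} failed", float("nan")
        )
    # measure along the integration variable: either the arc length of the
    # induced nondimensional parameter path, or the log10-scale coordinate.
    if measure == "arc_length":
        theta_arr = np.array([thetas[i] for i in keep])
        u_kept = nodes[keep]
        speed = np.gradient(theta_arr, u_kept, axis=0)
        dmeasure = np.linalg.norm(speed, axis=1)
    else:
        dmeasure = np.ones(len(keep))

    S = {out: np.zeros(len(PARAM_NAMES)) for out in OUTPUTS}
    for out in OUTPUTS:
        vals = np.array([sens[i][out] for i in keep])
        S[out] = np.einsum("q,q,qp->p", weights[keep], dmeasure, vals)
    dist = float(np.mean([
        np.linalg.norm(thetas[i] - base_nd) / base_norm for i in keep
    ]))
    return NeighborhoodIntegral(label, 10.0 ** nodes[keep], S, dist, measure, skipped)


@dataclass
class SensitivityReport:
    """Local and weighted-global steady-state sensitivities."""

    cluster: str
    local: dict[str, np.ndarray]              # output -> s_i at base (75)
    global_: dict[str, np.ndarray]            # output -> S_i (75)
    weights: dict[str, np.ndarray]            # neighborhood weights per output
    neighborhoods: list[NeighborhoodIntegral]
    metadata: dict

    def table(self, output: str = "cancer") -> pd.DataFrame:
        df = pd.DataFrame({
            "parameter": PARAM_NAMES,
            "output": output,
            "local": self.local[output],
            "global": self.global_[output],
        })
        df["rank"] = (-df["global"].abs()).rank(method="first").astype(int)
        return df.sort_values("rank").reset_index(drop=True)

    def top(self, n: int = 10, output: str = "cancer") -> list[str]:
        return self.table(output)["parameter"].head(n).tolist()

    def to_csv(self, path) -> None:
        pd.concat([self.table(o) for o in OUTPUTS]).to_csv(path, index=False)


def global_sensitivity(
    neighborhoods: list[NeighborhoodIntegral],
    base_params: ParameterSet,
    profile: ClusterProfile,
    *,
    metadata: dict | None = None,
) -> SensitivityReport:
    """Aggregate neighborhood integrals with distance-decaying weights."""
    if not neighborhoods:
        raise ValueError("at least one neighborhood is required")
    raw = np.array([np.exp(-nb.distance) for nb in neighborhoods])
    if np.all(raw == 0):
        raise ValueError("all neighborhood weights vanished")
    w = raw / raw.sum()

    s_local = local_sensitivity(base_params, profile.steady.values,
                                nondimensional=True)
    local = output_sensitivities(s_local)
    global_ = {
        out: np.sum([wk * nb.S[out] for wk, nb in zip(w, neighborhoods)], axis=0)
        for out in OUTPUTS
    }
    weights = {out: w.copy() for out in OUTPUTS}
    meta = {
        "neighborhood_labels": [nb.label for nb in neighborhoods],
        "measure": neighborhoods[0].measure,
        "n_nodes": [len(nb.scales) for nb in neighborhoods],
    }
    meta.update(metadata or {})
    return SensitivityReport(
        cluster=str(profile.cluster),
        local=local,
        global_=global_,
        weights=weights,
        neighborhoods=neighborhoods,
        metadata=meta,
    )
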