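"""The 17-equation tumor–immune ODE system.

Every equation is mass-action or logistic.  The right-hand side is defined
once, as a table of signed product terms, and everything else — derivative
evaluation, the analytic state and parameter Jacobians used by the
sensitivity analysis, and the steady-state rows used by the parameter
estimation — is generated from that table, so the three views can never
drift apart.

A term is ``sign * (prod of parameters) * (prod of state factors) *
(1 - x/capacity)``; the logistic factor is only present for the cancer,
adipocyte and estrogen self-renewal terms.  Naive-pool equations (naive
T cells, naive dendritic cells, naive macrophages) lose exactly the flux
that the corresponding activated pools gain, which keeps the activation
bounded without extra nonlinearities.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .state import (
    CAPACITY_NAMES,
    PARAM_INDEX,
    PARAM_NAMES,
    STATE_INDEX,
    STATE_NAMES,
    ModelState,
    ParameterSet,
    SimulationConfig,
)


@dataclass(frozen=True)
class Term:
    """One signed product term of a single equation."""

    eq: str                      # state variable whose derivative it feeds
    sign: float                  # +1 gain, -1 loss
    params: tuple[str, ...]      # parameter factors (product)
    states: tuple[str, ...]      # state factors (product)
    logistic: tuple[str, str] | None = None   # (state, capacity parameter)


def _activation(group: str, pairs: list[tuple[str, str]]) -> list[Term]:
    """Gain terms for an activated pool plus matching naive-pool losses."""
    naive = {"Th": "TN", "Tc": "TN", "Tr": "TN", "D": "DN", "M": "MN"}[group]
    terms = []
    for param, stimulus in pairs:
        terms.append(Term(group, +1.0, (param,), (stimulus, naive)))
        terms.append(Term(naive, -1.0, (param,), (stimulus, naive)))
    return terms


def _build_terms() -> tuple[Term, ...]:
    t: list[Term] = []
    # --- T cells -----------------------------------------------------------
    t += _activation("Th", [("lambda_ThH", "H"), ("lambda_ThD", "D"),
                            ("lambda_ThIL12", "IL12"), ("lambda_ThE", "E")])
    t += [Term("Th", -1, ("delta_ThTr",), ("Tr", "Th")),
          Term("Th", -1, ("delta_ThIL10",), ("IL10", "Th")),
          Term("Th", -1, ("delta_Th",), ("Th",))]
    t += _activation("Tc", [("lambda_TcE", "E"), ("lambda_TcD", "D"),
                            ("lambda_TcIL12", "IL12")])
    t += [Term("Tc", -1, ("delta_TcTr",), ("Tr", "Tc")),
          Term("Tc", -1, ("delta_TcIL10",), ("IL10", "Tc")),
          Term("Tc", -1, ("delta_Tc",), ("Tc",))]
    t += _activation("Tr", [("lambda_TrD", "D"), ("lambda_TrE", "E")])
    t += [Term("Tr", -1, ("delta_Tr",), ("Tr",))]
    t += [Term("TN", +1, ("A_TN",), ()),
          Term("TN", -1, ("delta_TN",), ("TN",))]
    # --- Dendritic cells ---------------------------------------------------
    t += _activation("D", [("lambda_DC", "C"), ("lambda_DH", "H"),
                           ("lambda_DE", "E")])
    t += [Term("D", -1, ("delta_DC",), ("C", "D")),
          Term("D", -1, ("delta_D",), ("D",)),
          Term("DN", +1, ("A_DN",), ()),
          Term("DN", -1, ("delta_DN",), ("DN",))]
    # --- Macrophages -------------------------------------------------------
    t += _activation("M", [("lambda_MIL10", "IL10"), ("lambda_MIg", "Ig"),
                           ("lambda_MIL12", "IL12"), ("lambda_MTh", "Th"),
                           ("lambda_ME", "E")])
    t += [Term("M", -1, ("delta_M",), ("M",)),
          Term("MN", +1, ("A_M",), ()),
          Term("MN", -1, ("delta_MN",), ("MN",))]
    # --- Cancer, adipocytes, necrosis -------------------------------------
    t += [Term("C", +1, ("lambda_C",), ("C",), ("C", "C0")),
          Term("C", +1, ("lambda_CIL6",), ("IL6", "C"), ("C", "C0")),
          Term("C", +1, ("lambda_CA",), ("A", "C"), ("C", "C0")),
          Term("C", -1, ("delta_CTc",), ("Tc", "C")),
          Term("C", -1, ("delta_CIg",), ("Ig", "C")),
          Term("C", -1, ("delta_C",), ("C",))]
    t += [Term("A", +1, ("lambda_A",), ("A",), ("A", "A0")),
          Term("A", -1, ("delta_A",), ("A",))]
    t += [Term("N", +1, ("alpha_NC", "delta_CIg"), ("Ig", "C")),
          Term("N", +1, ("alpha_NC", "delta_CTc"), ("Tc", "C")),
          Term("N", +1, ("alpha_NC", "delta_C"), ("C",)),
          Term("N", -1, ("delta_N",), ("N",))]
    # --- Molecules ---------------------------------------------------------
    for src, pairs in [
        ("H", [("lambda_HD", "D"), ("lambda_HN", "N"), ("lambda_HM", "M"),
               ("lambda_HTc", "Tc"), ("lambda_HC", "C")]),
        ("IL12", [("lambda_IL12M", "M"), ("lambda_IL12D", "D"),
                  ("lambda_IL12Th", "Th"), ("lambda_IL12Tc", "Tc")]),
        ("IL10", [("lambda_IL10M", "M"), ("lambda_IL10D", "D"),
                  ("lambda_IL10Tr", "Tr"), ("lambda_IL10Th", "Th"),
                  ("lambda_IL10Tc", "Tc"), ("lambda_IL10C", "C")]),
        ("IL6", [("lambda_IL6A", "A"), ("lambda_IL6M", "M"),
                 ("lambda_IL6D", "D")]),
    ]:
        for param, producer in pairs:
            t.append(Term(src, +1, (param,), (producer,)))
        t.append(Term(src, -1, (f"delta_{src}",), (src,)))
    t += [Term("E", +1, ("lambda_EA",), ("A",)),
          Term("E", +1, ("lambda_E",), ("E",), ("E", "E0")),
          Term("E", -1, ("delta_E",), ("E",)),
          Term("Ig", +1, ("lambda_IgTc",), ("Tc",)),
          Term("Ig", +1, ("lambda_IgTh",), ("Th",)),
          Term("Ig", +1, ("lambda_IgD",), ("E", "D")),
          Term("Ig", -1, ("delta_Ig",), ("Ig",))]
    return tuple(t)


TERMS: tuple[Term, ...] = _build_terms()

#: Weights of Total Cells: tumor-infiltrating pools count fully, naive
#: macrophages at 20% (the fraction retained before polarization), and naive
#: T cells not at all (they reside in circulation and lymph nodes).
TOTAL_CELL_WEIGHTS: dict[str, float] = {
    "Th": 1.0, "Tc": 1.0, "Tr": 1.0, "DN": 1.0, "D": 1.0,
    "MN": 0.2, "M": 1.0, "C": 1.0, "N": 1.0, "A": 1.0,
}

#: For each rate parameter, the equation whose gain/loss it primarily
#: parameterizes (used to define the nondimensional scaling of shared
#: activation rates, which also appear in the naive-pool equations).
_PRIMARY_EQ: dict[str, Term] = {}
for _term in TERMS:
    name = _term.params[-1]
    if name not in _PRIMARY_EQ or _term.eq not in ("TN", "DN", "MN"):
        if name in _PRIMARY_EQ and _PRIMARY_EQ[name].eq not in ("TN", "DN", "MN"):
            continue
        _PRIMARY_EQ[name] = _term


def _as_array(state) -> np.ndarray:
    if isinstance(state, ModelState):
        return state.values
    arr = np.asarray(state, dtype=float)
    if arr.shape != (17,):
        raise ValueError("state must have 17 entries")
    return arr


def _dimensional(params: ParameterSet) -> ParameterSet:
    if params.nondimensional:
        return dimensionalize(params, params.scales)
    return params


def rhs(state, params: ParameterSet, *, check: bool = True) -> np.ndarray:
    """Evaluate the 17 time derivatives (state units per day).

    For a nondimensional parameter set the derivative of the rescaled system
    is returned (states are then expected in rescaled units).
    """
    x = _as_array(state)
    if check:
        if np.any(x < 0):
            raise ValueError("state contains negative entries")
        if not np.all(np.isfinite(params.values)):
            raise ValueError("parameter set contains non-finite values")
    if params.nondimensional:
        scales = params.scales
        dim = dimensionalize(params, scales)
        return rhs(x * scales, dim, check=False) / scales
    p = params.values
    dx = np.zeros(17)
    for term in TERMS:
        val = term.sign
        for name in term.params:
            val *= p[PARAM_INDEX[name]]
        for name in term.states:
            val *= x[STATE_INDEX[name]]
        if term.logistic is not None:
            sname, cap = term.logistic
            val *= 1.0 - x[STATE_INDEX[sname]] / p[PARAM_INDEX[cap]]
        dx[STATE_INDEX[term.eq]] += val
    return dx


def state_jacobian(state, params: ParameterSet) -> np.ndarray:
    """Analytic Jacobian dF/dx (17 x 17)."""
    params = _dimensional(params)
    x = _as_array(state)
    p = params.values
    J = np.zeros((17, 17))
    for term in TERMS:
        coef = term.sign
        for name in term.params:
            coef *= p[PARAM_INDEX[name]]
        i = STATE_INDEX[term.eq]
        svals = [x[STATE_INDEX[s]] for s in term.states]
        logi = 1.0
        if term.logistic is not None:
            sname, cap = term.logistic
            logi = 1.0 - x[STATE_INDEX[sname]] / p[PARAM_INDEX[cap]]
        for k, s in enumerate(term.states):
            prod = coef * logi
            for k2, v in enumerate(svals):
                if k2 != k:
                    prod *= v
            J[i, STATE_INDEX[s]] += prod
        if term.logistic is not None:
            sname, cap = term.logistic
            prod = -coef / p[PARAM_INDEX[cap]]
            for v in svals:
                prod *= v
            J[i, STATE_INDEX[sname]] += prod
    return J


def parameter_jacobian(state, params: ParameterSet) -> np.ndarray:
    """Analytic Jacobian dF/dtheta (17 x 75), canonical parameter order."""
    params = _dimensional(params)
    x = _as_array(state)
    p = params.values
    J = np.zeros((17, 75))
    for term in TERMS:
        i = STATE_INDEX[term.eq]
        sprod = term.sign
        for s in term.states:
            sprod *= x[STATE_INDEX[s]]
        logi = 1.0
        if term.logistic is not None:
            sname, cap = term.logistic
            logi = 1.0 - x[STATE_INDEX[sname]] / p[PARAM_INDEX[cap]]
        pvals = [p[PARAM_INDEX[n]] for n in term.params]
        for k, name in enumerate(term.params):
            prod = sprod * logi
            for k2, v in enumerate(pvals):
                if k2 != k:
                    prod *= v
            J[i, PARAM_INDEX[name]] += prod
        if term.logistic is not None:
            sname, cap = term.logistic
            prod = sprod * x[STATE_INDEX[sname]] / p[PARAM_INDEX[cap]] ** 2
            for v in pvals:
                prod *= v
            J[i, PARAM_INDEX[cap]] += prod
    return J


def total_cells(state) -> float:
    """Total cells: Th + Tc + Tr + DN + D + 0.2 MN + M + C + N + A."""
    x = _as_array(state)
    return float(sum(w * x[STATE_INDEX[s]] for s, w in TOTAL_CELL_WEIGHTS.items()))


def total_cells_gradient() -> np.ndarray:
    g = np.zeros(17)
    for s, w in TOTAL_CELL_WEIGHTS.items():
        g[STATE_INDEX[s]] = w
    return g


# ---------------------------------------------------------------------------
# Nondimensionalization: each variable is divided by its scale maximum, time
# stays in days.  A rate whose term reads  p * (prod states) feeding equation
# ``eq`` rescales as  p' = p * (prod scales of states) / scale(eq); for the
# activation rates shared between an activated pool and its naive pool the
# activated pool's equation defines the scaling, and the rescaled system
# accounts for the ratio when evaluating the naive-pool loss.
# ---------------------------------------------------------------------------

def _scale_factor(name: str, scales: np.ndarray) -> float:
    if name in CAPACITY_NAMES:
        target = {"C0": "C", "A0": "A", "E0": "E"}[name]
        return 1.0 / scales[STATE_INDEX[target]]
    if name == "alpha_NC":
        return scales[STATE_INDEX["C"]] / scales[STATE_INDEX["N"]]
    term = _PRIMARY_EQ[name]
    fac = 1.0 / scales[STATE_INDEX[term.eq]]
    for s in term.states:
        fac *= scales[STATE_INDEX[s]]
    return fac


def scale_factors(scales) -> np.ndarray:
    """Multiplicative factor per parameter: theta_nondim = theta * factor."""
    scales = np.asarray(scales, dtype=float)
    if scales.shape != (17,) or np.any(scales <= 0):
        raise ValueError("17 strictly positive scale maxima are required")
    return np.array([_scale_factor(n, scales) for n in PARAM_NAMES])


def nondimensionalize(params: ParameterSet, scales) -> ParameterSet:
    """Rescale a dimensional parameter set by per-variable scale maxima."""
    if params.nondimensional:
        raise ValueError("parameter set is already nondimensional")
    scales = np.asarray(scales, dtype=float)
    if scales.shape != (17,):
        raise ValueError("17 scale maxima are required")
    if np.any(scales <= 0):
        raise ValueError("scale maxima must be strictly positive")
    values = params.values.copy()
    for name in PARAM_NAMES:
        values[PARAM_INDEX[name]] *= _scale_factor(name, scales)
    return ParameterSet(values, params.provenance, params.cluster,
                        nondimensional=True, scales=scales)


def dimensionalize(params: ParameterSet, scales=None) -> ParameterSet:
    """Inverse of :func:`nondimensionalize`."""
    if not params.nondimensional:
        raise ValueError("parameter set is already dimensional")
    scales = params.scales if scales is None else np.asarray(scales, float)
    if scales is None:
        raise ValueError("scale maxima are required")
    values = params.values.copy()
    for name in PARAM_NAMES:
        values[PARAM_INDEX[name]] /= _scale_factor(name, scales)
    return ParameterSet(values, params.provenance, params.cluster,
                        nondimensional=False, scales=scales)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

class SolverError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Result of integrating the system over a time grid."""

    time: np.ndarray            # days
    states: np.ndarray          # (len(time), 17), canonical order
    converged: bool             # steady-state criterion met at final time
    final_residual: float       # ||F(x_T)|| / ||x_T||
    params: ParameterSet

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_days", self.time)
        df["total_cells"] = [total_cells(s) for s in self.states]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def steady_state_residual(state, params: ParameterSet) -> float:
    x = _as_array(state)
    nx = np.linalg.norm(x)
    if nx == 0:
        return float(np.linalg.norm(rhs(x, params, check=False)))
    return float(np.linalg.norm(rhs(x, params, check=False)) / nx)


def simulate(
    params: ParameterSet,
    init,
    cfg: SimulationConfig | None = None,
    *,
    require_convergence: bool = False,
) -> Trajectory:
    """Integrate the system from ``init`` with a stiff-capable method.

    The state spans five orders of magnitude across variables, so an
    implicit/stiff-switching solver with tight tolerances is used.  Small
    negative excursions (within solver tolerance) are clipped to zero in the
    reported trajectory only, never inside the solver state.  With
    ``require_convergence`` the horizon is doubled (up to
    ``cfg.max_extensions`` times) until the steady-state criterion holds.
    """
    cfg = cfg or SimulationConfig()
    x0 = _as_array(init)
    if np.any(x0 < 0):
        raise ValueError("initial state contains negative entries")

    def fun(_t, x):
        return rhs(x, params, check=False)

    def jac(_t, x):
        if params.nondimensional:
            scales = params.scales
            dim = dimensionalize(params, scales)
            J = state_jacobian(x * scales, dim)
            return J * scales[np.newaxis, :] / scales[:, np.newaxis]
        return state_jacobian(x, params)

    horizon = cfg.horizon
    extensions = cfg.max_extensions if require_convergence else 0
    while True:
        t_eval = np.linspace(0.0, horizon, cfg.n_points)
        sol = solve_ivp(
            fun, (0.0, horizon), x0, method=cfg.method, jac=jac,
            rtol=cfg.rtol, atol=cfg.atol, t_eval=t_eval,
        )
        if not sol.success:
            raise SolverError(f"integration failed: {sol.message}")
        final = sol.y[:, -1]
        residual = steady_state_residual(np.clip(final, 0.0, None), params)
        converged = residual < cfg.ss_rtol
        if converged or extensions == 0:
            break
        horizon *= 2.0
        extensions -= 1
    if not converged:
        warnings.warn(
            f"steady state not reached within {horizon:g} days "
            f"(relative residual {residual:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    states = np.clip(sol.y.T, 0.0, None)
    return Trajectory(sol.t.copy(), states, converged, residual, params)
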