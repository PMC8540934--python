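"""Equilibrium analysis of the cancer equation.

With IL-6, adipocytes, cytotoxic cells and IFN-gamma frozen at their
cluster steady-state values, the cancer equation reduces to a scalar
logistic ODE

    dC/dt = Lambda (1 - C/C0) C - Delta C,
    Lambda = lambda_C + lambda_CIL6 * IL6* + lambda_CA * A*,
    Delta  = delta_CTc * Tc* + delta_CIg * Ig* + delta_C,

whose equilibria are C = 0 and, when Lambda > Delta, the positive branch
C* = C0 (1 - Delta/Lambda) < C0.  The two exchange stability where
Lambda = Delta — a transcritical bifurcation separating a regime in which
the tumor is cleared from one in which it persists.  Stability is read off
the sign of the scalar derivative at each equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .state import ParameterSet

__all__ = ["BifurcationCurve", "cancer_equilibria", "threshold"]

GROWTH_PARAMS = ("lambda_C", "lambda_CIL6", "lambda_CA")
DEATH_PARAMS = ("delta_CTc", "delta_CIg", "delta_C")

#: Frozen state multiplying each parameter in Lambda/Delta (None = constant).
_PARTNER = {
    "lambda_C": None, "lambda_CIL6": "IL6", "lambda_CA": "A",
    "delta_CTc": "Tc", "delta_CIg": "Ig", "delta_C": None,
}


def _require_frozen(frozen: dict[str, float]) -> dict[str, float]:
    missing = [k for k in ("IL6", "A", "Tc", "Ig") if k not in frozen]
    if missing:
        raise KeyError(f"frozen states missing: {missing}")
    return {k: float(frozen[k]) for k in ("IL6", "A", "Tc", "Ig")}


def growth_and_death(params: ParameterSet, frozen: dict[str, float]) -> tuple[float, float]:
    """(Lambda, Delta) of the reduced cancer equation."""
    fz = _require_frozen(frozen)
    lam = sum(
        params[p] * (1.0 if _PARTNER[p] is None else fz[_PARTNER[p]])
        for p in GROWTH_PARAMS
    )
    dlt = sum(
        params[p] * (1.0 if _PARTNER[p] is None else fz[_PARTNER[p]])
        for p in DEATH_PARAMS
    )
    return float(lam), float(dlt)


def reduced_rhs(c: float, params: ParameterSet, frozen: dict[str, float]) -> float:
    """Right-hand side of the reduced scalar cancer ODE."""
    lam, dlt = growth_and_death(params, frozen)
    c0 = params["C0"]
    return lam * (1.0 - c / c0) * c - dlt * c


@dataclass
class BifurcationCurve:
    parameter: str
    grid: np.ndarray
    zero_stable: np.ndarray        # bool per grid point
    positive_branch: np.ndarray    # C* or NaN where absent
    threshold: float | None        # parameter value where Lambda == Delta
    frozen: dict[str, float]
    c0: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for value, zs, cp in zip(self.grid, self.zero_stable, self.positive_branch):
            rows.append((value, 0.0, "stable" if zs else "unstable"))
            if np.isfinite(cp):
                rows.append((value, cp, "stable"))
        return pd.DataFrame(rows, columns=[self.parameter, "equilibrium", "stability"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def cancer_equilibria(
    params: ParameterSet,
    frozen: dict[str, float],
    bif_param: str,
    grid=None,
) -> BifurcationCurve:
    """Sweep one parameter and report equilibria with stability labels.

    The zero equilibrium is present everywhere and stable iff
    Lambda < Delta; the positive equilibrium C* = C0 (1 - Delta/Lambda)
    exists iff Lambda > Delta and is then stable.  The default grid spans
    [1e-3, 1e3] x the base value, 200 log-spaced points.
    """
    if bif_param not in GROWTH_PARAMS + DEATH_PARAMS:
        raise KeyError(
            f"{bif_param!r} does not enter the reduced cancer equation"
        )
    fz = _require_frozen(frozen)
    c0 = params["C0"]
    if c0 <= 0:
        raise ValueError("carrying capacity C0 must be positive")
    if grid is None:
        base = params[bif_param]
        center = base if base > 0 else 1.0
        grid = np.geomspace(1e-3 * center, 1e3 * center, 200)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("bifurcation grid must be nonnegative")

    zero_stable = np.empty(len(grid), dtype=bool)
    pos = np.full(len(grid), np.nan)
    for i, value in enumerate(grid):
        p = params.replace(**{bif_param: value})
        lam, dlt = growth_and_death(p, fz)
        zero_stable[i] = lam < dlt
        if lam > dlt:
            pos[i] = c0 * (1.0 - dlt / lam)
    return BifurcationCurve(
        bif_param, grid, zero_stable, pos,
        threshold(params, fz, bif_param), fz, c0,
    )


def threshold(params: ParameterSet, frozen: dict[str, float], bif_param: str) -> float | None:
    """Parameter value where Lambda = Delta (transcritical point).

    Returns ``None`` when the crossing would require a negative parameter
    value.  Raises for parameters not entering the reduced equation.
    """
    if bif_param not in GROWTH_PARAMS + DEATH_PARAMS:
        raise KeyError(
            f"{bif_param!r} does not enter the reduced cancer equation"
        )
    fz = _require_frozen(frozen)
    lam, dlt = growth_and_death(params, fz)
    partner = _PARTNER[bif_param]
    coeff = 1.0 if partner is None else fz[partner]
    contribution = params[bif_param] * coeff
    if bif_param in GROWTH_PARAMS:
        # lam - contribution + coeff * x == dlt
        value = (dlt - (lam - contribution)) / coeff
    else:
        value = (lam - (dlt - contribution)) / coeff
    return float(value) if value >= 0 else None
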