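"""State and parameter containers for the tumor–immune microenvironment model.

The model follows 17 interacting quantities in a breast tumor: 11 cell
populations (naive/helper/cytotoxic/regulatory T cells, naive/activated
dendritic cells, naive/activated macrophages, cancer cells, necrotic cells
and cancer-associated adipocytes) and 6 signalling molecules (HMGB1, IL-12,
IL-10, estrogen, IFN-gamma and IL-6).  Cell populations are measured in
cells, molecules in relative expression units; time is measured in days
throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: Canonical ordering of the 17 state variables.
STATE_NAMES: tuple[str, ...] = (
    "TN", "Th", "Tc", "Tr", "DN", "D", "MN", "M", "C", "N", "A",
    "H", "IL12", "IL10", "E", "Ig", "IL6",
)

STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}

#: Cell populations (cells) vs molecules (relative expression units).
CELL_STATES: tuple[str, ...] = STATE_NAMES[:11]
MOLECULE_STATES: tuple[str, ...] = STATE_NAMES[11:]

#: Activation / production rate constants.
LAMBDA_NAMES: tuple[str, ...] = (
    "lambda_ThH", "lambda_ThD", "lambda_ThIL12", "lambda_ThE",
    "lambda_TcE", "lambda_TcD", "lambda_TcIL12",
    "lambda_TrD", "lambda_TrE",
    "lambda_DC", "lambda_DH", "lambda_DE",
    "lambda_MIL10", "lambda_MIg", "lambda_MIL12", "lambda_MTh", "lambda_ME",
    "lambda_C", "lambda_CIL6", "lambda_CA",
    "lambda_A",
    "lambda_HD", "lambda_HN", "lambda_HM", "lambda_HTc", "lambda_HC",
    "lambda_IL12M", "lambda_IL12D", "lambda_IL12Th", "lambda_IL12Tc",
    "lambda_IL10M", "lambda_IL10D", "lambda_IL10Tr", "lambda_IL10Th",
    "lambda_IL10Tc", "lambda_IL10C",
    "lambda_EA", "lambda_E",
    "lambda_IgTc", "lambda_IgTh", "lambda_IgD",
    "lambda_IL6A", "lambda_IL6M", "lambda_IL6D",
)

#: Inhibition / death rate constants.
DELTA_NAMES: tuple[str, ...] = (
    "delta_ThTr", "delta_ThIL10", "delta_Th",
    "delta_TcTr", "delta_TcIL10", "delta_Tc",
    "delta_Tr", "delta_TN",
    "delta_DN", "delta_DC", "delta_D",
    "delta_MN", "delta_M",
    "delta_CTc", "delta_CIg", "delta_C",
    "delta_A", "delta_N", "delta_H",
    "delta_IL12", "delta_IL10", "delta_E", "delta_Ig", "delta_IL6",
)

#: Constant source terms (cells/day) and carrying capacities (state units).
SOURCE_NAMES: tuple[str, ...] = ("A_TN", "A_DN", "A_M")
CAPACITY_NAMES: tuple[str, ...] = ("C0", "A0", "E0")

#: All 75 parameters in canonical order.
PARAM_NAMES: tuple[str, ...] = (
    LAMBDA_NAMES + DELTA_NAMES + SOURCE_NAMES + CAPACITY_NAMES + ("alpha_NC",)
)

PARAM_INDEX: dict[str, int] = {name: i for i, name in enumerate(PARAM_NAMES)}

#: Death rates whose values come from measured cell/molecule half-lives.
HALF_LIFE_RATE_NAMES: tuple[str, ...] = (
    "delta_TN", "delta_Tc", "delta_Th", "delta_Tr", "delta_D", "delta_M",
    "delta_A", "delta_H", "delta_E", "delta_IL6", "delta_IL10",
    "delta_IL12", "delta_Ig",
)

assert len(PARAM_NAMES) == 75
assert len(HALF_LIFE_RATE_NAMES) == 13


def state_array(values: Mapping[str, float] | Iterable[float]) -> np.ndarray:
    """Coerce a mapping or iterable into the canonical 17-vector."""
    if isinstance(values, Mapping):
        missing = [n for n in STATE_NAMES if n not in values]
        if missing:
            raise KeyError(f"missing state variables: {missing}")
        arr = np.array([float(values[n]) for n in STATE_NAMES])
    else:
        arr = np.asarray(list(values), dtype=float)
    if arr.shape != (17,):
        raise ValueError(f"a model state has exactly 17 entries, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("state contains non-finite entries")
    if np.any(arr < 0):
        raise ValueError("state contains negative entries")
    return arr


@dataclass(frozen=True)
class ModelState:
    """An instantaneous state of the 17-variable system (canonical order)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", state_array(self.values))

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelState":
        return cls(state_array(mapping))

    def __getitem__(self, name: str) -> float:
        return float(self.values[STATE_INDEX[name]])

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(STATE_NAMES, self.values)}

    def asarray(self) -> np.ndarray:
        return self.values.copy()


class ParameterSet:
    """The 75 named rates, sources, capacities and the necrotic fraction.

    Parameters
    ----------
    values
        Mapping from canonical parameter name to a nonnegative value, or a
        length-75 array in canonical order.
    provenance
        Per-parameter provenance flag: ``half_life`` (taken from measured
        half-lives), ``estimated`` (from the steady-state solve) or
        ``configured`` (fixed by configuration).
    cluster
        Optional label of the patient cluster the set was estimated for.
    nondimensional
        Whether the values refer to the rescaled (nondimensionalized) system.
    scales
        The per-variable scale maxima used for nondimensionalization, if any.
    """

    def __init__(
        self,
        values: Mapping[str, float] | np.ndarray,
        provenance: Mapping[str, str] | None = None,
        cluster: str | int | None = None,
        nondimensional: bool = False,
        scales: np.ndarray | None = None,
    ) -> None:
        if isinstance(values, Mapping):
            missing = [n for n in PARAM_NAMES if n not in values]
            if missing:
                raise KeyError(f"missing parameters: {missing}")
            extra = [n for n in values if n not in PARAM_INDEX]
            if extra:
                raise KeyError(f"unknown parameters: {extra}")
            arr = np.array([float(values[n]) for n in PARAM_NAMES])
        else:
            arr = np.asarray(values, dtype=float)
            if arr.shape != (75,):
                raise ValueError("a parameter set has exactly 75 entries")
        if not np.all(np.isfinite(arr)):
            raise ValueError("parameter set contains non-finite values")
        if np.any(arr < 0):
            bad = [PARAM_NAMES[i] for i in np.nonzero(arr < 0)[0]]
            raise ValueError(f"negative parameters: {bad}")
        alpha = arr[PARAM_INDEX["alpha_NC"]]
        # the rescaled alpha_NC of a nondimensional set may exceed 1
        if not nondimensional and not (0.0 < alpha <= 1.0):
            raise ValueError("alpha_NC (necrotic fraction) must lie in (0, 1]")
        for cap in CAPACITY_NAMES:
            if arr[PARAM_INDEX[cap]] <= 0:
                raise ValueError(f"capacity {cap} must be positive")
        self.values = arr
        self.provenance = dict(provenance or {})
        for name in HALF_LIFE_RATE_NAMES:
            self.provenance.setdefault(name, "half_life")
        self.cluster = cluster
        self.nondimensional = bool(nondimensional)
        self.scales = None if scales is None else np.asarray(scales, dtype=float)

    def __getitem__(self, name: str) -> float:
        return float(self.values[PARAM_INDEX[name]])

    def replace(self, **updates: float) -> "ParameterSet":
        arr = self.values.copy()
        for name, value in updates.items():
            arr[PARAM_INDEX[name]] = value
        return ParameterSet(
            arr, self.provenance, self.cluster, self.nondimensional,
            self.scales,
        )

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self.values)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return bool(np.array_equal(self.values, other.values))

    def to_json(self, path) -> None:
        payload = {
            "parameters": self.to_dict(),
            "provenance": self.provenance,
            "cluster": self.cluster,
            "nondimensional": self.nondimensional,
        }
        if self.scales is not None:
            payload["scales"] = {
                n: float(s) for n, s in zip(STATE_NAMES, self.scales)
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            payload = json.load(fh)
        scales = payload.get("scales")
        return cls(
            payload["parameters"],
            provenance=payload.get("provenance"),
            cluster=payload.get("cluster"),
            nondimensional=payload.get("nondimensional", False),
            scales=None if scales is None else np.array(
                [scales[n] for n in STATE_NAMES]
            ),
        )


@dataclass
class SimulationConfig:
    """Integration settings.

    ``horizon`` is the maximum simulation time in days; the solver may extend
    it (doubling, up to ``max_extensions`` times) when convergence to a
    steady state is requested but not reached.  ``ss_rtol`` is the relative
    derivative-norm threshold ||F(x)|| / ||x|| below which the state is
    declared stationary.
    """

    horizon: float = 3000.0
    rtol: float = 1e-8
    atol: float = 1e-10
    ss_rtol: float = 1e-8
    n_points: int = 600
    method: str = "LSODA"
    max_extensions: int = 4  # 2**4 > 10x the base horizon

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.rtol <= 0 or self.atol <= 0 or self.ss_rtol <= 0:
            raise ValueError("tolerances must be positive")
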