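"""Steady-state-constrained parameter estimation.

Thirteen death rates come from measured half-lives and the three carrying
capacities, the necrotic fraction and the necrotic clearance rate are
configured; the remaining 57 rates are found by requiring the right-hand
side to vanish at a cluster's steady state, F(X_inf, theta) = 0.  Because
every equation is linear in the rate constants once the state is fixed,
those 17 conditions — completed by linear assumption relations between
parameters of the same equation block — form a square linear system that
is solved exactly (with a nonnegative least-squares fallback for modified
or inconsistent assumption sets).

Scaling an assumption relation ("scale x lhs = rhs") and re-solving yields
the alternative parameter sets used by the global sensitivity analysis and
the assumption-scaling experiments.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import nnls

from .ode import TERMS
from .profiles import ClusterProfile
from .state import (
    HALF_LIFE_RATE_NAMES,
    PARAM_INDEX,
    PARAM_NAMES,
    STATE_INDEX,
    ParameterSet,
)

__all__ = [
    "AssumptionSet",
    "EstimationFailure",
    "EstimationOptions",
    "KnownDeathRates",
    "Relation",
    "apply_scale",
    "build_linear_system",
    "default_assumptions",
    "default_known_rates",
    "estimate",
]

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# Known rates
# ---------------------------------------------------------------------------

class KnownDeathRates:
    """The 13 half-life-derived death/clearance rates (1/day)."""

    def __init__(self, rates: dict[str, float], sources: dict[str, str] | None = None):
        expected = set(HALF_LIFE_RATE_NAMES)
        if set(rates) != expected:
            raise ValueError(
                f"expected exactly the 13 half-life rates {sorted(expected)}, "
                f"got {sorted(rates)}"
            )
        for name, value in rates.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        self.rates = {n: float(rates[n]) for n in HALF_LIFE_RATE_NAMES}
        self.sources = dict(sources or {})

    def __getitem__(self, name: str) -> float:
        return self.rates[name]

    @classmethod
    def from_yaml(cls, path_or_file) -> "KnownDeathRates":
        if hasattr(path_or_file, "read"):
            doc = yaml.safe_load(path_or_file)
        else:
            with open(path_or_file) as fh:
                doc = yaml.safe_load(fh)
        rates, sources = {}, {}
        for name, entry in doc["rates"].items():
            if "value" in entry:
                rates[name] = float(entry["value"])
            else:
                rates[name] = LN2 / float(entry["half_life_days"])
            if "source" in entry:
                sources[name] = entry["source"]
        return cls(rates, sources)


def default_known_rates() -> KnownDeathRates:
    ref = resources.files("tme.data").joinpath("known_rates.yaml")
    with ref.open() as fh:
        return KnownDeathRates.from_yaml(fh)


# ---------------------------------------------------------------------------
# Assumption relations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Relation:
    """A linear relation ``scale * sum(lhs) == sum(rhs)`` between parameters.

    Each side is a list of ``(param, coeff, factors)`` where the factors are
    profile quantities (``max:X`` scale maximum, ``ss:X`` steady state) that
    multiply the coefficient when the relation is evaluated for a cluster.
    """

    label: str
    lhs: tuple[tuple[str, float, tuple[str, ...]], ...]
    rhs: tuple[tuple[str, float, tuple[str, ...]], ...]
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"relation {self.label!r}: scale must be positive")
        for param, _, _ in self.lhs + self.rhs:
            if param not in PARAM_INDEX:
                raise KeyError(f"relation {self.label!r}: unknown parameter {param!r}")


def _parse_side(side: list[dict]) -> tuple:
    out = []
    for term in side:
        out.append((
            term["param"],
            float(term.get("coeff", 1.0)),
            tuple(term.get("factors", ())),
        ))
    return tuple(out)


class AssumptionSet:
    """An ordered collection of assumption relations."""

    def __init__(self, relations: list[Relation]):
        labels = [r.label for r in relations]
        if len(set(labels)) != len(labels):
            raise ValueError("relation labels must be unique")
        self.relations = list(relations)

    def __len__(self) -> int:
        return len(self.relations)

    def __iter__(self):
        return iter(self.relations)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.relations]

    def __getitem__(self, label: str) -> Relation:
        for r in self.relations:
            if r.label == label:
                return r
        raise KeyError(f"no relation labelled {label!r}")

    def scaled(self, label: str, factor: float) -> "AssumptionSet":
        """Return a copy with one relation's scale multiplied by ``factor``."""
        if not factor > 0:
            raise ValueError("scale factor must be positive")
        found = False
        out = []
        for r in self.relations:
            if r.label == label:
                r = Relation(r.label, r.lhs, r.rhs, r.scale * factor)
                found = True
            out.append(r)
        if not found:
            raise KeyError(f"no relation labelled {label!r}")
        return AssumptionSet(out)

    @classmethod
    def from_yaml(cls, path_or_file) -> "AssumptionSet":
        if hasattr(path_or_file, "read"):
            doc = yaml.safe_load(path_or_file)
        else:
            with open(path_or_file) as fh:
                doc = yaml.safe_load(fh)
        relations = [
            Relation(
                label=str(entry["label"]),
                lhs=_parse_side(entry["lhs"]),
                rhs=_parse_side(entry["rhs"]),
                scale=float(entry.get("scale", 1.0)),
            )
            for entry in doc["relations"]
        ]
        return cls(relations)


def default_assumptions() -> AssumptionSet:
    ref = resources.files("tme.data").joinpath("assumptions.yaml")
    with ref.open() as fh:
        return AssumptionSet.from_yaml(fh)


def apply_scale(assumptions: AssumptionSet, label: str, factor: float) -> AssumptionSet:
    """Functional alias for :meth:`AssumptionSet.scaled`."""
    return assumptions.scaled(label, factor)


# ---------------------------------------------------------------------------
# Linear system and solve
# ---------------------------------------------------------------------------

@dataclass
class EstimationOptions:
    """Configured (non-estimated) quantities of the estimation.

    ``capacity_headroom`` sets the carrying capacities to headroom x the
    profile scale maxima (they enter the equations nonlinearly and are not
    identifiable from a single steady state).  ``delta_N`` is the necrotic
    clearance rate and ``alpha_NC`` the fraction of dying cancer cells that
    become necrotic; together they anchor the total cancer death rate
    through the necrotic balance equation.  ``context_mode`` selects whether
    ``max:`` factors in assumption relations read the profile scale maxima
    (default) or the steady-state values.
    """

    capacity_headroom: float = 1.2
    delta_N: float = 0.2       # necrotic debris clearance, t1/2 ~ 3.5 d
    alpha_NC: float = 0.5      # half of dying cancer cells become necrotic
    context_mode: str = "max"  # or "ss"
    residual_tol: float = 1e-8
    negative_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.context_mode not in ("max", "ss"):
            raise ValueError("context_mode must be 'max' or 'ss'")
        if not (0 < self.alpha_NC <= 1):
            raise ValueError("alpha_NC must lie in (0, 1]")
        if self.capacity_headroom <= 1.0:
            raise ValueError("capacity_headroom must exceed 1")


#: Parameters held fixed during estimation.
CONFIGURED_NAMES: tuple[str, ...] = HALF_LIFE_RATE_NAMES + (
    "delta_N", "alpha_NC", "C0", "A0", "E0",
)

#: The 57 unknowns, in canonical order.
UNKNOWN_NAMES: tuple[str, ...] = tuple(
    n for n in PARAM_NAMES if n not in CONFIGURED_NAMES
)
UNKNOWN_INDEX: dict[str, int] = {n: i for i, n in enumerate(UNKNOWN_NAMES)}

assert len(UNKNOWN_NAMES) == 57


@dataclass
class LinearSystem:
    matrix: np.ndarray          # (17 + n_relations, 57)
    rhs: np.ndarray
    unknown_names: tuple[str, ...]
    row_labels: list[str]
    configured: dict[str, float]


class EstimationFailure(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (relative residual {residual:.3e})")
        self.residual = residual


def _configured_values(
    profile: ClusterProfile,
    known: KnownDeathRates,
    options: EstimationOptions,
) -> dict[str, float]:
    vals = dict(known.rates)
    vals["delta_N"] = options.delta_N
    vals["alpha_NC"] = options.alpha_NC
    vals["C0"] = options.capacity_headroom * profile.scale_max["C"]
    vals["A0"] = options.capacity_headroom * profile.scale_max["A"]
    vals["E0"] = options.capacity_headroom * profile.scale_max["E"]
    return vals


def _factor_value(profile: ClusterProfile, spec: str, mode: str) -> float:
    if mode == "ss" and spec.startswith("max:"):
        spec = "ss:" + spec.split(":", 1)[1]
    return profile.quantity(spec)


def build_linear_system(
    profile: ClusterProfile,
    assumptions: AssumptionSet | None = None,
    known: KnownDeathRates | None = None,
    options: EstimationOptions | None = None,
) -> LinearSystem:
    """Assemble the steady-state + assumption rows over the 57 unknowns.

    Each steady-state equation contributes one row (the known rates moved to
    the right-hand side); each assumption relation contributes one row
    ``scale * lhs - rhs = 0``.
    """
    assumptions = assumptions if assumptions is not None else default_assumptions()
    known = known or default_known_rates()
    options = options or EstimationOptions()
    x = profile.steady.values
    if np.any(x <= 0):
        raise ValueError("steady state must be strictly positive for estimation")
    configured = _configured_values(profile, known, options)

    n_rows = 17 + len(assumptions)
    A = np.zeros((n_rows, len(UNKNOWN_NAMES)))
    b = np.zeros(n_rows)
    row_labels = [f"ss:{name}" for name in
                  sorted(STATE_INDEX, key=STATE_INDEX.get)] + assumptions.labels

    for term in TERMS:
        i = STATE_INDEX[term.eq]
        value = term.sign
        unknown = None
        for pname in term.params:
            if pname in UNKNOWN_INDEX:
                unknown = pname
            else:
                value *= configured[pname]
        for sname in term.states:
            value *= x[STATE_INDEX[sname]]
        if term.logistic is not None:
            sname, cap = term.logistic
            value *= 1.0 - x[STATE_INDEX[sname]] / configured[cap]
        if unknown is None:
            b[i] -= value
        else:
            A[i, UNKNOWN_INDEX[unknown]] += value

    for j, rel in enumerate(assumptions):
        i = 17 + j
        for side_sign, side in ((rel.scale, rel.lhs), (-1.0, rel.rhs)):
            for pname, coeff, factors in side:
                value = side_sign * coeff
                for f in factors:
                    value *= _factor_value(profile, f, options.context_mode)
                if pname in UNKNOWN_INDEX:
                    A[i, UNKNOWN_INDEX[pname]] += value
                else:
                    b[i] -= value * configured[pname]

    return LinearSystem(A, b, UNKNOWN_NAMES, row_labels, configured)


@dataclass
class EstimationReport:
    params: ParameterSet
    residual: float
    rank: int
    mode: str
    system: LinearSystem

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"EstimationReport(mode={self.mode!r}, rank={self.rank}, "
                f"residual={self.residual:.3e})")


def estimate(
    profile: ClusterProfile,
    assumptions: AssumptionSet | None = None,
    known: KnownDeathRates | None = None,
    options: EstimationOptions | None = None,
) -> EstimationReport:
    """Solve for the unknown rates and return the full 75-parameter set.

    The square, consistent default system is solved exactly; otherwise a
    nonnegative least-squares solution is computed.  A negative estimate or
    a residual above tolerance raises :class:`EstimationFailure` — the
    positivity of the parameter set is a hard requirement, never enforced by
    clipping.
    """
    options = options or EstimationOptions()
    system = build_linear_system(profile, assumptions, known, options)
    A, b = system.matrix, system.rhs
    # Equilibrate before the rank check: columns span the ~10 orders of
    # magnitude between cell counts and unit rate coefficients.
    col = np.linalg.norm(A, axis=0)
    col[col == 0] = 1.0
    rank = int(np.linalg.matrix_rank(A / col))
    scale = np.linalg.norm(b) or 1.0

    theta = None
    mode = "exact"
    if A.shape[0] == A.shape[1] == rank:
        try:
            theta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            theta = None
    if (
        theta is None
        or np.linalg.norm(A @ theta - b) / scale > options.residual_tol
        or np.any(theta < -options.negative_tol * np.max(np.abs(theta)))
    ):
        mode = "nnls"
        theta, _ = nnls(A, b)
    # float dust from the exact solve
    tiny = options.negative_tol * max(np.max(np.abs(theta)), 1.0)
    theta = np.where((theta < 0) & (theta > -tiny), 0.0, theta)
    residual = float(np.linalg.norm(A @ theta - b) / scale)
    if np.any(theta < 0):
        bad = [UNKNOWN_NAMES[i] for i in np.nonzero(theta < 0)[0]]
        raise EstimationFailure(f"negative estimates for {bad}", residual)
    if residual > max(options.residual_tol, 1e-6 if mode == "nnls" else 0.0):
        raise EstimationFailure("no nonnegative solution within tolerance", residual)

    values = np.empty(75)
    provenance: dict[str, str] = {}
    for name, value in system.configured.items():
        values[PARAM_INDEX[name]] = value
        provenance[name] = (
            "half_life" if name in HALF_LIFE_RATE_NAMES else "configured"
        )
    for name, value in zip(UNKNOWN_NAMES, theta):
        values[PARAM_INDEX[name]] = value
        provenance[name] = "estimated"
    params = ParameterSet(values, provenance, cluster=profile.cluster,
                          scales=profile.scale_max.values)
    return EstimationReport(params, residual, rank, mode, system)
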