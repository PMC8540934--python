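"""Per-cluster profiles: initial state, steady state and scale maxima.

A profile summarizes one immune-infiltration cluster of a patient cohort:
the average model-variable vector of its smallest tumors (used as initial
conditions), the average vector of its largest tumors (used as the
steady-state constraint of the parameter estimation), and per-variable
scale maxima (used for nondimensionalization and to weight the assumption
relations of the estimation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .state import STATE_INDEX, STATE_NAMES, ModelState


@dataclass(frozen=True)
class ClusterProfile:
    cluster: str
    initial: ModelState
    steady: ModelState
    scale_max: ModelState
    n_members: int = 2

    def __post_init__(self) -> None:
        if np.any(self.steady.values <= 0):
            zero = [n for n, v in zip(STATE_NAMES, self.steady.values) if v <= 0]
            raise ValueError(
                f"steady state must be strictly positive (zero/negative: {zero})"
            )
        if np.any(self.scale_max.values <= 0):
            raise ValueError("scale maxima must be strictly positive")
        if self.n_members < 2:
            raise ValueError("a cluster profile needs at least 2 members")

    def quantity(self, spec: str) -> float:
        """Resolve an evaluation-context factor like ``max:Tc`` or ``ss:Ig``."""
        kind, _, name = spec.partition(":")
        if name not in STATE_INDEX:
            raise KeyError(f"unknown state variable {name!r} in factor {spec!r}")
        if kind == "max":
            return self.scale_max[name]
        if kind == "ss":
            return self.steady[name]
        raise KeyError(f"unknown factor kind {kind!r} (use 'max:' or 'ss:')")

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster,
            "initial": self.initial.to_dict(),
            "steady": self.steady.to_dict(),
            "scale_max": self.scale_max.to_dict(),
            "n_members": self.n_members,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterProfile":
        return cls(
            cluster=str(d["cluster"]),
            initial=ModelState.from_dict(d["initial"]),
            steady=ModelState.from_dict(d["steady"]),
            scale_max=ModelState.from_dict(d["scale_max"]),
            n_members=int(d.get("n_members", 2)),
        )


def save_profiles(profiles: list[ClusterProfile], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in profiles], fh, indent=2, sort_keys=True)


def load_profiles(path) -> list[ClusterProfile]:
    with open(path) as fh:
        return [ClusterProfile.from_dict(d) for d in json.load(fh)]


def study_profiles() -> list[ClusterProfile]:
    """The five reference breast-cancer cluster profiles shipped with the
    package (initial conditions from the smallest tumors, steady states from
    the largest tumors of a TCGA+METABRIC-derived cohort clustered on immune
    infiltration)."""
    ref = resources.files("tme.data").joinpath("study_clusters.json")
    with ref.open() as fh:
        return [ClusterProfile.from_dict(d) for d in json.load(fh)]
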