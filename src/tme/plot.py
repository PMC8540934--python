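"""Minimal plotting helpers (matplotlib)."""

from __future__ import annotations

import numpy as np

from .ode import Trajectory
from .state import STATE_INDEX, STATE_NAMES


def plot_trajectory(traj: Trajectory, variables=None, ax=None, logy=True, **kwargs):
    """Plot selected state variables of a trajectory against time (days)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    variables = variables or STATE_NAMES
    for name in variables:
        ax.plot(traj.time, traj.states[:, STATE_INDEX[name]], label=name, **kwargs)
    if logy:
        ax.set_yscale("symlog", linthresh=1e-2)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("cells / relative expression")
    ax.legend(fontsize="small", ncols=2)
    return ax


def plot_envelope(envelope, ax=None):
    """Plot a cancer perturbation envelope with its base trajectory."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(envelope.time, envelope.lower, envelope.upper,
                    alpha=0.3, label=f"±{envelope.fraction:.0%} envelope")
    ax.plot(envelope.time, envelope.base, color="k", label="base")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("cancer cells")
    ax.legend()
    return ax


def plot_bifurcation(curve, ax=None):
    """Plot stable/unstable equilibrium branches of a bifurcation curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = curve.grid
    stable0 = np.where(curve.zero_stable, 0.0, np.nan)
    unstable0 = np.where(~curve.zero_stable, 0.0, np.nan)
    ax.plot(grid, stable0, "b-", label="C=0 stable")
    ax.plot(grid, unstable0, "b--", label="C=0 unstable")
    ax.plot(grid, curve.positive_branch, "r-", label="C* stable")
    if curve.threshold is not None:
        ax.axvline(curve.threshold, color="gray", ls=":", label="transcritical")
    ax.set_xscale("log")
    ax.set_xlabel(curve.parameter)
    ax.set_ylabel("cancer equilibrium (cells)")
    ax.legend()
    return ax
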