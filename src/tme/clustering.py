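"""Patient stratification on immune-cell fractions.

Patients are grouped by K-means on their deconvolved immune fractions;
the number of clusters is chosen with the elbow rule (the point of
maximum curvature — largest second difference — of the within-cluster
sum of squares).  Fractions already share the [0, 1] scale, so they are
clustered unstandardized by default; z-scoring is available.

From a clustered cohort of per-patient model states, each cluster yields
a :class:`~tme.profiles.ClusterProfile`: initial conditions from its
smallest tumors, steady-state constraints from its largest tumors, and
per-variable scale maxima.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .profiles import ClusterProfile
from .state import STATE_NAMES, ModelState

__all__ = ["cluster", "extract_profiles", "select_k_elbow", "wcss_curve"]

N_RESTARTS = 25


def _as_matrix(table) -> np.ndarray:
    X = table.to_numpy(dtype=float) if hasattr(table, "to_numpy") else np.asarray(table, float)
    if X.ndim != 2:
        raise ValueError("fraction table must be 2-dimensional")
    return X


def wcss_curve(table, k_range, seed: int = 0, standardize: bool = False) -> pd.Series:
    """Within-cluster sum of squares for each candidate K."""
    X = _as_matrix(table)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    ks = sorted(set(int(k) for k in k_range))
    if ks[0] < 1 or ks[-1] > len(X):
        raise ValueError("k_range must lie within [1, n_patients]")
    wcss = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed)
        km.fit(X)
        wcss[k] = float(km.inertia_)
    return pd.Series(wcss, name="wcss")


def select_k_elbow(table, k_range=range(1, 11), seed: int = 0,
                   standardize: bool = False) -> int:
    """Elbow selection: K at the maximum-curvature point of WCSS vs K.

    Curvature is measured as the second difference of log(WCSS): WCSS of a
    clustered dataset decays roughly geometrically up to the true K and
    flattens after it, so the log scale localizes the knee where the
    *relative* improvement collapses (the raw second difference is biased
    toward K=2).  Degenerate tables (all rows identical) return K = 1 with
    a warning.
    """
    X = _as_matrix(table)
    if np.allclose(X, X[0]):
        warnings.warn("all rows identical; returning K=1", RuntimeWarning,
                      stacklevel=2)
        return 1
    curve = wcss_curve(table, k_range, seed=seed, standardize=standardize)
    ks = curve.index.to_numpy()
    w = curve.to_numpy()
    if len(ks) < 3:
        return int(ks[np.argmin(w)])
    logw = np.log(np.maximum(w, 1e-300))
    curvature = {
        int(ks[i]): (logw[i - 1] - logw[i]) - (logw[i] - logw[i + 1])
        for i in range(1, len(ks) - 1)
    }
    return max(curvature, key=curvature.get)


def cluster(table, k: int, seed: int = 0, standardize: bool = False):
    """K-means partition into labels 1..K (best of 25 restarts).

    Returns ``(labels, inertia)``; labels are a pandas Series when the
    input carries an index.
    """
    X = _as_matrix(table)
    if k < 1:
        raise ValueError("K must be at least 1")
    if k > len(X):
        raise ValueError(f"K={k} exceeds the number of patients ({len(X)})")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed)
    raw = km.fit_predict(X) + 1
    if hasattr(table, "index"):
        return pd.Series(raw, index=table.index, name="cluster"), float(km.inertia_)
    return raw, float(km.inertia_)


def extract_profiles(
    states: pd.DataFrame,
    labels,
    small_pct: float = 10.0,
    large_pct: float = 90.0,
    *,
    size_column: str = "TCN",
) -> list[ClusterProfile]:
    """Build one profile per cluster from per-patient model states.

    Initial conditions average the members at or below the ``small_pct``
    percentile of total cell number, steady states those at or above the
    ``large_pct`` percentile; scale maxima are cluster-wise per-variable
    maxima.  An empty percentile window falls back to the single most
    extreme patient with a warning.
    """
    labels = pd.Series(labels, index=states.index)
    if not 0 < small_pct < large_pct < 100:
        raise ValueError("need 0 < small_pct < large_pct < 100")
    profiles = []
    for cl in sorted(labels.unique()):
        members = states.loc[labels == cl]
        if len(members) < 2:
            raise ValueError(f"cluster {cl} has fewer than 2 members")
        size = members[size_column].astype(float)
        lo = np.percentile(size, small_pct)
        hi = np.percentile(size, large_pct)
        small = members.loc[size <= lo]
        large = members.loc[size >= hi]
        if small.empty:
            warnings.warn(f"cluster {cl}: empty small window; using the "
                          "single smallest tumor", RuntimeWarning, stacklevel=2)
            small = members.loc[[size.idxmin()]]
        if large.empty:
            warnings.warn(f"cluster {cl}: empty large window; using the "
                          "single largest tumor", RuntimeWarning, stacklevel=2)
            large = members.loc[[size.idxmax()]]
        cols = list(STATE_NAMES)
        profiles.append(ClusterProfile(
            cluster=str(cl),
            initial=ModelState.from_dict(small[cols].mean().to_dict()),
            steady=ModelState.from_dict(large[cols].mean().to_dict()),
            scale_max=ModelState.from_dict(members[cols].max().to_dict()),
            n_members=int(len(members)),
        ))
    return profiles
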