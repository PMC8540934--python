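"""Synthetic deconvolution-style patient cohorts with planted clusters.

Generates the three tables the cohort pipeline consumes — an LM22-style
immune-fraction table (22 cell types + deconvolution quality columns), a
gene-expression table for the model's molecules, and a clinical table —
for a TCGA-like source (tumor size + necrosis percentage) and a
METABRIC-like source (tumor weight).  Patients are drawn from five
Dirichlet components around distinct immune centroids, so the downstream
clustering, profile extraction, estimation and simulation stages can be
exercised and validated against the planted labels without any cohort
download.

The default centroids are synthetic: they only echo the qualitative
contrasts seen across breast-tumor immune clusters (a macrophage-M2-heavy
cluster, a CD8/NK-inflamed one, a naive/resting-dominated one, ...), not
measured frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = ["LM22_TYPES", "MODEL_GENES", "SyntheticCohortSpec", "generate"]

LM22_TYPES: tuple[str, ...] = (
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory (Tregs)", "T cells gamma delta",
    "NK cells resting", "NK cells activated",
    "Monocytes", "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
)

MODEL_GENES: tuple[str, ...] = (
    "HMGB1", "IL12A", "IL12B", "IL10", "ESR1", "ESR2", "IFNG", "IL6",
)

#: Median expression level per gene (relative units, log-normal location).
_GENE_MEDIANS = {
    "HMGB1": 5.2, "IL12A": 2.8, "IL12B": 2.6, "IL10": 2.9,
    "ESR1": 6.0, "ESR2": 2.3, "IFNG": 3.0, "IL6": 3.4,
}

#: Mild per-cluster multiplicative tilts of molecule expression.
_GENE_TILTS = (
    {"IFNG": 1.1, "IL6": 1.1},
    {"ESR1": 1.2, "ESR2": 1.2, "IL10": 0.9},
    {"IL6": 1.3, "HMGB1": 1.05},
    {"IFNG": 1.3, "IL12A": 1.15, "IL12B": 1.15},
    {"ESR1": 0.8, "IFNG": 1.2, "HMGB1": 1.15},
)


def _default_centroids() -> np.ndarray:
    """Five synthetic immune patterns over the 22 LM22 fractions."""
    base = {t: 0.01 for t in LM22_TYPES}
    patterns = [
        # macrophage-M2-heavy, T-cell poor
        {"Macrophages M2": 0.30, "Macrophages M0": 0.18, "Monocytes": 0.08,
         "T cells CD4 memory resting": 0.10, "Mast cells resting": 0.06},
        # naive/resting dominated
        {"T cells CD4 naive": 0.22, "T cells CD4 memory resting": 0.20,
         "NK cells resting": 0.10, "B cells naive": 0.12, "Monocytes": 0.08},
        # mixed myeloid with plasma cells
        {"Macrophages M0": 0.22, "Macrophages M1": 0.12, "Plasma cells": 0.14,
         "Neutrophils": 0.08, "T cells CD4 memory resting": 0.10},
        # CD8/NK inflamed
        {"T cells CD8": 0.26, "NK cells activated": 0.10,
         "T cells CD4 memory activated": 0.12, "Macrophages M1": 0.10,
         "Dendritic cells activated": 0.06},
        # follicular/regulatory rich
        {"T cells follicular helper": 0.18, "T cells regulatory (Tregs)": 0.14,
         "T cells CD8": 0.12, "B cells memory": 0.10,
         "Dendritic cells resting": 0.08},
    ]
    rows = []
    for pat in patterns:
        row = dict(base)
        row.update(pat)
        vec = np.array([row[t] for t in LM22_TYPES])
        rows.append(vec / vec.sum())
    return np.array(rows)


@dataclass
class SyntheticCohortSpec:
    """Generation settings.

    ``concentration`` is the symmetric Dirichlet concentration of the
    unstructured component added on top of the cluster centroids: larger
    values pull every sample toward the simplex center, blurring the
    planted structure (the separation control).  ``tightness`` scales the
    centroid-aligned component.  Tumor sizes/weights are log-normal,
    necrosis percentages Beta-distributed with mean ~0.1, molecule
    expressions log-normal and strictly positive.
    """

    n_tcga: int = 250
    n_metabric: int = 250
    n_clusters: int = 5
    centroids: np.ndarray | None = None
    concentration: float = 1.0
    tightness: float = 60.0
    frac_fail_pvalue: float = 0.10
    size_lognorm: tuple[float, float] = (np.log(2.5), 0.40)    # cm
    weight_lognorm: tuple[float, float] = (np.log(60.0), 0.50)  # g
    necrosis_beta: tuple[float, float] = (2.0, 18.0)
    expression_sigma: float = 0.25
    seed: int = 0

    def resolved_centroids(self) -> np.ndarray:
        cents = self.centroids if self.centroids is not None else _default_centroids()
        cents = np.asarray(cents, dtype=float)
        if cents.shape != (self.n_clusters, len(LM22_TYPES)):
            raise ValueError(
                f"centroids must be ({self.n_clusters}, {len(LM22_TYPES)})"
            )
        if np.any(cents < 0) or np.any(cents.sum(axis=1) > 1 + 1e-9):
            raise ValueError("centroids must be nonnegative with row sums <= 1")
        return cents

    def __post_init__(self) -> None:
        if self.concentration <= 0 or self.tightness <= 0:
            raise ValueError("concentration and tightness must be positive")
        if self.n_clusters > self.n_tcga + self.n_metabric:
            raise ValueError("more clusters than patients")


class CohortTables(NamedTuple):
    fractions: pd.DataFrame
    expression: pd.DataFrame
    clinical: pd.DataFrame
    labels: pd.Series


def generate(spec: SyntheticCohortSpec) -> CohortTables:
    """Draw a synthetic two-source cohort with planted cluster labels.

    Fraction rows sum to exactly 1 over the 22 cell types; TCGA-like rows
    carry tumor size and necrosis percentage, METABRIC-like rows tumor
    weight; a synthetic deconvolution p-value column includes a fraction of
    failing rows (> 0.05) so that quality filtering is exercised.
    """
    rng = np.random.default_rng(spec.seed)
    cents = spec.resolved_centroids()
    n = spec.n_tcga + spec.n_metabric
    sources = np.array(["tcga"] * spec.n_tcga + ["metabric"] * spec.n_metabric)
    ids = np.array(
        [f"SYN-T-{i:04d}" for i in range(spec.n_tcga)]
        + [f"SYN-M-{i:04d}" for i in range(spec.n_metabric)]
    )
    labels = rng.integers(0, spec.n_clusters, size=n)

    alpha = spec.tightness * cents[labels] + spec.concentration
    fractions = np.vstack([rng.dirichlet(a) for a in alpha])

    fail = rng.random(n) < spec.frac_fail_pvalue
    pvals = np.where(
        fail,
        rng.uniform(0.05, 0.8, size=n),
        rng.uniform(0.0, 0.049, size=n),
    )
    frac_df = pd.DataFrame(fractions, columns=list(LM22_TYPES), index=ids)
    frac_df.insert(0, "Mixture", ids)
    frac_df["P-value"] = pvals
    frac_df["Correlation"] = rng.uniform(0.5, 0.99, size=n)
    frac_df["RMSE"] = rng.uniform(0.4, 1.2, size=n)
    frac_df = frac_df.set_index("Mixture")

    mu = np.log([
        [_GENE_MEDIANS[g] * _GENE_TILTS[k].get(g, 1.0) for g in MODEL_GENES]
        for k in range(spec.n_clusters)
    ])
    expr = np.exp(
        mu[labels % len(_GENE_TILTS)]
        + rng.normal(0.0, spec.expression_sigma, size=(n, len(MODEL_GENES)))
    )
    expr_df = pd.DataFrame(expr.T, index=list(MODEL_GENES), columns=ids)

    clin = pd.DataFrame(index=ids)
    clin["sample"] = ids
    clin["source"] = sources
    size = np.exp(rng.normal(*spec.size_lognorm, size=n))
    weight = np.exp(rng.normal(*spec.weight_lognorm, size=n))
    necro = rng.beta(*spec.necrosis_beta, size=n)
    clin["tumor_size_cm"] = np.where(sources == "tcga", np.round(size, 3), np.nan)
    clin["tumor_weight_g"] = np.where(sources == "metabric", np.round(weight, 3), np.nan)
    clin["necrosis_percent"] = np.where(sources == "tcga", np.round(necro, 4), np.nan)
    clin["age"] = rng.integers(28, 88, size=n)
    clin["er_status"] = rng.choice(["Positive", "Negative"], size=n, p=[0.7, 0.3])
    clin["her2_status"] = rng.choice(["Positive", "Negative"], size=n, p=[0.2, 0.8])
    clin["pam50"] = rng.choice(
        ["LumA", "LumB", "Basal", "Her2", "Normal"], size=n,
        p=[0.45, 0.2, 0.18, 0.1, 0.07],
    )
    clin["survival_months"] = np.round(rng.exponential(80.0, size=n), 1)
    clin["vital_status"] = rng.choice(["Alive", "Dead"], size=n, p=[0.65, 0.35])
    clin = clin.set_index("sample")

    label_s = pd.Series(labels + 1, index=ids, name="planted_cluster")
    return CohortTables(frac_df, expr_df, clin, label_s)


def write_tables(tables: CohortTables, outdir) -> None:
    """Write the three TSVs (and planted labels) in the reader dialects."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables.fractions.to_csv(out / "fractions.tsv", sep="\t")
    tables.expression.to_csv(out / "expression.tsv", sep="\t")
    tables.clinical.to_csv(out / "clinical.tsv", sep="\t")
    tables.labels.to_csv(out / "planted_labels.tsv", sep="\t")
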