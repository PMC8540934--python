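"""Mapping deconvolution, expression and clinical tables to model variables.

The immune-fraction table (CIBERSORTx/LM22 dialect) is collapsed onto the
model's cell pools, molecule variables are read off the expression of
their encoding genes, and the per-patient absolute cell numbers are
reconstructed from tumor size/weight: the total cell number is
proportional to tumor bulk (density scale alpha = 4.5e4 cells per unit),
and the immune : cancer : necrotic split follows the 0.3 : 0.6 : 0.1
ratio observed in breast tumors, using the recorded necrosis percentage
where available (TCGA-style) and the deconvolution immune content
otherwise (METABRIC-style).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .state import STATE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "CohortScaling",
    "EmptyCohortError",
    "SchemaError",
    "FRACTION_VARIABLES",
    "MOLECULE_GENES",
    "assemble_states",
    "estimate_cell_numbers_metabric",
    "estimate_cell_numbers_tcga",
    "filter_patients",
    "linear_from_log2",
    "map_variables",
    "read_cibersortx",
    "read_clinical",
    "read_expression",
    "replace_zero_fractions",
    "rescale_to_reference",
]

#: Model cell pools as combinations of LM22 cell types.
FRACTION_VARIABLES: dict[str, tuple[str, ...]] = {
    "TN": ("T cells CD4 naive", "T cells CD4 memory resting", "NK cells resting"),
    "Th": ("T cells CD4 memory activated", "T cells follicular helper"),
    "Tc": ("T cells CD8", "NK cells activated"),
    "Tr": ("T cells regulatory (Tregs)",),
    "DN": ("Dendritic cells resting",),
    "D": ("Dendritic cells activated",),
    "MN": ("Macrophages M0", "Monocytes"),
    "M": ("Macrophages M1", "Macrophages M2"),
}

#: Model molecules as sums of gene expressions.
MOLECULE_GENES: dict[str, tuple[str, ...]] = {
    "H": ("HMGB1",),
    "IL12": ("IL12A", "IL12B"),
    "IL10": ("IL10",),
    "E": ("ESR1", "ESR2"),
    "Ig": ("IFNG",),
    "IL6": ("IL6",),
}

#: Immune pools whose absolute counts are apportioned from total immune cells.
IMMUNE_POOLS = ("TN", "Th", "Tc", "Tr", "DN", "D", "MN", "M")


class SchemaError(KeyError):
    pass


class EmptyCohortError(RuntimeError):
    pass


@dataclass
class CohortScaling:
    """Cohort-level scaling constants.

    ``alpha`` is the epithelial cell density scale (cells per unit tumor
    bulk); ``ratio`` the immune:cancer:necrotic composition;
    ``immune_factor`` the immune-to-cancer proportion (TIC = 0.5 C);
    ``zero_replacement`` the factor applied to the smallest positive
    fraction when substituting zeros.
    """

    alpha: float = 4.5e4
    ratio: tuple[float, float, float] = (0.3, 0.6, 0.1)
    immune_factor: float = 0.5
    zero_replacement: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.immune_factor <= 0 or self.zero_replacement <= 0:
            raise ValueError("scaling constants must be positive")
        if abs(sum(self.ratio) - 1.0) > 1e-9 or any(r <= 0 for r in self.ratio):
            raise ValueError("ratio must be positive and sum to 1")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_cibersortx(path) -> pd.DataFrame:
    """Read a CIBERSORTx-style TSV (Mixture, 22 cell types, P-value, ...)."""
    df = pd.read_csv(path, sep="\t")
    if "Mixture" not in df.columns:
        raise SchemaError("Mixture")
    return df.set_index("Mixture")


def read_expression(path) -> pd.DataFrame:
    """Read a gene-by-sample expression TSV (gene symbols in column 0)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def linear_from_log2(expr: pd.DataFrame) -> pd.DataFrame:
    """Undo log2(x+1) normalization before any cross-cohort mapping."""
    return (2.0 ** expr) - 1.0


def rescale_to_reference(
    expr: pd.DataFrame,
    reference: pd.DataFrame,
    method: str = "minmax",
) -> pd.DataFrame:
    """Map each gene of ``expr`` onto the reference cohort's range.

    ``minmax`` applies a per-gene linear map onto [min, max] of the
    reference; ``quantile`` matches the empirical quantiles.  Both are
    defensible readings of cross-platform range alignment; the choice is
    recorded by the caller's configuration.
    """
    common = expr.index.intersection(reference.index)
    out = expr.loc[common].astype(float).copy()
    for gene in common:
        x = out.loc[gene].to_numpy(dtype=float)
        r = reference.loc[gene].to_numpy(dtype=float)
        if method == "minmax":
            span = x.max() - x.min()
            if span == 0:
                out.loc[gene] = np.full_like(x, np.median(r))
            else:
                out.loc[gene] = r.min() + (x - x.min()) * (r.max() - r.min()) / span
        elif method == "quantile":
            ranks = pd.Series(x).rank(pct=True).to_numpy()
            out.loc[gene] = np.quantile(r, ranks)
        else:
            raise ValueError("method must be 'minmax' or 'quantile'")
    return out


# ---------------------------------------------------------------------------
# Variable mapping and filtering
# ---------------------------------------------------------------------------

def map_variables(fractions: pd.DataFrame, expressions: pd.DataFrame) -> pd.DataFrame:
    """Collapse LM22 fractions and gene expressions onto model variables.

    Returns one row per patient with the 8 immune-pool *fractions* and the
    6 molecule expression values.
    """
    out = pd.DataFrame(index=fractions.index)
    for var, cols in FRACTION_VARIABLES.items():
        for c in cols:
            if c not in fractions.columns:
                raise SchemaError(c)
        out[var] = fractions[list(cols)].sum(axis=1)
    expr_t = expressions.T  # samples x genes
    for var, genes in MOLECULE_GENES.items():
        for g in genes:
            if g not in expr_t.columns:
                raise SchemaError(g)
        out[var] = expr_t.loc[out.index, list(genes)].sum(axis=1)
    return out


def filter_patients(
    cohort: pd.DataFrame,
    p_threshold: float = 0.05,
    *,
    p_values: pd.Series | None = None,
) -> pd.DataFrame:
    """Keep rows with deconvolution p < threshold (strict) and complete
    source-required clinical fields (TCGA: size + necrosis; METABRIC:
    weight)."""
    df = cohort
    n0 = len(df)
    if p_values is not None:
        df = df.loc[p_values.reindex(df.index) < p_threshold]
    elif "P-value" in df.columns:
        df = df.loc[df["P-value"] < p_threshold]
    n1 = len(df)
    if "source" in df.columns:
        is_tcga = df["source"] == "tcga"
        ok = pd.Series(True, index=df.index)
        if "tumor_size_cm" in df.columns:
            ok &= ~is_tcga | (df["tumor_size_cm"].notna() & df["necrosis_percent"].notna())
        if "tumor_weight_g" in df.columns:
            ok &= is_tcga | df["tumor_weight_g"].notna()
        df = df.loc[ok]
    logger.info(
        "filter_patients: %d -> %d after p<%g, -> %d after clinical completeness",
        n0, n1, p_threshold, len(df),
    )
    if df.empty:
        raise EmptyCohortError("no patients left after filtering")
    return df


def replace_zero_fractions(fractions: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Substitute zeros with 10% of the smallest positive fraction.

    The minimum is taken over the whole deconvolution table (the given
    columns), matching the numerical-stability rule used before converting
    fractions to cell numbers.
    """
    cols = list(columns) if columns is not None else list(fractions.columns)
    block = fractions[cols].to_numpy(dtype=float)
    positive = block[block > 0]
    if positive.size == 0:
        raise ValueError("no positive fraction available for zero replacement")
    floor = 0.1 * positive.min()
    out = fractions.copy()
    out[cols] = np.where(block == 0, floor, block)
    return out


# ---------------------------------------------------------------------------
# Absolute cell numbers
# ---------------------------------------------------------------------------

def _per_type_counts(tic: pd.Series, fractions: pd.DataFrame) -> pd.DataFrame:
    """Apportion total immune cells over the model's immune pools
    (fractions renormalized over those pools only)."""
    sub = fractions[list(IMMUNE_POOLS)].to_numpy(dtype=float)
    share = sub / sub.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        share * tic.to_numpy()[:, None], columns=list(IMMUNE_POOLS),
        index=fractions.index,
    )


def estimate_cell_numbers_tcga(
    sizes: pd.Series,
    necrosis: pd.Series,
    fractions: pd.DataFrame,
    scaling: CohortScaling | None = None,
) -> pd.DataFrame:
    """TCGA-style reconstruction from tumor size and necrosis percentage.

    TCN = alpha * size / mean(size);  N = TCN * Np;
    C = (2/3) TCN (1 - Np);  TIC = 0.5 C.
    """
    scaling = scaling or CohortScaling()
    sizes = sizes.astype(float)
    if (sizes <= 0).any():
        raise ValueError("tumor sizes must be positive")
    necrosis = necrosis.astype(float)
    if ((necrosis < 0) | (necrosis > 1)).any():
        raise ValueError("necrosis percentages must lie in [0, 1]")
    tcn = scaling.alpha * sizes / sizes.mean()
    n = tcn * necrosis
    c = (2.0 / 3.0) * tcn * (1.0 - necrosis)
    tic = scaling.immune_factor * c
    out = pd.DataFrame({"TCN": tcn, "C": c, "N": n, "TIC": tic})
    return pd.concat([out, _per_type_counts(tic, fractions)], axis=1)


def estimate_cell_numbers_metabric(
    sizes: pd.Series,
    fractions: pd.DataFrame,
    scaling: CohortScaling | None = None,
) -> pd.DataFrame:
    """METABRIC-style reconstruction from tumor weight and immune content.

    TCN = alpha * weight / mean(weight);
    TIC = 0.3 alpha * immune_sum / mean(immune_sum);
    C = (6/7)(TCN - TIC);  N = C/6  (so C + N + TIC = TCN).
    """
    scaling = scaling or CohortScaling()
    sizes = sizes.astype(float)
    if (sizes <= 0).any():
        raise ValueError("tumor weights must be positive")
    tcn = scaling.alpha * sizes / sizes.mean()
    imm = fractions[list(IMMUNE_POOLS)].sum(axis=1).astype(float)
    tic = scaling.ratio[0] * scaling.alpha * imm / imm.mean()
    over = tic > tcn
    if over.any():
        warnings.warn(
            f"{int(over.sum())} patients with TIC > TCN; immune count clipped",
            RuntimeWarning,
            stacklevel=2,
        )
        tic = tic.where(~over, tcn)
    c = (6.0 / 7.0) * (tcn - tic)
    n = c / 6.0
    out = pd.DataFrame({"TCN": tcn, "C": c, "N": n, "TIC": tic})
    return pd.concat([out, _per_type_counts(tic, fractions)], axis=1)


def assemble_states(
    variables: pd.DataFrame,
    cell_numbers: pd.DataFrame,
) -> pd.DataFrame:
    """Per-patient 17-variable model states (canonical column order).

    Immune pools take their absolute counts, cancer and necrotic cells the
    reconstructed numbers, adipocytes twice the total immune count, and
    molecules their (summed) expression values.
    """
    out = pd.DataFrame(index=variables.index)
    for pool in IMMUNE_POOLS:
        out[pool] = cell_numbers[pool]
    out["C"] = cell_numbers["C"]
    out["N"] = cell_numbers["N"]
    out["A"] = 2.0 * cell_numbers["TIC"]
    for mol in MOLECULE_GENES:
        out[mol] = variables[mol]
    out["TCN"] = cell_numbers["TCN"]
    return out[[*STATE_NAMES, "TCN"]]
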