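"""Shared fixtures: fitted reference-cluster models and a synthetic cohort
pipeline run, computed once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tme import TumorImmuneModel, synth
from tme import cohort as coh
from tme.clustering import cluster, extract_profiles


@pytest.fixture(scope="session")
def fitted():
    """Fitted results for the five reference cluster profiles, by label."""
    return {c: TumorImmuneModel.from_cluster(c).fit() for c in "12345"}


@pytest.fixture(scope="session")
def cluster1(fitted):
    return fitted["1"]


@pytest.fixture(scope="session")
def synthetic_tables():
    """Default-separation synthetic cohort (500 patients, seed 7)."""
    return synth.generate(synth.SyntheticCohortSpec(seed=7))


@pytest.fixture(scope="session")
def synthetic_cohort(synthetic_tables):
    """The processed synthetic cohort: per-patient states, labels, profiles."""
    tables = synthetic_tables
    merged = tables.clinical.join(tables.fractions["P-value"])
    merged = coh.filter_patients(merged)
    kept = merged.index
    fr = coh.replace_zero_fractions(
        tables.fractions.loc[kept], columns=list(synth.LM22_TYPES)
    )
    variables = coh.map_variables(fr, tables.expression)
    is_tcga = merged["source"] == "tcga"
    with pytest.warns(RuntimeWarning):
        numbers = pd.concat([
            coh.estimate_cell_numbers_tcga(
                merged.loc[is_tcga, "tumor_size_cm"],
                merged.loc[is_tcga, "necrosis_percent"],
                variables.loc[merged.index[is_tcga]],
            ),
            coh.estimate_cell_numbers_metabric(
                merged.loc[~is_tcga, "tumor_weight_g"],
                variables.loc[merged.index[~is_tcga]],
            ),
        ]).loc[kept]
    states = coh.assemble_states(variables.loc[kept], numbers)
    labels, _ = cluster(fr.loc[kept, list(synth.LM22_TYPES)], 5, seed=0)
    profiles = extract_profiles(states, labels)
    return {
        "states": states,
        "labels": labels,
        "profiles": profiles,
        "planted": tables.labels.loc[kept],
        "fractions": fr.loc[kept, list(synth.LM22_TYPES)],
    }
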