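"""Cohort processing: variable mapping, filtering, cell-number formulas."""

import numpy as np
import pandas as pd
import pytest

from tme.cohort import (
    CohortScaling,
    EmptyCohortError,
    SchemaError,
    IMMUNE_POOLS,
    estimate_cell_numbers_metabric,
    estimate_cell_numbers_tcga,
    filter_patients,
    linear_from_log2,
    map_variables,
    replace_zero_fractions,
    rescale_to_reference,
)
from tme.synth import LM22_TYPES, MODEL_GENES


def _fraction_row(**kwargs) -> pd.DataFrame:
    row = {t: 0.0 for t in LM22_TYPES}
    row.update(kwargs)
    return pd.DataFrame([row], index=["P1"])


def _expr(values=None) -> pd.DataFrame:
    vals = {g: 0.0 for g in MODEL_GENES}
    vals.update(values or {})
    return pd.DataFrame({ "P1": vals }).loc[list(MODEL_GENES)]


class TestMapVariables:
    def test_cytotoxic_pool_combination(self):
        fr = _fraction_row(**{"T cells CD8": 0.1, "NK cells activated": 0.05})
        out = map_variables(fr, _expr())
        assert out.loc["P1", "Tc"] == pytest.approx(0.15)

    def test_macrophage_pools(self):
        fr = _fraction_row(**{"Macrophages M0": 0.2, "Monocytes": 0.1,
                              "Macrophages M1": 0.05, "Macrophages M2": 0.15})
        out = map_variables(fr, _expr())
        assert out.loc["P1", "MN"] == pytest.approx(0.3)
        assert out.loc["P1", "M"] == pytest.approx(0.2)

    def test_zero_expression_gives_zero_molecules(self):
        out = map_variables(_fraction_row(), _expr())
        for mol in ("H", "IL12", "IL10", "E", "Ig", "IL6"):
            assert out.loc["P1", mol] == 0.0

    def test_molecule_gene_sums(self):
        out = map_variables(_fraction_row(),
                            _expr({"IL12A": 1.5, "IL12B": 2.0, "ESR1": 3.0,
                                   "ESR2": 0.5}))
        assert out.loc["P1", "IL12"] == pytest.approx(3.5)
        assert out.loc["P1", "E"] == pytest.approx(3.5)

    def test_missing_column_named(self):
        fr = _fraction_row().drop(columns=["T cells CD8"])
        with pytest.raises(SchemaError, match="T cells CD8"):
            map_variables(fr, _expr())


class TestFilter:
    def _cohort(self):
        return pd.DataFrame({
            "P-value": [0.01, 0.05, 0.049, 0.2],
            "source": ["tcga", "tcga", "tcga", "metabric"],
            "tumor_size_cm": [2.0, 2.0, np.nan, np.nan],
            "necrosis_percent": [0.1, 0.1, 0.1, np.nan],
            "tumor_weight_g": [np.nan, np.nan, np.nan, 50.0],
        }, index=["a", "b", "c", "d"])

    def test_strict_inequality_and_completeness(self):
        kept = filter_patients(self._cohort())
        # b fails p == 0.05 exactly; c lacks tumor size; d fails p
        assert list(kept.index) == ["a"]

    def test_idempotent(self):
        once = filter_patients(self._cohort())
        twice = filter_patients(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_cohort_raises(self):
        df = self._cohort()
        df["P-value"] = 0.9
        with pytest.raises(EmptyCohortError):
            filter_patients(df)

    def test_planted_failure_fraction(self, synthetic_tables):
        merged = synthetic_tables.clinical.join(synthetic_tables.fractions["P-value"])
        kept = filter_patients(merged)
        frac = len(kept) / len(merged)
        assert 0.75 < frac < 0.95  # ~10% planted failures removed


class TestZeroReplacement:
    def test_positives_unchanged(self):
        df = pd.DataFrame({"x": [0.2, 0.3], "y": [0.5, 0.01]})
        out = replace_zero_fractions(df)
        pd.testing.assert_frame_equal(out, df)

    def test_zero_becomes_tenth_of_min_positive(self):
        df = pd.DataFrame({"x": [0.0, 0.3], "y": [0.5, 0.01]})
        out = replace_zero_fractions(df)
        assert out.loc[0, "x"] == pytest.approx(0.001)

    def test_all_zero_raises(self):
        df = pd.DataFrame({"x": [0.0, 0.0]})
        with pytest.raises(ValueError):
            replace_zero_fractions(df)


def _uniform_fractions(index) -> pd.DataFrame:
    return pd.DataFrame(
        {pool: 1.0 / len(IMMUNE_POOLS) for pool in IMMUNE_POOLS}, index=index
    )


class TestTcgaFormulas:
    def test_composition_split_at_np_01(self):
        idx = ["p1", "p2"]
        out = estimate_cell_numbers_tcga(
            pd.Series([2.0, 4.0], index=idx),
            pd.Series([0.1, 0.1], index=idx),
            _uniform_fractions(idx),
        )
        np.testing.assert_allclose(out["C"] / out["TCN"], 0.6)
        np.testing.assert_allclose(out["TIC"] / out["TCN"], 0.3)
        np.testing.assert_allclose(out["N"] / out["TCN"], 0.1)

    def test_full_necrosis(self):
        idx = ["p1", "p2"]
        out = estimate_cell_numbers_tcga(
            pd.Series([1.0, 1.0], index=idx), pd.Series([1.0, 1.0], index=idx),
            _uniform_fractions(idx),
        )
        assert (out["C"] == 0).all() and (out["TIC"] == 0).all()
        np.testing.assert_allclose(out["N"], out["TCN"])

    def test_immune_is_half_of_cancer(self):
        idx = list("abc")
        out = estimate_cell_numbers_tcga(
            pd.Series([1.0, 2.0, 3.0], index=idx),
            pd.Series([0.05, 0.4, 0.8], index=idx),
            _uniform_fractions(idx),
        )
        np.testing.assert_allclose(out["TIC"], 0.5 * out["C"], rtol=1e-15)

    def test_mean_total_matches_density_scale(self):
        idx = list("abcd")
        scaling = CohortScaling()
        out = estimate_cell_numbers_tcga(
            pd.Series([1.0, 2.0, 3.0, 4.0], index=idx),
            pd.Series([0.1] * 4, index=idx),
            _uniform_fractions(idx), scaling,
        )
        assert out["TCN"].mean() == pytest.approx(scaling.alpha, rel=1e-9)

    def test_invalid_inputs(self):
        idx = ["p"]
        with pytest.raises(ValueError):
            estimate_cell_numbers_tcga(pd.Series([-1.0], index=idx),
                                       pd.Series([0.1], index=idx),
                                       _uniform_fractions(idx))
        with pytest.raises(ValueError):
            estimate_cell_numbers_tcga(pd.Series([1.0], index=idx),
                                       pd.Series([1.5], index=idx),
                                       _uniform_fractions(idx))


class TestMetabricFormulas:
    def test_identity_and_necrotic_sixth(self):
        rng = np.random.default_rng(0)
        idx = [f"p{i}" for i in range(30)]
        fr = pd.DataFrame(
            rng.dirichlet(np.ones(len(IMMUNE_POOLS)), size=30) * 0.4,
            columns=list(IMMUNE_POOLS), index=idx,
        )
        out = estimate_cell_numbers_metabric(
            pd.Series(rng.uniform(10, 150, 30), index=idx), fr,
        )
        np.testing.assert_allclose(out["N"], out["C"] / 6.0, rtol=1e-12)
        np.testing.assert_allclose(out["C"] + out["N"] + out["TIC"],
                                   out["TCN"], rtol=1e-9)

    def test_tic_clipped_with_warning(self):
        idx = ["big", "small"]
        fr = _uniform_fractions(idx)
        fr.loc["small"] *= 40.0  # immune-rich tiny tumor
        with pytest.warns(RuntimeWarning, match="clipped"):
            out = estimate_cell_numbers_metabric(
                pd.Series([100.0, 0.01], index=idx), fr,
            )
        assert out.loc["small", "C"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc["small", "TIC"] == pytest.approx(out.loc["small", "TCN"])


def test_log2_and_range_mapping():
    expr = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 5.0]},
                        index=["HMGB1", "IL6"])
    lin = linear_from_log2(expr)
    assert lin.loc["HMGB1", "s1"] == pytest.approx(1.0)   # 2^1 - 1
    assert lin.loc["IL6", "s2"] == pytest.approx(31.0)    # 2^5 - 1
    ref = pd.DataFrame({"r1": [10.0, 100.0], "r2": [20.0, 400.0]},
                       index=["HMGB1", "IL6"])
    mapped = rescale_to_reference(lin, ref, method="minmax")
    assert mapped.loc["HMGB1"].min() == pytest.approx(10.0)
    assert mapped.loc["HMGB1"].max() == pytest.approx(20.0)
    q = rescale_to_reference(lin, ref, method="quantile")
    assert q.loc["IL6"].max() == pytest.approx(400.0)
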