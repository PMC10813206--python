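"""TOP3 quantification, replicate correction and ribosome-content summaries."""

import numpy as np
import pandas as pd
import pytest

from rpg_regulon import proteome as pr
from rpg_regulon import simulate as sim
from rpg_regulon.stats import spearman_rho


def peptide_rows(protein, areas, condition="c", replicate=1):
    return [(protein, f"{protein}_p{i}", condition, replicate, a)
            for i, a in enumerate(areas)]


def table_from(rows):
    return pd.DataFrame(rows, columns=["protein_id", "peptide_id",
                                       "condition", "replicate", "area"])


class TestTop3:
    def test_mean_of_three_largest(self):
        quant = pr.top3_quantify(table_from(peptide_rows("P1", [10, 8, 6, 1])),
                                 min_replicates=1)
        assert quant.top3.loc["P1", ("c", 1)] == pytest.approx(8.0)

    def test_two_peptides_flagged(self):
        quant = pr.top3_quantify(table_from(peptide_rows("P1", [4, 2])),
                                 min_replicates=1)
        assert quant.top3.loc["P1", ("c", 1)] == pytest.approx(3.0)
        assert quant.low_peptide.loc["P1"]

    def test_detection_needs_three_replicates_of_one_condition(self):
        rows = []
        for cond in ["c", "t"]:
            for rep in [1, 2]:
                rows += peptide_rows("P1", [5, 4, 3], cond, rep)
        quant = pr.top3_quantify(table_from(rows))
        assert not quant.detected.loc["P1"]
        rows += peptide_rows("P1", [5, 4, 3], "c", 3)
        quant = pr.top3_quantify(table_from(rows))
        assert quant.detected.loc["P1"]

    def test_monotone_in_top_peptides(self, rng):
        areas = [10.0, 8.0, 6.0, 1.0]
        base = pr.top3_quantify(table_from(peptide_rows("P", areas)),
                                min_replicates=1).top3.iloc[0, 0]
        bigger = pr.top3_quantify(
            table_from(peptide_rows("P", [12.0, 8.0, 6.0, 1.0])),
            min_replicates=1).top3.iloc[0, 0]
        assert bigger > base
        shuffled = list(areas)
        rng.shuffle(shuffled)
        again = pr.top3_quantify(table_from(peptide_rows("P", shuffled)),
                                 min_replicates=1).top3.iloc[0, 0]
        assert again == pytest.approx(base)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            pr.top3_quantify(table_from(peptide_rows("P1", [1, -2])))

    def test_duplicate_rows_rejected(self):
        rows = peptide_rows("P1", [1.0]) * 2
        with pytest.raises(ValueError):
            pr.top3_quantify(table_from(rows))


class TestNormalizeReplicates:
    def test_stated_factor_arithmetic(self):
        top3 = pd.DataFrame({"r1": [60.0, 40.0], "r2": [200.0, 100.0]})
        norm, factors = pr.normalize_replicates(top3, per_condition=False)
        assert factors.values == pytest.approx([0.5, 1.5])
        assert norm.sum(axis=0).values == pytest.approx([200.0, 200.0])

    def test_single_replicate_unchanged(self):
        top3 = pd.DataFrame({"r1": [60.0, 40.0]})
        norm, factors = pr.normalize_replicates(top3)
        assert factors.values == pytest.approx([1.0])
        assert norm.equals(top3)

    def test_equal_sums_give_unit_factors(self):
        top3 = pd.DataFrame({"r1": [60.0, 40.0], "r2": [30.0, 70.0]})
        _, factors = pr.normalize_replicates(top3, per_condition=False)
        assert factors.values == pytest.approx([1.0, 1.0])

    def test_sums_equalized_with_missing_values(self, rng):
        cols = pd.MultiIndex.from_product([["c"], [1, 2, 3]])
        values = rng.lognormal(3, 1, size=(30, 3))
        values[rng.random((30, 3)) < 0.2] = np.nan
        top3 = pd.DataFrame(values, columns=cols)
        norm, _ = pr.normalize_replicates(top3)
        sums = norm.sum(axis=0)
        assert np.allclose(sums, sums.mean(), rtol=1e-9)

    def test_zero_total_rejected(self):
        top3 = pd.DataFrame({"r1": [0.0], "r2": [1.0]})
        with pytest.raises(ValueError):
            pr.normalize_replicates(top3)

    def test_per_condition_preserves_global_shift(self):
        cols = pd.MultiIndex.from_product([["c", "t"], [1, 2]])
        top3 = pd.DataFrame([[10, 10, 5, 5], [10, 10, 5, 5]],
                            columns=cols, dtype=float)
        norm, factors = pr.normalize_replicates(top3, per_condition=True)
        # the 2x condition difference survives within-condition correction
        assert norm[("t", 1)].sum() / norm[("c", 1)].sum() == pytest.approx(0.5)


class TestDifferentialAbundance:
    def _quant(self, ctrl, trt):
        cols = pd.MultiIndex.from_product([["c", "t"], [1, 2, 3]])
        top3 = pd.DataFrame([list(ctrl) + list(trt)], index=["P1"],
                            columns=cols)
        detected = pd.Series({"P1": True})
        return top3, detected

    def test_identical_groups(self):
        top3, det = self._quant([8, 9, 10], [8, 9, 10])
        out = pr.differential_abundance(top3, det, "c", "t")
        assert out.loc["P1", "log2fc"] == pytest.approx(0.0)
        assert out.loc["P1", "p_value"] > 0.9

    def test_condition_unique_protein(self):
        cols = pd.MultiIndex.from_product([["c", "t"], [1, 2, 3]])
        top3 = pd.DataFrame([[8, 9, 10, np.nan, np.nan, np.nan]],
                            index=["P1"], columns=cols)
        out = pr.differential_abundance(top3, pd.Series({"P1": True}),
                                        "c", "t")
        assert out.loc["P1", "test"] == "unique_c"

    def test_planted_twofold_reduction(self, rng):
        cols = pd.MultiIndex.from_product([["c", "t"], range(1, 7)])
        n = 90
        base = rng.lognormal(10, 1, size=n)
        ctrl = base[:, None] * 2 ** rng.normal(0, 0.2, size=(n, 6))
        trt = base[:, None] / 2 * 2 ** rng.normal(0, 0.2, size=(n, 6))
        top3 = pd.DataFrame(np.hstack([ctrl, trt]),
                            index=[f"P{i}" for i in range(n)], columns=cols)
        det = pd.Series(True, index=top3.index)
        out = pr.differential_abundance(top3, det, "c", "t")
        assert out["log2fc"].median() == pytest.approx(-1.0, abs=0.25)


class TestMassFractionAndStoichiometry:
    def test_all_rp_gives_one(self):
        top3 = pd.DataFrame({"r1": [1.0, 2.0]}, index=["RPL3", "RPS2"])
        assert pr.rp_mass_fraction(top3, ["RPL3", "RPS2"]).iloc[0] == 1.0

    def test_fraction_definition(self):
        top3 = pd.DataFrame({"r1": [75.0, 25.0]}, index=["RPL3", "X"])
        assert pr.rp_mass_fraction(top3, ["RPL3"]).iloc[0] == pytest.approx(0.75)

    def test_equal_intensities_equal_shares(self):
        cols = pd.MultiIndex.from_product([["c"], [1]])
        top3 = pd.DataFrame([[2.0], [2.0], [2.0], [2.0]],
                            index=["RPL3", "RPL4", "RPS2", "RPS3"],
                            columns=cols)
        shares = pr.stoichiometry(top3, ["RPL3", "RPL4", "RPS2", "RPS3"])
        assert np.allclose(shares.values, 0.25)

    def test_shares_sum_to_one_and_scale_invariant(self, rng):
        cols = pd.MultiIndex.from_product([["c", "t"], [1, 2]])
        top3 = pd.DataFrame(rng.lognormal(5, 1, size=(10, 4)),
                            index=[f"RP{i}" for i in range(10)], columns=cols)
        s1 = pr.stoichiometry(top3, top3.index)
        assert s1.sum(axis=0).values == pytest.approx([1.0, 1.0])
        s2 = pr.stoichiometry(top3 * 7.0, top3.index)
        assert np.allclose(s1.values, s2.values)

    def test_zero_total_rejected(self):
        top3 = pd.DataFrame({"r1": [1.0]}, index=["X"])
        with pytest.raises(ValueError):
            pr.stoichiometry(top3, ["RPL3"])


class TestProteinMRNARatio:
    def test_equal_vectors_zero_ratio(self):
        v = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        assert pr.protein_mrna_ratio(v, v).values == pytest.approx([0, 0, 0])

    def test_identical_ratios_perfect_correlation(self, rng):
        genes = [f"g{i}" for i in range(30)]
        r = pd.Series(rng.normal(size=30), index=genes)
        out = pr.ratio_correlation(r, r)
        assert out.loc["all", "rho"] == pytest.approx(1.0)

    def test_independent_ratios_weak_correlation(self, rng):
        hits = 0
        for s in range(40):
            local = np.random.default_rng(s)
            genes = [f"g{i}" for i in range(80)]
            a = pd.Series(local.normal(size=80), index=genes)
            b = pd.Series(local.normal(size=80), index=genes)
            rho, _ = spearman_rho(a.values, b.values)
            hits += abs(rho) < 0.3
        assert hits >= 36

    def test_empty_intersection_rejected(self):
        a = pd.Series([1.0], index=["x"])
        b = pd.Series([1.0], index=["y"])
        with pytest.raises(ValueError):
            pr.protein_mrna_ratio(a, b)
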