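"""Spike-in size factors, filtering, the NB test and DE calling."""

import numpy as np
import pandas as pd
import pytest

from rpg_regulon import expression as ex
from rpg_regulon import simulate as sim


def make_cm(counts: dict, spike: list, conditions: dict):
    df = pd.DataFrame(counts)
    is_spike = pd.Series([g in spike for g in df.index], index=df.index)
    return ex.CountMatrix(df, is_spike, pd.Series(conditions)[df.columns])


class TestSizeFactors:
    def test_doubled_spike_counts_double_factor(self):
        cm = make_cm({"A": [10, 20, 5], "B": [20, 40, 500]},
                     spike=[0, 1], conditions={"A": "c", "B": "t"})
        f = ex.spikein_size_factors(cm)
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_identical_spikes_give_unit_factors(self):
        cm = make_cm({"A": [10, 20, 5], "B": [10, 20, 999]},
                     spike=[0, 1], conditions={"A": "c", "B": "t"})
        assert ex.spikein_size_factors(cm).values == pytest.approx([1.0, 1.0])

    def test_scale_equivariance(self, rng):
        counts = rng.integers(10, 1000, size=(50, 4))
        df = {f"s{i}": counts[:, i] for i in range(4)}
        cm = make_cm(df, spike=list(range(20)),
                     conditions={f"s{i}": "c" if i < 2 else "t"
                                 for i in range(4)})
        f1 = ex.spikein_size_factors(cm)
        scaled = dict(df)
        scaled["s0"] = scaled["s0"] * 3
        cm2 = make_cm(scaled, spike=list(range(20)),
                      conditions={f"s{i}": "c" if i < 2 else "t"
                                  for i in range(4)})
        f2 = ex.spikein_size_factors(cm2)
        assert f2["s0"] / f1["s0"] == pytest.approx(
            3.0 * (f2["s1"] / f1["s1"]))

    def test_no_usable_spike_rejected(self):
        cm = make_cm({"A": [0, 5], "B": [3, 5]}, spike=[0],
                     conditions={"A": "c", "B": "t"})
        with pytest.raises(ValueError):
            ex.spikein_size_factors(cm)

    def test_global_shift_fools_total_counts_not_spikes(self):
        genes = [r.symbol for r in sim.rpg_catalog()]
        cm, truth = sim.gen_count_matrix(
            rpg_genes=[f"GENE_{i:04d}" for i in range(1910)] + genes,
            n_genes=2000, global_shift_log2=-1.0, seed=11)
        spike_f = ex.spikein_size_factors(cm)
        total_f = ex.totalcount_size_factors(cm)
        assert np.abs(spike_f.values - 1.0).max() < 0.05
        assert np.abs(total_f.values - 1.0).max() > 0.20


class TestNormalizeFilter:
    def test_strict_cpm_boundary(self):
        # one sample, library 1e5 normalized counts: gene at exactly 10 CPM
        counts = {"A": [1, 2, 99_997 - 900, 900]}
        cm = make_cm(counts, spike=[], conditions={"A": "c"})
        factors = pd.Series([1.0], index=["A"])
        _, kept = ex.normalize_filter(cm, factors, min_avg=10.0)
        cpm = cm.counts["A"] / cm.counts["A"].sum() * 1e6
        assert cpm[0] == pytest.approx(10.0)
        assert not kept.iloc[0]          # exactly 10 -> filtered
        assert kept.iloc[1]              # 20 CPM -> kept
        assert kept.iloc[3]

    def test_all_zero_gene_filtered(self):
        cm = make_cm({"A": [0, 100], "B": [0, 100]}, spike=[],
                     conditions={"A": "c", "B": "t"})
        _, kept = ex.normalize_filter(cm, pd.Series([1.0, 1.0],
                                                    index=["A", "B"]))
        assert not kept.iloc[0]

    def test_nonpositive_factor_rejected(self):
        cm = make_cm({"A": [1], "B": [1]}, spike=[],
                     conditions={"A": "c", "B": "t"})
        with pytest.raises(ValueError):
            ex.normalize_filter(cm, pd.Series([1.0, 0.0], index=["A", "B"]))


class TestNBWald:
    def test_identical_replicate_sets_zero_lfc(self):
        data = pd.DataFrame({"a1": [100, 50], "a2": [120, 55],
                             "b1": [100, 50], "b2": [120, 55]},
                            index=["g1", "g2"], dtype=float)
        cond = pd.Series({"a1": "c", "a2": "c", "b1": "t", "b2": "t"})
        res = ex.nb_wald_test(data, cond)
        assert res["log2fc"].abs().max() == pytest.approx(0.0)

    def test_all_zero_gene_is_na(self):
        data = pd.DataFrame({"a1": [0, 50], "a2": [0, 55],
                             "b1": [0, 50], "b2": [0, 55]},
                            index=["g0", "g1"], dtype=float)
        cond = pd.Series({"a1": "c", "a2": "c", "b1": "t", "b2": "t"})
        res = ex.nb_wald_test(data, cond)
        assert np.isnan(res.loc["g0", "p_value"])

    def test_single_condition_rejected(self):
        data = pd.DataFrame({"a1": [1], "a2": [2]}, dtype=float)
        with pytest.raises(ValueError):
            ex.nb_wald_test(data, pd.Series({"a1": "c", "a2": "c"}))

    def test_planted_shift_recovered(self):
        genes = [r.symbol for r in sim.rpg_catalog()]
        cm, _ = sim.gen_count_matrix(rpg_genes=genes, global_shift_log2=-1.0,
                                     seed=2)
        f = ex.spikein_size_factors(cm)
        norm, kept = ex.normalize_filter(cm, f)
        res = ex.nb_wald_test(norm.loc[~cm.is_spike & kept], cm.condition)
        planted = res.index.isin(genes)
        assert res.loc[planted, "log2fc"].median() == pytest.approx(-1.0,
                                                                    abs=0.15)


class TestCallDE:
    def _frame(self, lfc, p):
        return pd.DataFrame({"log2fc": [lfc], "p_value": [p],
                             "q_value": [min(1.0, p)]})

    @pytest.mark.parametrize("lfc,p,status", [
        (0.8, 0.01, "up"),
        (-0.8, 0.2, "unchanged"),
        (0.7, 0.001, "unchanged"),      # strict > 0.7
        (-0.71, 0.05, "down"),          # p <= 0.05 inclusive
        (np.nan, np.nan, "filtered"),
    ])
    def test_threshold_rules(self, lfc, p, status):
        assert ex.call_de(self._frame(lfc, p)).iloc[0] == status

    def test_monotone_in_lfc_threshold(self, rng):
        res = pd.DataFrame({"log2fc": rng.normal(0, 1, 200),
                            "p_value": rng.uniform(0, 1, 200)})
        res["q_value"] = res["p_value"]
        loose = ex.call_de(res, lfc_threshold=0.5)
        tight = ex.call_de(res, lfc_threshold=1.0)
        changed = loose.isin(["up", "down"])
        assert set(tight[~changed]) <= {"unchanged"}


class TestTopPercentile:
    def test_distinct_values(self):
        s = pd.Series(np.arange(100, dtype=float))
        assert ex.top_percentile_flag(s, 5).sum() == 5

    def test_all_equal_all_flagged(self):
        s = pd.Series(np.ones(50))
        assert ex.top_percentile_flag(s, 5).all()

    def test_max_flagged(self):
        s = pd.Series(np.arange(1, 21, dtype=float))
        flags = ex.top_percentile_flag(s, 5)
        assert flags.iloc[-1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ex.top_percentile_flag(pd.Series(dtype=float), 5)


class TestStratify:
    def _calls(self, genes, bound):
        from rpg_regulon.chip import OccupancyCall
        return [OccupancyCall(g, "DYRK1A", 9.0 if b else 0.0, b, 5.0)
                for g, b in zip(genes, bound)]

    def test_identical_distributions_nonsignificant(self, rng):
        genes = [f"g{i}" for i in range(60)]
        values = pd.Series(rng.normal(size=60), index=genes)
        calls = self._calls(genes, [i < 30 for i in range(60)])
        out = ex.stratify_by_occupancy(values, calls)
        assert out.report.p_value > 0.01
        assert abs(out.group_medians["bound"]
                   - out.group_medians["unbound"]) < 1.0

    def test_paired_mode_detects_common_shift(self, rng):
        genes = [f"g{i}" for i in range(30)]
        before = pd.Series(rng.normal(10, 1, 30), index=genes)
        after = before - 1.0 + rng.normal(0, 0.1, 30)
        calls = self._calls(genes, [True] * 15 + [False] * 15)
        out = ex.stratify_by_occupancy(before, calls, paired_values=after)
        assert out.report.p_value < 1e-4
        assert out.report.test_name == "wilcoxon-signed-rank"

    def test_empty_group_rejected(self):
        genes = [f"g{i}" for i in range(10)]
        values = pd.Series(np.arange(10.0), index=genes)
        calls = self._calls(genes, [True] * 10)
        with pytest.raises(ValueError):
            ex.stratify_by_occupancy(values, calls)

    def test_unclassified_gene_rejected(self):
        values = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        calls = self._calls(["a", "b"], [True, False])
        with pytest.raises(ValueError):
            ex.stratify_by_occupancy(values, calls)
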