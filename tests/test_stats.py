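"""Usage profiles, U/T ratios, pairing matrices, junction stats, group comparison."""

import numpy as np
import pandas as pd
import pytest

from ighjkit import (
    IntDistribution,
    RepertoireTable,
    SimulationParams,
    apply_pergene_trim_shift,
    band_label,
    collapse_unique,
    compare_groups,
    dj_pairing_matrix,
    ighj_usage,
    junction_trim_stats,
    simulate_repertoire,
    ut_ratio,
)
from ighjkit.errors import DegenerateAnovaError, EmptyStratumError, ParameterError


def _table(rows):
    df = pd.DataFrame(rows)
    if "duplicate_count" not in df.columns:
        df["duplicate_count"] = 1
    if "frame" not in df.columns:
        df["frame"] = "in_frame"
    return RepertoireTable(df)


class TestUsage:
    def test_hand_counted_split(self):
        rows = (
            [{"j_call": "IGHJ4", "junction": f"A{i}"} for i in range(50)]
            + [{"j_call": "IGHJ6", "junction": f"B{i}"} for i in range(30)]
            + [{"j_call": "IGHJ3", "junction": f"C{i}"} for i in range(20)]
        )
        prof = ighj_usage(_table(rows))
        assert prof.frequencies == pytest.approx(
            {"IGHJ4": 0.5, "IGHJ6": 0.3, "IGHJ3": 0.2}
        )
        assert sum(prof.frequencies.values()) == pytest.approx(1.0)

    def test_single_gene_frequency_one(self):
        prof = ighj_usage(_table([{"j_call": "IGHJ4", "junction": "X"}]))
        assert prof.frequencies == {"IGHJ4": 1.0}
        assert prof.bands == {"IGHJ4": "high"}

    def test_empty_stratum_raises(self):
        with pytest.raises(EmptyStratumError):
            ighj_usage(_table([{"j_call": "IGHJ4", "junction": "X"}]), frame="out_of_frame")

    @pytest.mark.parametrize(
        "freq, label",
        [(0.45, "high"), (0.15, "medium"), (0.10, "medium"), (0.20, "medium"),
         (0.03, "low"), (0.25, "unbanded"), (0.07, "unbanded")],
    )
    def test_band_thresholds(self, freq, label):
        assert band_label(freq) == label

    def test_duplicate_weighting_flag(self):
        rows = [
            {"j_call": "IGHJ4", "junction": "A", "duplicate_count": 9},
            {"j_call": "IGHJ6", "junction": "B", "duplicate_count": 1},
        ]
        unique_based = ighj_usage(_table(rows))
        total_based = ighj_usage(_table(rows), weight_by_duplicates=True)
        assert unique_based.frequencies["IGHJ4"] == 0.5
        assert total_based.frequencies["IGHJ4"] == 0.9


class TestUtRatio:
    def test_all_singletons_ratio_one(self):
        rows = [{"j_call": f"IGHJ{1 + i % 6}", "d_call": "IGHD6-13",
                 "junction": f"TGT{i}", "duplicate_count": 1} for i in range(60)]
        ratios = ut_ratio(_table(rows))
        assert all(r == 1.0 for r in ratios.values())

    def test_singleton_expansion_ratio_near_one_despite_convergence(self, germline):
        """With clone size fixed at 1, U/T < 1 only through convergent
        recombination (independent draws of the same junction), a rare event."""
        params = SimulationParams(
            n_total=400, seed=31,
            expansion_dist=IntDistribution("constant", mean=1, support_min=1),
        )
        table = simulate_repertoire(germline, params)
        ratios = ut_ratio(table)
        assert all(0.95 <= r <= 1.0 for r in ratios.values())
        # default geometric expansion drives the ratio far below one
        expanded = simulate_repertoire(germline, SimulationParams(n_total=400, seed=31))
        assert max(ut_ratio(expanded).values()) < 0.9

    def test_hand_computed_ratio(self):
        rows = [{"j_call": "IGHJ4", "d_call": "IGHD6-13", "junction": j,
                 "duplicate_count": 10} for j in ("AAA", "CCC")]
        total = _table(rows)
        assert ut_ratio(total) == {"IGHJ4": pytest.approx(2 / 20)}

    def test_matches_per_gene_set_size_oracle(self, germline):
        table = simulate_repertoire(germline, SimulationParams(n_total=8_000, seed=32))
        ratios = ut_ratio(table)
        df = table.df
        for gene, ratio in ratios.items():
            sub = df[df["j_call"] == gene]
            n_unique = len({(r.j_call, r.d_call, r.junction)
                            for r in sub.itertuples(index=False)})
            assert ratio == pytest.approx(n_unique / sub["duplicate_count"].sum())

    def test_two_collapse_routes_agree(self, germline):
        """Per-gene collapse vs global collapse then split give identical ratios."""
        table = simulate_repertoire(germline, SimulationParams(n_total=6_000, seed=33))
        global_ratios = ut_ratio(table, collapse_unique(table))
        for gene in global_ratios:
            sub = table.with_df(table.df[table.df["j_call"] == gene])
            assert ut_ratio(sub, collapse_unique(sub))[gene] == global_ratios[gene]

    def test_absent_gene_reported_missing_not_zero(self):
        ratios = ut_ratio(_table([{"j_call": "IGHJ4", "d_call": "IGHD1-1",
                                   "junction": "A"}]))
        assert "IGHJ1" not in ratios


class TestPairing:
    def test_single_pair_cell_is_one(self):
        table = _table([{"j_call": "IGHJ4", "d_call": "IGHD6-13", "junction": "A"}])
        pm = dj_pairing_matrix(table)
        assert pm.matrix.loc["IGHJ4", "IGHD6-13"] == 1.0

    def test_normalization_modes_sum_correctly(self, germline):
        table = simulate_repertoire(germline, SimulationParams(n_total=4_000, seed=34))
        glob = dj_pairing_matrix(table, "global")
        assert glob.matrix.values.sum() == pytest.approx(1.0)
        per_j = dj_pairing_matrix(table, "per_J")
        assert per_j.matrix.sum(axis=1).values == pytest.approx(np.ones(len(per_j.matrix)))

    def test_uniform_pairing_within_multinomial_envelope(self, germline):
        from ighjkit import GeneWeights

        d_names = sorted(n for n in germline if n.startswith("IGHD"))
        uniform = GeneWeights({d: 1 / len(d_names) for d in d_names}, mode="calibrated")
        n = 50_000
        table = simulate_repertoire(
            germline,
            SimulationParams(n_total=n, seed=35, d_weights=uniform,
                             expansion_dist=IntDistribution("constant", 1, support_min=1)),
        )
        counts = table.df["d_call"].value_counts()
        p = 1 / len(d_names)
        sigma = np.sqrt(p * (1 - p) / n)
        for d in d_names:
            assert abs(counts.get(d, 0) / n - p) < 3 * sigma

    def test_skewed_d_weights_dominate_their_column(self, germline):
        table = simulate_repertoire(germline, SimulationParams(n_total=20_000, seed=36))
        pm = dj_pairing_matrix(table, "global")
        col_mass = pm.matrix.sum(axis=0)
        # the high-pairing tier genes outrank every low-tier gene
        for hi in ("IGHD6-13", "IGHD3-22"):
            for lo in ("IGHD1-7", "IGHD7-27"):
                assert col_mass[hi] > col_mass[lo]

    def test_missing_d_calls_excluded_and_counted(self):
        rows = [
            {"j_call": "IGHJ4", "d_call": "IGHD6-13", "junction": "A"},
            {"j_call": "IGHJ4", "d_call": None, "junction": "B"},
        ]
        pm = dj_pairing_matrix(_table(rows))
        assert pm.n_pairs == 1 and pm.n_excluded_missing_d == 1

    def test_no_pairable_records_is_error(self):
        with pytest.raises(EmptyStratumError):
            dj_pairing_matrix(_table([{"j_call": "IGHJ4", "d_call": None,
                                       "junction": "A"}]))


class TestJunctionStats:
    def test_all_zero_trims(self):
        rows = [{"j_call": "IGHJ4", "junction": "A", "d_3_trim": 0,
                 "j_5_trim": 0, "n2_length": 0}] * 5
        js = junction_trim_stats(_table(rows))
        assert js.per_gene.loc["IGHJ4", ("d_3_trim", "mean")] == 0.0
        assert js.per_gene.loc["IGHJ4", ("n2_length", "mean")] == 0.0

    def test_hand_computed_means(self):
        rows = [
            {"j_call": "IGHJ4", "junction": "A", "d_3_trim": 1, "j_5_trim": 2, "n2_length": 3},
            {"j_call": "IGHJ4", "junction": "B", "d_3_trim": 3, "j_5_trim": 4, "n2_length": 5},
            {"j_call": "IGHJ6", "junction": "C", "d_3_trim": 0, "j_5_trim": 6, "n2_length": 1},
        ]
        js = junction_trim_stats(_table(rows))
        assert js.per_gene.loc["IGHJ4", ("d_3_trim", "mean")] == 2.0
        assert js.per_gene.loc["IGHJ4", ("j_5_trim", "mean")] == 3.0
        assert js.per_gene.loc["IGHJ6", ("j_5_trim", "mean")] == 6.0
        assert js.per_gene.loc["IGHJ4", ("d_3_trim", "count")] == 2

    def test_missing_fields_counted_per_field(self):
        rows = [{"j_call": "IGHJ4", "junction": "A", "d_3_trim": 1,
                 "j_5_trim": None, "n2_length": 2}]
        js = junction_trim_stats(_table(rows))
        assert js.missing_counts["j_5_trim"] == 1
        assert js.missing_counts["d_3_trim"] == 0

    def test_planted_trim_shift_recovered_through_stats(self, germline):
        p = apply_pergene_trim_shift(SimulationParams(n_total=100_000, seed=37), "IGHJ6", 2)
        js = junction_trim_stats(simulate_repertoire(germline, p))
        means = js.per_gene[("j_5_trim", "mean")]
        others = means.drop("IGHJ6").mean()
        assert means["IGHJ6"] - others == pytest.approx(2.0, abs=0.2)


def _anova_oracle(groups):
    """Textbook one-way ANOVA arithmetic, independent of scipy."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestCompareGroups:
    def _df(self, groups):
        rows = [{"group": name, "value": v} for name, vals in groups.items() for v in vals]
        return pd.DataFrame(rows)

    def test_identical_groups_f_zero_p_one(self):
        data = self._df({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        res = compare_groups(data, "value", "group")
        assert res.f_statistic == pytest.approx(0.0)
        assert all(p["p_adj"] == 1.0 for p in res.pairwise.values())

    def test_f_matches_hand_anova_on_three_groups(self):
        groups = {"a": [4.0, 5.0, 6.0], "b": [6.0, 7.0, 8.0], "c": [9.0, 10.0, 11.0]}
        res = compare_groups(self._df(groups), "value", "group")
        assert res.f_statistic == pytest.approx(
            _anova_oracle([groups["a"], groups["b"], groups["c"]])
        )
        assert res.n_comparisons == 3

    def test_planted_effect_highly_significant(self):
        rng = np.random.default_rng(38)
        groups = {
            "ctrl": (rng.normal(0, 0.1, 8)).tolist(),
            "case": (rng.normal(5, 0.1, 8)).tolist(),
        }
        res = compare_groups(self._df(groups), "value", "group")
        pair = res.pairwise[("case", "ctrl")]
        assert pair["p_adj"] < 0.001
        assert pair["tier"] == "***"

    def test_bonferroni_adjusted_ge_raw_and_capped(self):
        rng = np.random.default_rng(39)
        groups = {k: rng.normal(0, 1, 5).tolist() for k in "abcd"}
        res = compare_groups(self._df(groups), "value", "group")
        assert res.n_comparisons == 6
        for pair in res.pairwise.values():
            assert pair["p_raw"] <= pair["p_adj"] <= 1.0
            assert pair["p_adj"] == pytest.approx(min(1.0, pair["p_raw"] * 6))

    def test_degenerate_all_constant_groups(self):
        data = self._df({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(DegenerateAnovaError):
            compare_groups(data, "value", "group")

    def test_needs_two_groups(self):
        with pytest.raises(ParameterError):
            compare_groups(self._df({"a": [1.0, 2.0]}), "value", "group")
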