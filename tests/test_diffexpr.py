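"""Normalization, imputation, Welch/BH differential expression and flags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invadome.config import PipelineConfig
from invadome.diffexpr import (
    bh_adjust,
    differential_expression,
    flag_hits,
    impute_missing,
    log_fold_change,
    median_ratio_normalize,
    welch_t_test,
)
from invadome.simulate import simulate_quant
from invadome.config import SimConfig

from conftest import make_table
from oracles import bh_oracle


class TestMedianRatioNormalize:
    def test_doubled_column_rescaled(self):
        cols = ["A_s1_r1", "A_s1_r2", "I_s1_r1", "I_s1_r2"]
        base = np.array([10.0, 20, 40, 80, 160])
        rows = {f"P{i}": [base[i]] * 4 for i in range(5)}
        for i in range(5):
            rows[f"P{i}"][1] = base[i] * 2  # second column doubled
        table = make_table(rows, columns=cols)
        normed, scales = median_ratio_normalize(table)
        assert scales["A_s1_r2"] == pytest.approx(0.5)
        ref = normed.values.median(axis=1)
        for col in cols:
            assert (normed.values[col] / ref).median() == pytest.approx(1.0)

    def test_idempotent_on_normalized_table(self, tiny_table):
        normed, _ = median_ratio_normalize(tiny_table)
        again, scales = median_ratio_normalize(normed)
        assert np.allclose(scales.to_numpy(), 1.0)
        assert np.allclose(again.values, normed.values)

    def test_missing_cells_ignored_in_medians(self):
        cols = ["A_s1_r1", "A_s1_r2", "I_s1_r1"]
        table = make_table(
            {"P1": [10, None, 30], "P2": [5, 10, 15], "P3": [2, 4, 6]},
            columns=cols,
        )
        _, scales = median_ratio_normalize(table)
        # brute force: reference over present values only
        vals = table.values
        ref = vals.median(axis=1, skipna=True)
        for col in cols:
            ratios = (vals[col] / ref).dropna()
            assert scales[col] == pytest.approx(1.0 / ratios.median())


class TestImputeMissing:
    def test_complete_table_identity(self, tiny_table):
        imputed, flags = impute_missing(tiny_table)
        assert np.allclose(imputed.values, tiny_table.values)
        assert not flags.to_numpy().any()

    def test_missing_imputed_at_low_quantile(self):
        cols = ["A_s1_r1", "A_s1_r2"]
        rows = {f"P{i}": [float(v), float(v)] for i, v in enumerate(range(10, 1001, 10))}
        rows["PX"] = [None, 500.0]
        table = make_table(rows, columns=cols)
        imputed, flags = impute_missing(table)
        present = table.values["A_s1_r1"].dropna().to_numpy()
        assert imputed.values.at["PX", "A_s1_r1"] == pytest.approx(
            np.quantile(present, 0.01)
        )
        assert flags.at["PX", "A_s1_r1"]
        assert not imputed.values.isna().to_numpy().any()

    def test_fully_missing_column_rejected(self):
        table = make_table({"P1": [None, 5.0], "P2": [None, 6.0]},
                           columns=["A_s1_r1", "A_s1_r2"])
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(table)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # means 11 vs 2, both variances 1: t = 9/sqrt(2/3), df = 4
        t, df, p = welch_t_test([10, 11, 12], [1, 2, 3])
        assert t == pytest.approx(9 / np.sqrt(2 / 3))
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(3.85e-4, rel=1e-2)

    def test_too_few_values_undefined(self):
        t, df, p = welch_t_test([1.0], [1, 2, 3])
        assert np.isnan(t) and np.isnan(p)

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(2, 12))
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(2, 12))
            t, df, p = welch_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(4000):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0, 1, 5)
            ps.append(welch_t_test(a, b).p)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.002, 0.03], [0.004, 0.03]),
            ([0.5], [0.5]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 50))
            assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_nan_entries_excluded_and_restored(self):
        p = np.array([0.01, np.nan, 0.04])
        adj = bh_adjust(p)
        assert np.isnan(adj[1])
        assert adj[[0, 2]] == pytest.approx(bh_oracle(np.array([0.01, 0.04])))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 30)
        perm = rng.permutation(30)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestLogFoldChange:
    @pytest.mark.parametrize(
        "mi,ma,expected", [(4.0, 4.0, 0.0), (8.0, 2.0, 2.0), (2.0, 8.0, -2.0)]
    )
    def test_log2_ratio(self, mi, ma, expected):
        assert log_fold_change(mi, ma) == pytest.approx(expected)

    def test_nonpositive_mean_undefined(self):
        assert np.isnan(log_fold_change(0.0, 5.0))

    def test_planted_effect_recovered(self):
        cfg = SimConfig(
            n_human=60, n_mouse=0, de_fraction=1.0, log2fc_range=(3.0, 3.0),
            invasive_up_fraction=1.0, cv_bulk=0.2, cv_tail_fraction=0.0,
            dropout=False, seed=21,
        )
        table, truth = simulate_quant(cfg)
        de = differential_expression(table)
        assert de["log2fc"].mean() == pytest.approx(3.0, abs=0.3)


class TestFlagsAndPipelineProperties:
    def _de_row(self, padj, log2fc, species="human"):
        return {
            "protein_id": "P1", "gene_symbol": "G1", "species": species,
            "n_A": 9, "n_I": 9, "mean_A": 1.0, "mean_I": 1.0,
            "log2fc": log2fc, "t": 1.0, "df": 4.0, "p": padj, "padj": padj,
        }

    @pytest.mark.parametrize(
        "padj,log2fc,sig,enr,cm",
        [
            (0.005, 1.5, True, True, False),  # passes padj and |lfc|>1 only
            (0.02, 6.0, False, False, False),  # fails the padj gate
            (0.005, 2.5, True, True, True),
            (0.005, 0.5, True, False, False),
        ],
    )
    def test_human_threshold_tiers(self, padj, log2fc, sig, enr, cm):
        de = pd.DataFrame([self._de_row(padj, log2fc)])
        out = flag_hits(de, PipelineConfig())
        assert bool(out.loc[0, "significant"]) is sig
        assert bool(out.loc[0, "enrichment_hit"]) is enr
        assert bool(out.loc[0, "clustermap_hit"]) is cm

    def test_mouse_uses_higher_clustermap_gate(self):
        de = pd.DataFrame([self._de_row(0.005, 4.0, species="mouse")])
        out = flag_hits(de, PipelineConfig())
        assert bool(out.loc[0, "enrichment_hit"])
        assert not bool(out.loc[0, "clustermap_hit"])  # needs |lfc| > 5

    def test_direction_follows_sign(self):
        de = pd.DataFrame(
            [self._de_row(0.005, 2.0), self._de_row(0.005, -2.0)]
        )
        out = flag_hits(de, PipelineConfig())
        assert list(out["direction"]) == ["invasive-up", "core-up"]

    def test_tiers_nested_on_simulation(self):
        cfg = SimConfig(n_human=150, n_mouse=0, seed=22)
        table, _ = simulate_quant(cfg)
        de = flag_hits(differential_expression(table), PipelineConfig())
        assert (de["clustermap_hit"] <= de["enrichment_hit"]).all()
        assert (de["enrichment_hit"] <= de["significant"]).all()

    def test_null_simulation_controls_fdr(self):
        cfg = SimConfig(
            n_human=400, n_mouse=0, de_fraction=0.0, cv_tail_fraction=0.0,
            dropout=False, seed=23,
        )
        table, _ = simulate_quant(cfg)
        de = flag_hits(differential_expression(table), PipelineConfig())
        # expected false positives at padj<0.01 on a 400-protein null: ~0
        assert de["significant"].sum() <= 4
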