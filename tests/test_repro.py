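"""Coefficient-of-variation filtering and presence aggregation."""

import math

import numpy as np
import pytest

from invadome.repro import aggregate, coefficient_of_variation, cv_filter
from invadome.simulate import simulate_quant
from invadome.config import SimConfig

from conftest import make_table


class TestCoefficientOfVariation:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((5, 5, 5), 0.0),  # constant vector
            ((1, 2, 3), 0.5),  # sd=1, mean=2
            ((2, 2, 8), math.sqrt(12) / 4),  # sd≈3.464, mean=4 → ≈0.866
        ],
    )
    def test_hand_computed_values(self, values, expected):
        assert coefficient_of_variation(values) == pytest.approx(expected)

    def test_high_dispersion_triplet_crosses_threshold(self):
        # (2, 2, 8) exceeds the 0.8 reproducibility gate
        assert coefficient_of_variation((2, 2, 8)) > 0.8

    def test_fewer_than_two_values_undefined(self):
        assert np.isnan(coefficient_of_variation([5.0]))
        assert np.isnan(coefficient_of_variation([5.0, np.nan]))

    def test_population_sd_option(self):
        # ddof=0: sd of (1,2,3) is sqrt(2/3)
        assert coefficient_of_variation((1, 2, 3), ddof=0) == pytest.approx(
            math.sqrt(2 / 3) / 2
        )


def _values_with_cv(mean: float, cv: float) -> list[float]:
    """Triplet with exact sample CV around the given mean."""
    sd = cv * mean
    d = sd  # (m-d, m, m+d) has sample sd d
    return [mean - d, mean, mean + d]


class TestCvFilter:
    def test_all_low_cv_retained(self):
        row = []
        for _ in range(6):  # 6 triplets, all CV 0.2
            row += _values_with_cv(100, 0.2)
        table = make_table({"P1": row})
        kept, report = cv_filter(table, threshold=0.8)
        assert kept.protein_ids == ["P1"]
        assert (report.per_sample["cv"] < 0.8).all()

    def test_single_bad_triplet_removes_protein(self):
        # one sample in condition A with CV 0.85 vetoes the protein
        row = _values_with_cv(100, 0.85)
        for _ in range(5):
            row += _values_with_cv(100, 0.1)
        table = make_table({"P1": row})
        kept, report = cv_filter(table, threshold=0.8)
        assert kept.n_proteins == 0
        assert not report.retained["P1"]

    def test_partial_triplet_does_not_veto(self):
        # a triplet with <2 present values contributes no CV
        row = [None, None, 100.0]
        for _ in range(5):
            row += _values_with_cv(100, 0.1)
        table = make_table({"P1": row})
        kept, report = cv_filter(table)
        assert kept.protein_ids == ["P1"]
        sub = report.per_sample.query("condition == 'A' and sample == 1")
        assert sub["cv"].isna().all()

    def test_idempotent(self):
        cfg = SimConfig(n_human=80, n_mouse=0, cv_tail_fraction=0.3, seed=11)
        table, _ = simulate_quant(cfg)
        once, _ = cv_filter(table)
        twice, _ = cv_filter(once)
        assert twice.protein_ids == once.protein_ids

    @pytest.mark.parametrize("tight,loose", [(0.3, 0.8), (0.5, 1.2)])
    def test_threshold_monotonicity(self, tight, loose):
        cfg = SimConfig(n_human=80, n_mouse=0, cv_tail_fraction=0.3, seed=12)
        table, _ = simulate_quant(cfg)
        kept_tight, _ = cv_filter(table, threshold=tight)
        kept_loose, _ = cv_filter(table, threshold=loose)
        assert set(kept_tight.protein_ids) <= set(kept_loose.protein_ids)

    def test_planted_tail_mostly_removed(self):
        # 20% of proteins get true CV 1.2; Monte-Carlo (200k triplets) puts
        # per-protein removal probability at ~0.94, so ≥85% removal is ~4 sd
        # safe at this n, while bulk CV 0.1 proteins never cross 0.8
        cfg = SimConfig(
            n_human=500, n_mouse=0, cv_bulk=0.1, cv_tail=1.2,
            cv_tail_fraction=0.2, dropout=False, de_fraction=0.0, seed=13,
        )
        table, truth = simulate_quant(cfg)
        kept, _ = cv_filter(table, threshold=0.8)
        kept_ids = set(kept.protein_ids)
        tail = truth.table[truth.table["high_cv"]]["protein_id"]
        bulk = truth.table[~truth.table["high_cv"]]["protein_id"]
        removed_tail = sum(pid not in kept_ids for pid in tail) / len(tail)
        retained_bulk = sum(pid in kept_ids for pid in bulk) / len(bulk)
        assert removed_tail >= 0.85
        assert retained_bulk >= 0.99


class TestAggregate:
    def _presence_row(self, n_a: int, n_i: int) -> list:
        row = [100.0] * n_a + [None] * (9 - n_a)
        row += [100.0] * n_i + [None] * (9 - n_i)
        return row

    @pytest.mark.parametrize(
        "n_a,n_i,kept",
        [
            (6, 9, True),   # 6-of-9 in A, full in I
            (9, 5, False),  # fails the I condition
            (5, 5, False),
            (9, 9, True),
        ],
    )
    def test_presence_rule(self, n_a, n_i, kept):
        table = make_table({"P1": self._presence_row(n_a, n_i)})
        agg, _ = aggregate(table, presence_min=6, presence_total=9)
        assert (agg.n_proteins == 1) is kept

    def test_common_flag_requires_full_presence(self):
        table = make_table(
            {"FULL": self._presence_row(9, 9), "PART": self._presence_row(7, 9)}
        )
        agg, common = aggregate(table)
        assert set(agg.protein_ids) == {"FULL", "PART"}
        assert bool(common["FULL"]) and not bool(common["PART"])

    def test_common_subset_of_aggregated(self):
        cfg = SimConfig(n_human=200, n_mouse=0, seed=14)
        table, _ = simulate_quant(cfg)
        agg, common = aggregate(table)
        assert set(common.index) == set(agg.protein_ids)

    def test_grid_mismatch_rejected(self):
        table = make_table(
            {"P1": [1.0] * 4},
            columns=["A_s1_r1", "A_s1_r2", "I_s1_r1", "I_s1_r2"],
        )
        with pytest.raises(ValueError, match="presence_total"):
            aggregate(table, presence_min=6, presence_total=9)

    def test_survivors_match_naive_enumeration(self):
        # independent oracle: count present cells per condition per protein
        cfg = SimConfig(n_human=300, n_mouse=100, seed=15)
        table, _ = simulate_quant(cfg)
        agg, _ = aggregate(table)
        expected = []
        for pid in table.protein_ids:
            row = table.values.loc[pid]
            n_a = sum(
                not np.isnan(row[c]) for c in row.index if c.startswith("A")
            )
            n_i = sum(
                not np.isnan(row[c]) for c in row.index if c.startswith("I")
            )
            if n_a >= 6 and n_i >= 6:
                expected.append(pid)
        assert agg.protein_ids == expected
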