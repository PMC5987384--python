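"""Contingency tests, conservation proxy and the rank-sum test."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosphoage.cohort_stats import (
    AnalysisError,
    column_conservation_rate,
    contingency_test,
    exact_multivariate_hypergeom_p,
    module_age_comparison,
    proportion_by_age,
    rank_sum_test,
)

from conftest import make_alignment
from oracles import fisher_2x2_enumeration, pearson_chi2_formula


def sites_frame(records: list[dict]) -> pd.DataFrame:
    base = {
        "family": "f",
        "position": 1,
        "residue": "S",
        "functional": False,
        "polymorphic": False,
        "module": "NA",
        "age_group": "old",
        "structure": "disordered",
        "is_phospho": True,
    }
    return pd.DataFrame([{**base, **r} for r in records])


class TestChiSquared:
    @pytest.mark.parametrize(
        "table",
        [
            [[30, 70], [15, 85], [5, 95]],
            [[10, 10], [10, 10]],
            [[3, 9], [12, 2]],
            [[50, 1], [2, 40], [7, 7]],
        ],
    )
    def test_statistic_matches_direct_formula(self, table):
        result = contingency_test(np.array(table))
        assert result.statistic == pytest.approx(pearson_chi2_formula(table))

    def test_uniform_table_gives_zero(self):
        result = contingency_test(np.array([[10, 10], [10, 10]]))
        assert result.statistic == pytest.approx(0.0)
        assert result.pvalue == pytest.approx(1.0)

    def test_exact_fallback_on_sparse_table(self):
        result = contingency_test(np.array([[1, 0], [0, 12]]))
        assert result.test == "exact"
        # oracle: conditional two-sided Fisher on the same table
        assert result.pvalue == pytest.approx(
            fisher_2x2_enumeration([[1, 0], [0, 12]])
        )

    def test_exact_matches_fisher_on_2x2(self):
        for table in ([[2, 5], [6, 1]], [[4, 0], [1, 3]]):
            p_exact = exact_multivariate_hypergeom_p(np.array(table))
            _, p_fisher = stats.fisher_exact(table)
            assert p_exact == pytest.approx(p_fisher)

    def test_row_order_invariance(self):
        a = contingency_test(np.array([[30, 70], [5, 95], [15, 85]]))
        b = contingency_test(np.array([[5, 95], [30, 70], [15, 85]]))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)


class TestProportionByAge:
    def test_equal_proportions_null(self):
        records = []
        for group in ("old", "median", "young"):
            records += [{"age_group": group, "functional": True}] * 10
            records += [{"age_group": group, "functional": False}] * 30
        result = proportion_by_age(sites_frame(records), "functional")
        assert result.statistic == pytest.approx(0.0)
        assert result.pvalue == pytest.approx(1.0)

    def test_planted_age_gradient_detected(self, rng):
        records = []
        for group, p in [("old", 0.30), ("median", 0.15), ("young", 0.05)]:
            flags = rng.random(500) < p
            records += [
                {"age_group": group, "functional": bool(f)} for f in flags
            ]
        result = proportion_by_age(sites_frame(records), "functional")
        assert result.pvalue < 0.01

    def test_empty_group_dropped_with_note(self):
        records = [{"age_group": "old", "functional": True}] * 5
        records += [{"age_group": "old", "functional": False}] * 5
        records += [{"age_group": "young", "functional": False}] * 10
        result = proportion_by_age(sites_frame(records), "functional")
        assert "median" in result.note

    def test_counts_conserved(self):
        records = [{"age_group": g, "functional": f}
                   for g in ("old", "young") for f in (True, False)] * 3
        result = proportion_by_age(sites_frame(records), "functional")
        assert int(result.table.to_numpy().sum()) == len(records)


class TestModuleComparison:
    def test_balanced_fisher_is_one(self):
        records = []
        for module in ("BFM", "VFM"):
            for func in (True, False):
                records += [
                    {"module": module, "age_group": "young", "functional": func}
                ] * 5
            records += [{"module": module, "age_group": "old"}] * 5
        _, young = module_age_comparison(sites_frame(records))
        assert young.pvalue == pytest.approx(1.0)

    def test_perfect_separation_matches_hypergeometric(self):
        records = [{"module": "BFM", "age_group": "young", "functional": True}] * 10
        records += [{"module": "VFM", "age_group": "young", "functional": False}] * 10
        # pad other groups so the module-by-age table is testable
        records += [{"module": m, "age_group": "old"} for m in ("BFM", "VFM")] * 5
        _, young = module_age_comparison(sites_frame(records))
        assert young.pvalue == pytest.approx(2 / comb(20, 10))

    def test_identical_age_distributions_null(self):
        records = []
        for module in ("BFM", "VFM"):
            for group in ("old", "median", "young"):
                records += [{"module": module, "age_group": group}] * 8
        age_cmp, _ = module_age_comparison(sites_frame(records))
        assert age_cmp.statistic == pytest.approx(0.0)

    def test_all_na_modules_raise(self):
        with pytest.raises(AnalysisError):
            module_age_comparison(sites_frame([{"module": "NA"}] * 10))


class TestConservationRate:
    def test_identical_column_is_zero(self):
        aln = make_alignment({"F": "S", "G": "S", "H": "S"}, focal="F")
        assert column_conservation_rate(aln, 0) == 0.0

    def test_direct_count(self):
        seqs = {"F": "S"}
        for i, ch in enumerate("SSSSDDE"):  # 4 match, 3 differ
            seqs[f"o{i}"] = ch
        aln = make_alignment(seqs, focal="F")
        assert column_conservation_rate(aln, 0) == pytest.approx(3 / 7)

    def test_gaps_excluded(self):
        aln = make_alignment({"F": "S", "G": "-", "H": "D"}, focal="F")
        assert column_conservation_rate(aln, 0) == pytest.approx(1.0)

    def test_no_usable_orthologs_is_nan(self):
        aln = make_alignment({"F": "S", "G": "-"}, focal="F")
        assert np.isnan(column_conservation_rate(aln, 0))

    def test_slower_module_shows_lower_rates(self, rng):
        """VFM proteins evolve at half the BFM substitution rate; the
        mismatch-fraction proxy detects VFM < BFM by rank-sum at
        300 columns per module."""
        from phosphoage.synthetic_data import GeneratorConfig, generate_dataset

        config = GeneratorConfig(
            n_families=30, n_phospho_sites=100, n_control_sites=0,
            background_columns=30,
        )
        dataset = generate_dataset(config, seed=19)
        module_of = {
            fam: dataset.sites.loc[dataset.sites["family"] == fam, "module"].iloc[0]
            for fam in dataset.alignments
        }
        rates: dict[str, list[float]] = {"BFM": [], "VFM": []}
        for fam, aln in dataset.alignments.items():
            for col in range(config.background_columns):
                rate = column_conservation_rate(aln, col)
                if rate == rate:
                    rates[module_of[fam]].append(rate)
        sub = {k: rng.choice(v, size=300, replace=False) for k, v in rates.items()}
        result = rank_sum_test(sub["VFM"], sub["BFM"], alternative="less")
        assert result.pvalue < 0.01


class TestRankSum:
    def test_exact_enumeration_separated_samples(self):
        result = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert result.test == "rank_sum_exact"
        assert result.pvalue == pytest.approx(2 / 20)

    def test_identical_samples(self):
        result = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert result.pvalue == pytest.approx(1.0)

    def test_two_sided_symmetry(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=15)
        assert rank_sum_test(a, b).pvalue == pytest.approx(
            rank_sum_test(b, a).pvalue
        )

    def test_exact_agrees_with_normal_approximation(self, rng):
        """At n = 8 per group the exact and approximate p differ < 0.02."""
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(0.5, size=8)
            exact = rank_sum_test(a, b).pvalue
            mw = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            )
            assert abs(exact - mw.pvalue) < 0.02

    def test_one_sided_alternatives(self):
        greater = rank_sum_test([10, 11, 12], [1, 2, 3], alternative="greater")
        less = rank_sum_test([10, 11, 12], [1, 2, 3], alternative="less")
        assert greater.pvalue == pytest.approx(1 / 20)
        assert less.pvalue == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(AnalysisError):
            rank_sum_test([], [1.0])
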