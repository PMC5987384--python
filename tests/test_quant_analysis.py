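"""Tissue-level summaries, covariate ANOVA, stepwise selection, correlation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosphoage.cohort_stats import AnalysisError
from phosphoage.io_formats import InputError
from phosphoage.quant_analysis import (
    compare_groups_quant,
    covariate_anova,
    level_breadth_correlation,
    low_low_enrichment,
    stepwise_selection,
    summarize_quant,
)
from phosphoage.synthetic_data import GeneratorConfig, generate_quant


def quant_frame(levels: list[list[float]]) -> pd.DataFrame:
    df = pd.DataFrame(
        {"family": "f", "position": range(1, len(levels) + 1)}
    )
    for t in range(9):
        df[f"tissue_{t + 1}"] = [row[t] for row in levels]
    df["protein_abundance"] = 1.0
    df["protein_breadth"] = 5
    return df


def dated_frame(n: int, groups: list[str] | None = None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": "f",
            "position": range(1, n + 1),
            "is_phospho": True,
            "structure": "disordered",
            "age_group": groups if groups is not None else ["old"] * n,
            "origin": "D",
            "residue": "S",
        }
    )


def summaries_from_generator(
    config: GeneratorConfig, n: int, seed: int, groups: np.ndarray | None = None
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = rng.choice(["old", "median", "young"], size=n)
    truth = pd.DataFrame(
        {"family": "f", "position": range(1, n + 1), "is_phospho": True,
         "group": groups}
    )
    quant = generate_quant(truth, config, rng)
    dated = dated_frame(n, list(groups))
    return summarize_quant(quant, dated)


class TestSummarize:
    def test_max_and_breadth(self):
        quant = quant_frame([[0, 0, 5, 2, 0, 0, 0, 0, 0],
                             [0] * 9])
        summaries = summarize_quant(quant, dated_frame(2))
        assert summaries.loc[0, "max_level"] == 5
        assert summaries.loc[0, "breadth"] == 2
        assert summaries.loc[1, "max_level"] == 0
        assert summaries.loc[1, "breadth"] == 0

    def test_breadth_zero_iff_max_zero(self, small_config):
        summaries = summaries_from_generator(small_config, 500, seed=8)
        assert ((summaries["max_level"] == 0) == (summaries["breadth"] == 0)).all()
        assert summaries["breadth"].between(0, 9).all()

    def test_duplicate_keys_rejected(self):
        quant = quant_frame([[1] * 9, [1] * 9])
        quant["position"] = [1, 1]
        with pytest.raises(InputError, match="duplicate"):
            summarize_quant(quant, dated_frame(2))

    def test_group_sizes_match_generator(self, small_config, rng):
        groups = rng.choice(["old", "young"], size=400)
        summaries = summaries_from_generator(
            small_config, 400, seed=3, groups=groups
        )
        counts = summaries["age_group"].value_counts()
        assert counts["old"] == (groups == "old").sum()
        assert counts["young"] == (groups == "young").sum()


class TestGroupComparisons:
    def test_planted_old_young_effect_detected(self, small_config):
        summaries = summaries_from_generator(small_config, 1000, seed=5)
        results = compare_groups_quant(summaries)
        assert results["max_level"].pvalue < 0.01
        assert results["breadth"].pvalue < 0.01
        assert results["protein_abundance"].pvalue > 0.01

    def test_identical_distributions_null(self):
        levels = [[1, 2, 0, 0, 0, 0, 0, 0, 0]] * 40
        quant = quant_frame(levels)
        dated = dated_frame(40, ["old", "young"] * 20)
        results = compare_groups_quant(summarize_quant(quant, dated))
        assert results["max_level"].pvalue == pytest.approx(1.0)


class TestCovariateAnova:
    def test_group_effect_beyond_protein_breadth(self, small_config):
        summaries = summaries_from_generator(small_config, 1000, seed=6)
        result = covariate_anova(summaries)
        assert result.pvalue < 0.01

    def test_constant_covariate_reduces_to_one_way(self, rng):
        n = 120
        groups = rng.choice(["old", "young"], size=n)
        breadth = rng.integers(0, 10, size=n) + (groups == "old") * 2
        df = pd.DataFrame(
            {"breadth": breadth, "protein_breadth": 5, "age_group": groups}
        )
        result = covariate_anova(df)
        f, p = stats.f_oneway(
            df.loc[df.age_group == "old", "breadth"],
            df.loc[df.age_group == "young", "breadth"],
        )
        assert result.statistic == pytest.approx(f)
        assert result.pvalue == pytest.approx(p)
        assert "one-way" in result.note

    def test_null_calibration(self, rng):
        """Group independent of breadth: p should not be systematically small."""
        pvals = []
        for _ in range(50):
            n = 150
            df = pd.DataFrame(
                {
                    "breadth": rng.integers(0, 10, size=n),
                    "protein_breadth": rng.integers(0, 10, size=n),
                    "age_group": rng.choice(["old", "median", "young"], size=n),
                }
            )
            pvals.append(covariate_anova(df).pvalue)
        assert np.mean(np.array(pvals) < 0.05) < 0.2


class TestStepwise:
    def test_no_signal_retains_nothing_usually(self, rng):
        retained = 0
        for _ in range(40):
            n = 200
            df = pd.DataFrame(
                {
                    "max_level": rng.normal(size=n),
                    "breadth": rng.integers(0, 10, size=n),
                    "age_group": rng.choice(["old", "median", "young"], size=n),
                }
            )
            entered, _ = stepwise_selection(df)
            retained += bool(entered)
        # under the null each candidate clears the AIC bar with
        # P(chi2_1 > 2) ~ 0.157, so some spurious retention is expected,
        # but it must stay near that rate (two candidates -> ~29%)
        assert retained / 40 <= 0.55

    def test_single_predictor_definition(self, rng):
        n = 200
        breadth = rng.integers(0, 10, size=n)
        score = breadth + rng.normal(0, 2, size=n)
        groups = np.where(score > np.quantile(score, 2 / 3), "old",
                          np.where(score > np.quantile(score, 1 / 3),
                                   "median", "young"))
        df = pd.DataFrame(
            {"breadth": breadth, "age_group": groups,
             "max_level": rng.normal(size=n)}
        )
        entered, trace = stepwise_selection(df, predictors=("breadth",))
        assert entered == ["breadth"]
        assert trace["breadth"] < trace["null"]

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame(
            {"max_level": [1.0] * 5, "breadth": [2] * 5, "age_group": ["old"] * 5}
        )
        with pytest.raises(AnalysisError):
            stepwise_selection(df)


class TestCorrelation:
    def test_perfect_correlation(self):
        df = pd.DataFrame({"max_level": [1, 2, 3, 4.0], "breadth": [1, 2, 3, 4]})
        r, n = level_breadth_correlation(df)
        assert r == pytest.approx(1.0) and n == 4

    def test_permuted_levels_uncorrelated(self, small_config, rng):
        summaries = summaries_from_generator(small_config, 2000, seed=9)
        shuffled = summaries.copy()
        shuffled["max_level"] = rng.permutation(shuffled["max_level"].to_numpy())
        r, _ = level_breadth_correlation(shuffled)
        assert abs(r) < 0.05

    def test_zero_variance_is_nan(self):
        df = pd.DataFrame({"max_level": [2.0] * 5, "breadth": [1, 2, 3, 4, 5]})
        r, _ = level_breadth_correlation(df)
        assert np.isnan(r)


class TestLowLow:
    def test_identical_distributions_null(self):
        patterns = [
            [1, 0, 0, 0, 0, 0, 0, 0, 0],          # low level, low breadth
            [5, 5, 5, 5, 5, 0, 0, 0, 0],
            [9, 9, 9, 9, 9, 9, 9, 9, 9],
        ]
        levels = [p for p in patterns for _ in range(10)] * 2
        quant = quant_frame(levels)
        dated = dated_frame(60, ["old"] * 30 + ["young"] * 30)
        result = low_low_enrichment(summarize_quant(quant, dated))
        assert result is not None
        assert result.pvalue == pytest.approx(1.0)

    def test_planted_young_excess_detected(self, small_config):
        summaries = summaries_from_generator(small_config, 1000, seed=10)
        result = low_low_enrichment(summaries)
        assert result is not None
        young = result.table.loc["young", True] / result.table.loc["young"].sum()
        old = result.table.loc["old", True] / result.table.loc["old"].sum()
        assert young > old

    def test_quantile_zero_skips(self, small_config):
        summaries = summaries_from_generator(small_config, 200, seed=2)
        assert low_low_enrichment(summaries, quantile=0.0) is None
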