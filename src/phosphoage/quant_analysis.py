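"""Tissue-level phosphorylation analyses across evolutionary age groups.

Per site the nine-tissue quantification is summarised by the maximum
phosphorylation level and the phosphorylation breadth (number of tissues
with a nonzero level).  The analyses compare these between age groups,
control for protein abundance/breadth, and quantify the level-breadth
coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .cohort_stats import AnalysisError, GroupComparison, contingency_test, rank_sum_test
from .io_formats import InputError

logger = logging.getLogger(__name__)

DEFAULT_LOW_QUANTILE = 1.0 / 3.0
AGE_CODES = {"young": 0, "median": 1, "old": 2}


def summarize_quant(
    quant: pd.DataFrame,
    dated_sites: pd.DataFrame,
    n_tissues: int = 9,
    disordered_only: bool = True,
) -> pd.DataFrame:
    """Join quantification to dated sites and summarise per site.

    Keeps dated phosphosites (disordered only by default, where the age
    signal concentrates), computing ``max_level`` (maximum level across
    tissues) and ``breadth`` (tissues with level > 0).  Join losses are
    logged; duplicate site keys are an input error.
    """
    keys = ["family", "position"]
    if quant.duplicated(keys).any():
        dups = quant[quant.duplicated(keys, keep=False)][keys].head()
        raise InputError(f"duplicate site keys in quant table:\n{dups}")

    dated = dated_sites[dated_sites["is_phospho"]]
    if disordered_only:
        dated = dated[dated["structure"] == "disordered"]

    tissue_cols = [f"tissue_{i}" for i in range(1, n_tissues + 1)]
    merged = quant.merge(
        dated[keys + ["age_group", "origin", "residue"]], on=keys, how="inner"
    )
    lost = len(quant) - len(merged)
    if lost:
        logger.info("summarize_quant: %d quant rows without a dated site", lost)

    levels = merged[tissue_cols].to_numpy(float)
    merged["max_level"] = levels.max(axis=1)
    merged["breadth"] = (levels > 0).sum(axis=1)
    return merged[
        keys
        + ["age_group", "origin", "residue", "max_level", "breadth",
           "protein_abundance", "protein_breadth"]
    ]


def compare_groups_quant(
    summaries: pd.DataFrame,
) -> dict[str, GroupComparison]:
    """Young-vs-old rank-sum tests for level, breadth and protein abundance.

    The protein-abundance comparison is the negative control: a group
    difference in phosphorylation level is only interpretable if abundance
    shows none.  Comparisons with a missing or singleton group are skipped
    with a log entry.
    """
    out: dict[str, GroupComparison] = {}
    old = summaries[summaries["age_group"] == "old"]
    young = summaries[summaries["age_group"] == "young"]
    for label, col in [
        ("max_level", "max_level"),
        ("breadth", "breadth"),
        ("protein_abundance", "protein_abundance"),
    ]:
        if len(old) < 2 or len(young) < 2:
            logger.info("compare_groups_quant: skipping %s (group too small)", label)
            continue
        cmp = rank_sum_test(young[col], old[col], alternative="two-sided")
        cmp.name = f"young_vs_old_{label}"
        out[label] = cmp
    return out


def covariate_anova(summaries: pd.DataFrame) -> GroupComparison:
    """Sequential ANOVA: age-group effect on phospho breadth after protein breadth.

    Fits ``breadth ~ protein_breadth + C(age_group)`` and returns the F-test
    for the group term with the covariate entered first, i.e. whether the
    age groups still differ in phosphorylation breadth once the protein's
    own expression breadth is accounted for.  A constant covariate reduces
    the model to a one-way ANOVA on the group factor.
    """
    needed = ["breadth", "protein_breadth", "age_group"]
    df = summaries[needed].dropna()
    if df.empty:
        raise AnalysisError("covariate_anova: no complete cases")
    if df["age_group"].nunique() < 2:
        raise AnalysisError("covariate_anova: need at least two age groups")

    degenerate = df["protein_breadth"].nunique() == 1
    formula = (
        "breadth ~ C(age_group)"
        if degenerate
        else "breadth ~ protein_breadth + C(age_group)"
    )
    model = smf.ols(formula, data=df).fit()
    if not degenerate and np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise AnalysisError(
            "covariate_anova: rank-deficient design "
            "(protein_breadth collinear with age group)"
        )
    anova = sm.stats.anova_lm(model, typ=1)
    row = anova.loc["C(age_group)"]
    return GroupComparison(
        name="breadth_anova_group_after_protein_breadth",
        test="anova_F",
        statistic=float(row["F"]),
        pvalue=float(row["PR(>F)"]),
        n=len(df),
        note="one-way (constant covariate)" if degenerate else "",
    )


def stepwise_selection(
    summaries: pd.DataFrame,
    predictors: tuple[str, ...] = ("max_level", "breadth"),
) -> tuple[list[str], dict[str, float]]:
    """Forward AIC selection of quantitative predictors of evolutionary age.

    The response is the age group coded ordinally (young 0, median 1,
    old 2).  Predictors enter one at a time, each step adding the candidate
    with the largest AIC improvement; selection stops when no candidate
    improves the AIC.  Returns the ordered list of entered predictors and
    the AIC trace (null model plus each accepted step).
    """
    df = summaries[list(predictors) + ["age_group"]].dropna()
    if len(df) < 10:
        raise AnalysisError(
            f"stepwise_selection: need >= 10 sites, got {len(df)}"
        )
    y = df["age_group"].map(AGE_CODES)
    if y.isna().any():
        raise InputError("age_group contains labels other than young/median/old")
    y = y.astype(float)

    entered: list[str] = []
    remaining = list(predictors)
    X0 = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    current_aic = sm.OLS(y, X0).fit().aic
    trace = {"null": float(current_aic)}

    while remaining:
        best_aic, best_pred = None, None
        for pred in remaining:
            X = sm.add_constant(df[entered + [pred]])
            aic = sm.OLS(y, X).fit().aic
            if best_aic is None or aic < best_aic:
                best_aic, best_pred = aic, pred
        if best_aic is not None and best_aic < current_aic:
            entered.append(best_pred)
            remaining.remove(best_pred)
            current_aic = best_aic
            trace[best_pred] = float(best_aic)
        else:
            break
    return entered, trace


def level_breadth_correlation(summaries: pd.DataFrame) -> tuple[float, int]:
    """Pooled Pearson correlation between maximum level and breadth.

    Requires at least three sites detected in at least one tissue; returns
    ``(nan, n)`` when either variable has zero variance.
    """
    df = summaries[["max_level", "breadth"]].dropna()
    if (df["breadth"] > 0).sum() < 3:
        raise AnalysisError(
            "level_breadth_correlation: need >= 3 sites with breadth > 0"
        )
    if df["max_level"].nunique() == 1 or df["breadth"].nunique() == 1:
        return float("nan"), len(df)
    r, _ = stats.pearsonr(df["max_level"], df["breadth"])
    return float(r), len(df)


def low_low_enrichment(
    summaries: pd.DataFrame, quantile: float = DEFAULT_LOW_QUANTILE
) -> GroupComparison | None:
    """Old-vs-young enrichment of jointly low-level, low-breadth sites.

    "Low" means the site's pooled empirical CDF value is at most
    ``quantile`` for both maximum level and breadth (bottom tertile by
    default).  Returns ``None`` (with a log entry) when the low-low set is
    empty or the quantile is degenerate.
    """
    if not 0.0 <= quantile <= 1.0:
        raise InputError(f"quantile {quantile} outside [0, 1]")
    df = summaries[summaries["age_group"].isin(["old", "young"])].copy()
    if df.empty:
        raise AnalysisError("low_low_enrichment: no old/young sites")

    def ecdf_le(x: pd.Series) -> pd.Series:
        vals = x.to_numpy(float)
        return pd.Series(
            stats.rankdata(vals, method="max") / len(vals), index=df.index
        )

    low_level = ecdf_le(df["max_level"]) <= quantile
    low_breadth = ecdf_le(df["breadth"]) <= quantile
    df["low_low"] = low_level & low_breadth
    if not df["low_low"].any():
        logger.info(
            "low_low_enrichment: empty low-low set at quantile %.3g; skipped",
            quantile,
        )
        return None
    table = pd.crosstab(df["age_group"], df["low_low"])
    table = table.reindex(index=["old", "young"], columns=[True, False], fill_value=0)
    result = contingency_test(table, name="low_low_by_age")
    result.name = "low_low_by_age"
    return result
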