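"""Age-group proportion tests, module comparisons and rank-based tests.

Conventions shared by every test here:

* Pearson chi-squared without Yates correction (the 3x2 tables make the
  correction inapplicable anyway); when any expected count drops below 1 an
  exact conditional test on the same margins is substituted and noted.
* Fisher's exact test is two-sided.
* The Wilcoxon rank-sum test uses mid-ranks for ties, exact enumeration of
  arrangements when both samples have at most 8 observations, and the
  normal approximation with tie correction otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GAP, InputError, OrthologAlignment

EXACT_RANKSUM_MAX_N = 8
EXACT_TABLE_MAX_TOTAL = 400


class AnalysisError(ValueError):
    """An analysis cannot run on the given data (empty group, etc.)."""


@dataclass
class GroupComparison:
    """A contingency table or two-sample comparison with its test result."""

    name: str
    test: str
    statistic: float
    pvalue: float
    n: int
    table: pd.DataFrame | None = None
    note: str = ""

    def as_row(self) -> dict:
        return {
            "analysis": self.name,
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "n": self.n,
            "note": self.note,
        }


# ---------------------------------------------------------------------------
# chi-squared with exact small-count fallback
# ---------------------------------------------------------------------------


def pearson_chi2(table: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Pearson chi-squared statistic, p and expected counts (no Yates)."""
    table = np.asarray(table, dtype=float)
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), expected


def exact_multivariate_hypergeom_p(table: np.ndarray) -> float:
    """Conditional exact p for an r x c table (Freeman-Halton style).

    Enumerates every table with the observed margins and sums the
    multivariate hypergeometric probabilities of tables no more probable
    than the observed one.  Feasible for the small totals where it is used.
    """
    table = np.asarray(table, dtype=int)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    total = int(table.sum())
    if total > EXACT_TABLE_MAX_TOTAL:
        raise AnalysisError(
            f"exact test infeasible for table total {total} > "
            f"{EXACT_TABLE_MAX_TOTAL}"
        )

    log_fact = [math.lgamma(i + 1) for i in range(total + 1)]
    const = (
        sum(log_fact[s] for s in row_sums)
        + sum(log_fact[s] for s in col_sums)
        - log_fact[total]
    )

    def log_prob(cells: tuple[int, ...]) -> float:
        return const - sum(log_fact[c] for c in cells)

    obs_lp = log_prob(tuple(int(x) for x in table.ravel()))

    r, c = table.shape
    p_total = 0.0

    def recurse(row: int, remaining_cols: list[int], cells: list[int]) -> None:
        nonlocal p_total
        if row == r - 1:
            # last row is forced by the column margins
            last = remaining_cols
            if any(v < 0 for v in last):
                return
            if sum(last) != row_sums[row]:
                return
            lp = log_prob(tuple(cells + last))
            if lp <= obs_lp + 1e-9:
                p_total += math.exp(lp)
            return

        target = row_sums[row]

        def fill(col: int, left: int, row_cells: list[int]) -> None:
            if col == c - 1:
                if left <= remaining_cols[col]:
                    new_remaining = [
                        remaining_cols[i] - (row_cells + [left])[i]
                        for i in range(c)
                    ]
                    recurse(row + 1, new_remaining, cells + row_cells + [left])
                return
            for v in range(min(left, remaining_cols[col]) + 1):
                fill(col + 1, left - v, row_cells + [v])

        fill(0, int(target), [])

    recurse(0, [int(s) for s in col_sums], [])
    return min(1.0, p_total)


def contingency_test(
    table: pd.DataFrame | np.ndarray, name: str = "contingency"
) -> GroupComparison:
    """Chi-squared independence test with exact fallback on sparse tables."""
    frame = table if isinstance(table, pd.DataFrame) else pd.DataFrame(np.asarray(table))
    arr = frame.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise AnalysisError(f"{name}: table must be at least 2x2, got {arr.shape}")
    n = int(arr.sum())
    note = ""
    # all-zero margins make expected counts degenerate; drop them first
    keep_rows = arr.sum(axis=1) > 0
    keep_cols = arr.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        frame = frame.loc[keep_rows, keep_cols]
        arr = frame.to_numpy(dtype=float)
        note = "dropped all-zero rows/columns"
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            return GroupComparison(
                name=name, test="chi2", statistic=0.0, pvalue=1.0, n=n,
                table=frame, note=note + "; table degenerate after dropping",
            )
    stat, p, expected = pearson_chi2(arr)
    test = "chi2"
    if (expected < 1).any():
        note = (note + "; " if note else "") + (
            "expected count < 1; exact conditional test substituted"
        )
        p = exact_multivariate_hypergeom_p(arr.astype(int))
        test = "exact"
    return GroupComparison(
        name=name, test=test, statistic=stat, pvalue=p, n=n,
        table=frame, note=note,
    )


# ---------------------------------------------------------------------------
# age-group proportion tests
# ---------------------------------------------------------------------------

AGE_ORDER = ["old", "median", "young"]


def proportion_by_age(sites: pd.DataFrame, flag: str) -> GroupComparison:
    """3x2 table of a boolean annotation flag across age groups + chi-squared.

    Age groups with zero sites are dropped with a note (the test needs at
    least two non-empty groups).
    """
    if flag not in sites.columns:
        raise InputError(f"no column {flag!r} in site table")
    counts = []
    kept_groups = []
    dropped = []
    for group in AGE_ORDER:
        sub = sites[sites["age_group"] == group]
        if len(sub) == 0:
            dropped.append(group)
            continue
        flagged = int(sub[flag].sum())
        counts.append([flagged, len(sub) - flagged])
        kept_groups.append(group)
    if len(kept_groups) < 2:
        raise AnalysisError(
            f"proportion_by_age({flag}): fewer than two non-empty age groups"
        )
    frame = pd.DataFrame(
        counts, index=kept_groups, columns=[flag, f"not_{flag}"]
    )
    result = contingency_test(frame, name=f"{flag}_by_age")
    if dropped:
        result.note = (result.note + f"; dropped empty groups {dropped}").lstrip("; ")
    return result


def module_age_comparison(
    sites: pd.DataFrame,
) -> tuple[GroupComparison, GroupComparison]:
    """BFM-vs-VFM age-distribution test and young-group functionality test.

    Returns (chi-squared on the module x age-group table, two-sided Fisher
    exact on the 2x2 module x functional table restricted to young sites).
    Sites with module ``NA`` are excluded.
    """
    labelled = sites[sites["module"].isin(["BFM", "VFM"])]
    if labelled.empty:
        raise AnalysisError("module_age_comparison: no BFM/VFM-labelled sites")

    age_table = pd.crosstab(labelled["module"], labelled["age_group"])
    age_table = age_table.reindex(
        index=["BFM", "VFM"],
        columns=[g for g in AGE_ORDER if g in age_table.columns],
        fill_value=0,
    )
    age_cmp = contingency_test(age_table, name="module_by_age")

    young = labelled[labelled["age_group"] == "young"]
    table = pd.crosstab(young["module"], young["functional"])
    table = table.reindex(index=["BFM", "VFM"], columns=[True, False], fill_value=0)
    odds, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    young_cmp = GroupComparison(
        name="young_functional_by_module",
        test="fisher",
        statistic=float(odds),
        pvalue=float(p),
        n=int(table.to_numpy().sum()),
        table=table,
    )
    return age_cmp, young_cmp


# ---------------------------------------------------------------------------
# conservation proxy
# ---------------------------------------------------------------------------


def column_conservation_rate(
    alignment: OrthologAlignment, column_index: int
) -> float:
    """Fraction of non-gap ortholog residues differing from the focal residue.

    A per-column mismatch fraction in [0, 1]: 0 means perfectly conserved.
    Monotone in substitution count, it serves as the evolutionary-rate proxy
    for module-level conservation comparisons.  Requires the focal residue
    plus at least one non-gap ortholog; returns ``nan`` otherwise so callers
    can exclude the site.
    """
    col = alignment.column(column_index)
    focal_char = col[alignment.focal_species]
    if focal_char == GAP:
        return float("nan")
    others = [
        ch
        for sp, ch in col.items()
        if sp != alignment.focal_species and ch != GAP
    ]
    if not others:
        return float("nan")
    return sum(1 for ch in others if ch != focal_char) / len(others)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _rank_sum_statistic(pooled_ranks: np.ndarray, n_a: int) -> float:
    return float(pooled_ranks[:n_a].sum())


def rank_sum_test(
    a, b, alternative: str = "two-sided"
) -> GroupComparison:
    """Wilcoxon rank-sum (Mann-Whitney) test with mid-rank tie handling.

    Exact enumeration over all arrangements when both samples have at most
    8 observations; otherwise the normal approximation with tie correction.
    The alternative is relative to sample ``a`` ("greater" means ``a``
    stochastically larger).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise AnalysisError("rank_sum_test: both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise InputError(f"unknown alternative {alternative!r}")

    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks
    w_obs = _rank_sum_statistic(ranks, n_a)
    mu = n_a * (n_a + n_b + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return GroupComparison(
            name="rank_sum", test="rank_sum", statistic=w_obs, pvalue=1.0,
            n=n_a + n_b, note="all values tied across both samples",
        )

    if n_a <= EXACT_RANKSUM_MAX_N and n_b <= EXACT_RANKSUM_MAX_N:
        total = 0
        count = 0
        eps = 1e-9
        delta = abs(w_obs - mu)
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            w = ranks[list(combo)].sum()
            total += 1
            if alternative == "two-sided":
                hit = abs(w - mu) >= delta - eps
            elif alternative == "greater":
                hit = w >= w_obs - eps
            else:
                hit = w <= w_obs + eps
            if hit:
                count += 1
        return GroupComparison(
            name="rank_sum", test="rank_sum_exact", statistic=w_obs,
            pvalue=count / total, n=n_a + n_b,
        )

    # normal approximation with tie correction
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return GroupComparison(
            name="rank_sum", test="rank_sum_normal", statistic=w_obs, pvalue=1.0,
            n=n, note="zero variance under ties",
        )
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = (abs(w_obs - mu) - 0.5) / sd
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (w_obs - mu - 0.5) / sd
        p = stats.norm.sf(z)
    else:
        z = (w_obs - mu + 0.5) / sd
        p = stats.norm.cdf(z)
    return GroupComparison(
        name="rank_sum", test="rank_sum_normal", statistic=w_obs,
        pvalue=float(min(1.0, p)), n=n,
    )


def report_frame(results: list[GroupComparison]) -> pd.DataFrame:
    """Flatten a list of comparisons into a one-row-per-test report table."""
    return pd.DataFrame([r.as_row() for r in results])
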