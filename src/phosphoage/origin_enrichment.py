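"""Ancestral-origin enrichment of phosphosites versus control residues.

Tests whether the amino acids that phospho-acceptors evolved *from* (their
ancestral origins, e.g. the phosphomimetic Asp/Glu or Lys) are
over-represented among phosphosites relative to non-phosphorylated S/T/Y
sites on the same proteins, via bootstrap resampling of the control pool
with the disordered/ordered composition balanced to the phosphosite set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .age_dating import ORIGIN_AMBIGUOUS, ORIGIN_UNKNOWN
from .cohort_stats import AnalysisError, GroupComparison, contingency_test
from .io_formats import AMINO_ACIDS, InputError

DEFAULT_BOOTSTRAP_B = 1000
DEFAULT_KINASE_SCORE_MAX = 2.0

ENRICHABLE_GROUPS = ("median", "young")


@dataclass
class EnrichmentTable:
    """Per-amino-acid bootstrap enrichment of ancestral origins.

    ``table`` has one row per amino acid with the observed phosphosite
    origin fraction, the bootstrap mean control fraction, their ratio, and
    the one-sided empirical p-value with +1 correction:
    ``p = (1 + #{b : f_b >= f_obs}) / (B + 1)``.
    """

    table: pd.DataFrame
    n_phospho: int
    n_control_pool: int
    bootstrap_B: int
    seed: int
    strata: tuple[str, ...] = ("structure",)
    bonferroni: bool = False
    #: per-stratum draw size of every bootstrap round (fixed across rounds,
    #: equal to the phosphosite set's stratum counts by construction)
    stratum_counts: dict[str, int] = field(default_factory=dict)

    def ratio(self, aa: str) -> float:
        return float(self.table.loc[aa, "ratio"])

    def pvalue(self, aa: str) -> float:
        return float(self.table.loc[aa, "pvalue"])


def resolved_origins(sites: pd.DataFrame) -> pd.DataFrame:
    """Rows whose origin is a concrete residue (not ambiguous/unknown)."""
    return sites[~sites["origin"].isin([ORIGIN_AMBIGUOUS, ORIGIN_UNKNOWN])]


def build_control_pool(
    dated_sites: pd.DataFrame,
    kinase_score_max: float = DEFAULT_KINASE_SCORE_MAX,
) -> pd.DataFrame:
    """Assemble the non-phosphosite control pool for enrichment testing.

    Controls are S/T/Y sites not known to be phosphorylated, drawn from the
    same proteins as the phosphosites and restricted to the median and
    young age groups (old-group origins are unpredictable).  Sites flagged
    in the PTM database analogue and sites with predicted kinase score
    strictly above ``kinase_score_max`` are excluded as likely
    unannotated phosphosites.
    """
    phospho_fams = set(dated_sites.loc[dated_sites["is_phospho"], "family"])
    pool = dated_sites[~dated_sites["is_phospho"]]
    counts = {"non_phospho": len(pool)}

    pool = pool[pool["family"].isin(phospho_fams)]
    counts["same_proteins"] = len(pool)

    pool = pool[pool["age_group"].isin(ENRICHABLE_GROUPS)]
    counts["median_young"] = len(pool)

    pool = pool[~pool["known_ptm_db"]]
    counts["not_in_ptm_db"] = len(pool)

    pool = pool[pool["kinase_score"] <= kinase_score_max]
    counts["kinase_score_ok"] = len(pool)

    if pool.empty:
        raise AnalysisError(
            f"control pool empty; sites surviving each filter: {counts}"
        )
    return pool


def _stratum_keys(df: pd.DataFrame, strata: tuple[str, ...]) -> pd.Series:
    key = df[strata[0]].astype(str)
    for col in strata[1:]:
        key = key + "|" + df[col].astype(str)
    return key


def bootstrap_enrichment(
    phospho: pd.DataFrame,
    control_pool: pd.DataFrame,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = 0,
    match_residue: bool = True,
    bonferroni: bool = False,
) -> EnrichmentTable:
    """Bootstrap test for enrichment of each ancestral origin amino acid.

    Each of the ``B`` bootstrap rounds draws, with replacement, as many
    controls as there are datable phosphosites, stratified on structure
    class (and residue type when ``match_residue``) so every draw's
    disordered:ordered composition equals the phosphosite set's exactly.
    Sites with ambiguous or unknown origins are excluded from both sets
    before fractions are computed, so observed fractions sum to 1.

    With ``bonferroni`` the p-values are additionally multiplied by 20
    (one test per amino acid), capped at 1.
    """
    if B < 1:
        raise InputError(f"bootstrap_B must be >= 1, got {B}")
    phospho = resolved_origins(phospho[phospho["is_phospho"]])
    pool = resolved_origins(control_pool)
    if phospho.empty:
        raise AnalysisError("no phosphosites with resolved origins")
    if pool.empty:
        raise AnalysisError("no control sites with resolved origins")

    strata: tuple[str, ...] = ("structure",) + (
        ("residue",) if match_residue else ()
    )
    ph_keys = _stratum_keys(phospho, strata)
    pool_keys = _stratum_keys(pool, strata)

    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    n_aa = len(AMINO_ACIDS)
    ph_codes = phospho["origin"].map(aa_index)
    if ph_codes.isna().any():
        bad = sorted(set(phospho["origin"]) - set(aa_index))
        raise InputError(f"unexpected origin states {bad}")

    obs_counts = np.bincount(ph_codes.to_numpy(int), minlength=n_aa)
    n_phospho = len(phospho)
    f_obs = obs_counts / n_phospho

    rng = np.random.default_rng(seed)
    boot_counts = np.zeros((B, n_aa), dtype=np.int64)
    offsets = n_aa * np.arange(B)[:, None]
    stratum_counts = {
        str(k): int(v) for k, v in ph_keys.value_counts().items()
    }
    for key, n_stratum in ph_keys.value_counts().items():
        stratum_codes = pool.loc[pool_keys == key, "origin"].map(aa_index)
        if stratum_codes.empty:
            raise AnalysisError(
                f"stratum {key!r} present among phosphosites but absent "
                "from the control pool"
            )
        codes = stratum_codes.to_numpy(int)
        draws = codes[rng.integers(0, codes.size, size=(B, int(n_stratum)))]
        boot_counts += np.bincount(
            (draws + offsets).ravel(), minlength=n_aa * B
        ).reshape(B, n_aa)

    f_boot = boot_counts / n_phospho
    mean_control = f_boot.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            mean_control > 0,
            f_obs / np.where(mean_control > 0, mean_control, 1.0),
            np.where(f_obs > 0, np.inf, np.nan),
        )
    exceed = (f_boot >= f_obs[None, :] - 1e-12).sum(axis=0)
    pvalues = (1.0 + exceed) / (B + 1.0)
    if bonferroni:
        pvalues = np.minimum(1.0, pvalues * n_aa)

    table = pd.DataFrame(
        {
            "origin": list(AMINO_ACIDS),
            "f_obs": f_obs,
            "mean_control": mean_control,
            "ratio": ratio,
            "pvalue": pvalues,
            "n_obs": obs_counts,
        }
    ).set_index("origin")
    return EnrichmentTable(
        table=table,
        n_phospho=n_phospho,
        n_control_pool=len(pool),
        bootstrap_B=B,
        seed=seed,
        strata=strata,
        bonferroni=bonferroni,
        stratum_counts=stratum_counts,
    )


ORIGIN_CLASSES = {"DE": ("D", "E"), "K": ("K",)}


def origin_by_age_table(dated_sites: pd.DataFrame) -> GroupComparison:
    """Counts of D/E-, K- and other-origin phosphosites by median/young group.

    Returns the 2x3 contingency table with a chi-squared independence test
    (exact conditional test substituted when an expected count falls
    below 1).
    """
    sites = resolved_origins(
        dated_sites[
            dated_sites["is_phospho"]
            & dated_sites["age_group"].isin(ENRICHABLE_GROUPS)
        ]
    )
    if sites.empty:
        raise AnalysisError("no datable phosphosites with resolved origins")

    def classify(origin: str) -> str:
        for label, members in ORIGIN_CLASSES.items():
            if origin in members:
                return label
        return "other"

    categories = sites["origin"].map(classify)
    table = pd.crosstab(sites["age_group"], categories)
    table = table.reindex(
        index=[g for g in ENRICHABLE_GROUPS if g in table.index],
        columns=[c for c in ("DE", "K", "other") if c in table.columns],
        fill_value=0,
    )
    return contingency_test(table, name="origin_class_by_age")
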