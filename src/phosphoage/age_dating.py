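"""Dating phospho-acceptor emergence and binning sites into age groups.

A site's emergence age is the age of the oldest node, on the root-to-focal
path, from which its own acceptor residue (S, T or Y) is continuously
present down to the focal leaf.  Sites are binned as:

* **old** — emergence at or before ``old_min`` (435 MY, the vertebrate root)
  and, in strict mode, the acceptor conserved in every non-gap leaf;
* **young** — emergence strictly after the mammal MRCA (``young_max`` = 96 MY);
* **median** — everything in between.

The ancestral origin of a non-old site is the residue the acceptor evolved
from: the state of the parent of the emergence node (singleton set -> that
residue, larger set -> "ambiguous"); sites emerging at the root have no
parent and get origin "unknown".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .ancestral import (
    AncestralStateMap,
    TooFewSpeciesError,
    fitch_reconstruct,
    restrict_tree_to_family,
)
from .io_formats import GAP, DatedTree, InputError, OrthologAlignment, TreeNode

logger = logging.getLogger(__name__)

DEFAULT_OLD_MIN = 435.0
DEFAULT_YOUNG_MAX = 96.0
DEFAULT_MIN_ORTHOLOGS = 4
DEFAULT_DISORDER_THRESHOLD = 0.5

AgeGroup = Literal["old", "median", "young"]
EmergenceMode = Literal["stretch", "earliest"]

ORIGIN_UNKNOWN = "unknown"
ORIGIN_AMBIGUOUS = "ambiguous"


class DataInconsistencyError(InputError):
    """The focal leaf does not carry the residue the site table claims."""


@dataclass
class AgeAssignment:
    """Age dating result for one site."""

    family: str
    position: int
    residue: str
    emergence_age: float
    age_group: str
    origin: str
    ortholog_count: int
    conserved_all_leaves: bool
    structure: str


def filter_families(
    families: Iterable[OrthologAlignment],
    min_orthologs: int = DEFAULT_MIN_ORTHOLOGS,
) -> tuple[list[OrthologAlignment], list[tuple[str, int]]]:
    """Keep families with strictly more than ``min_orthologs`` sequences.

    Returns the retained families and a discard log of (family id, count).
    """
    kept: list[OrthologAlignment] = []
    discarded: list[tuple[str, int]] = []
    for fam in families:
        if fam.n_orthologs > min_orthologs:
            kept.append(fam)
        else:
            discarded.append((fam.family_id, fam.n_orthologs))
    if discarded:
        logger.info(
            "filter_families: discarded %d families with <= %d orthologs",
            len(discarded),
            min_orthologs,
        )
    return kept, discarded


def date_emergence(
    residue: str,
    tree: DatedTree,
    column: Mapping[str, str],
    states: AncestralStateMap,
    mode: EmergenceMode = "stretch",
) -> tuple[float, TreeNode, bool]:
    """Date the acceptor's emergence on the root-to-focal-leaf path.

    A node "has the acceptor" when ``residue`` is in its final state set.
    In the default ``"stretch"`` mode the emergence node is the oldest node
    of the maximal *uninterrupted* acceptor stretch ending at the focal
    leaf, so a gain-loss-regain history dates from the most recent regain
    (the old group is defined by continuous conservation).  ``"earliest"``
    instead reports the oldest path node carrying the acceptor at all.

    Returns (emergence age, emergence node, conserved-in-all-leaves flag).
    """
    focal = tree.focal_species
    if column[focal] != residue:
        raise DataInconsistencyError(
            f"focal leaf carries {column[focal]!r}, site table says {residue!r}"
        )
    path = tree.path_to_leaf(focal)
    has = [residue in states.state_set(node) for node in path]
    assert has[-1], "focal leaf must carry the acceptor"

    if mode == "stretch":
        idx = len(path) - 1
        while idx > 0 and has[idx - 1]:
            idx -= 1
    elif mode == "earliest":
        idx = has.index(True)
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown emergence mode {mode!r}")

    conserved = all(
        column[leaf.name] == residue
        for leaf in tree.leaves
        if column[leaf.name] != GAP
    )
    node = path[idx]
    return node.age, node, conserved


def assign_age_group(
    emergence_age: float,
    conserved: bool,
    old_min: float = DEFAULT_OLD_MIN,
    young_max: float = DEFAULT_YOUNG_MAX,
    strict_old: bool = True,
) -> str:
    """Bin an emergence age into old / median / young.

    Old requires emergence at or beyond ``old_min`` and (in strict mode)
    conservation of the acceptor across every non-gap leaf.  Young means
    emergence strictly below ``young_max``: presence at the mammal-MRCA node
    itself implies a gain on the preceding branch, hence median.
    """
    if not old_min > young_max > 0:
        raise InputError(
            f"thresholds must satisfy old_min > young_max > 0, "
            f"got {old_min} and {young_max}"
        )
    if emergence_age >= old_min and (conserved or not strict_old):
        return "old"
    if emergence_age < young_max:
        return "young"
    return "median"


def infer_origin_state(
    emergence_node: TreeNode, states: AncestralStateMap
) -> str:
    """Ancestral origin: the state of the emergence node's parent.

    Root emergence has no parent -> ``"unknown"`` (the old group's ancestral
    state is unpredictable).  A non-singleton parent set -> ``"ambiguous"``.
    """
    parent = emergence_node.parent
    if parent is None:
        return ORIGIN_UNKNOWN
    parent_set = states.state_set(parent)
    if len(parent_set) == 1:
        return next(iter(parent_set))
    return ORIGIN_AMBIGUOUS


def classify_structure(
    disorder_score: float, threshold: float = DEFAULT_DISORDER_THRESHOLD
) -> str:
    """Classify a site as disordered (score strictly above threshold) or ordered."""
    if not 0.0 <= disorder_score <= 1.0:
        raise InputError(f"disorder score {disorder_score} outside [0, 1]")
    return "disordered" if disorder_score > threshold else "ordered"


def date_sites(
    sites: pd.DataFrame,
    alignments: Mapping[str, OrthologAlignment],
    tree: DatedTree,
    *,
    old_min: float = DEFAULT_OLD_MIN,
    young_max: float = DEFAULT_YOUNG_MAX,
    strict_old: bool = True,
    min_orthologs: int = DEFAULT_MIN_ORTHOLOGS,
    disorder_threshold: float = DEFAULT_DISORDER_THRESHOLD,
    emergence_mode: EmergenceMode = "stretch",
) -> pd.DataFrame:
    """Date every site of a site table; the pipeline's central step.

    Families failing the ortholog-count filter (or with fewer than two
    species) are dropped with their sites; the returned frame is the input
    rows of surviving families plus the columns ``emergence_age``,
    ``age_group``, ``origin``, ``ortholog_count``, ``conserved_all_leaves``
    and ``structure``.
    """
    kept, discarded = filter_families(
        (alignments[f] for f in sorted(sites["family"].unique())
         if f in alignments),
        min_orthologs,
    )
    missing_fams = sorted(set(sites["family"]) - set(alignments))
    if missing_fams:
        raise InputError(f"sites reference unknown families {missing_fams[:5]}")

    rows: list[dict] = []
    for fam in kept:
        try:
            rtree = restrict_tree_to_family(tree, fam)
        except TooFewSpeciesError as exc:
            logger.info("skipping family: %s", exc)
            continue
        fam_sites = sites[sites["family"] == fam.family_id]
        cache: dict[int, AncestralStateMap] = {}
        for row in fam_sites.itertuples(index=False):
            col_idx = fam.focal_to_column(row.position)
            states = cache.get(col_idx)
            if states is None:
                states = fitch_reconstruct(rtree, fam.column(col_idx))
                cache[col_idx] = states
            column = fam.column(col_idx)
            age, node, conserved = date_emergence(
                row.residue, rtree, column, states, emergence_mode
            )
            group = assign_age_group(age, conserved, old_min, young_max, strict_old)
            origin = infer_origin_state(node, states)
            record = row._asdict()
            record.update(
                emergence_age=age,
                age_group=group,
                origin=origin,
                ortholog_count=fam.n_orthologs,
                conserved_all_leaves=conserved,
                structure=classify_structure(row.disorder, disorder_threshold),
            )
            rows.append(record)

    out = pd.DataFrame(rows)
    logger.info(
        "date_sites: dated %d sites (%d families discarded)",
        len(out),
        len(discarded),
    )
    return out


def write_ages_tsv(ages: pd.DataFrame, path) -> None:
    ages.to_csv(path, sep="\t", index=False)


def read_ages_tsv(path) -> pd.DataFrame:
    from .io_formats import _coerce_bool, _SITE_BOOL_COLUMNS  # shared coding

    df = pd.read_csv(path, sep="\t", dtype={"family": str})
    for col in _SITE_BOOL_COLUMNS + ["conserved_all_leaves"]:
        if col in df.columns:
            df[col] = _coerce_bool(df[col], col)
    return df
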