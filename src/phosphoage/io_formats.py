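"""Readers, writers and coordinate conventions shared by the whole pipeline.

Coordinate conventions (fixed here, used everywhere else):

* Positions in a focal protein are **1-based** and counted over the ungapped
  focal sequence, matching phosphosite-database convention.
* Alignment columns are **0-based** internal indices.
* The gap character is ``'-'`` only; ambiguous residues such as ``'X'`` are
  rejected at parse time.
* Node ages are in million years (MY); extant leaves sit at age 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = frozenset(AMINO_ACIDS) | {GAP}
ACCEPTOR_RESIDUES = frozenset("STY")

#: Species of the default dated vertebrate tree.
DEFAULT_SPECIES = (
    "H_sapiens",
    "P_troglodytes",
    "M_musculus",
    "R_norvegicus",
    "B_taurus",
    "G_gallus",
    "X_tropicalis",
    "D_rerio",
)

DEFAULT_FOCAL_SPECIES = "H_sapiens"

#: Eight-taxon vertebrate tree with TimeTree-style divergence times (MY):
#: vertebrate root 435, amphibian split 352, amniote split 312, mammal MRCA 96,
#: primate/rodent split 90, mouse/rat 20.9, human/chimp 6.7.
DEFAULT_TREE_NEWICK = (
    "((((((H_sapiens:6.7,P_troglodytes:6.7):83.3,"
    "(M_musculus:20.9,R_norvegicus:20.9):69.1):6.0,"
    "B_taurus:96.0):216.0,G_gallus:312.0):40.0,"
    "X_tropicalis:352.0):83.0,D_rerio:435.0);"
)

ULTRAMETRIC_TOL = 1e-6  # MY


class FormatError(ValueError):
    """A file violates its format contract (e.g. ragged alignment)."""


class InputError(ValueError):
    """Well-formed input that violates a pipeline precondition."""


class CoordinateError(ValueError):
    """A focal-protein position outside the valid 1-based range."""


# ---------------------------------------------------------------------------
# Dated species tree
# ---------------------------------------------------------------------------


class TreeNode:
    """Node of a rooted dated tree; age in MY, leaves at age 0."""

    __slots__ = ("name", "age", "children", "parent")

    def __init__(self, name: str, age: float):
        self.name = name
        self.age = float(age)
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, age={self.age:g})"


class DatedTree:
    """Rooted ultrametric species tree with node ages in million years.

    Parameters
    ----------
    root:
        Root :class:`TreeNode`; every internal node must be strictly older
        than each of its children and every leaf must sit at age 0.
    focal_species:
        Leaf label of the focal (phosphosite-bearing) species.
    """

    def __init__(self, root: TreeNode, focal_species: str):
        self.root = root
        self.focal_species = focal_species
        self._leaves = [n for n in self.preorder() if n.is_leaf]
        names = [leaf.name for leaf in self._leaves]
        if len(set(names)) != len(names):
            raise InputError(f"duplicate leaf labels in tree: {sorted(names)}")
        if focal_species not in names:
            raise InputError(
                f"focal species {focal_species!r} is not a leaf of the tree"
            )
        for node in self.preorder():
            for child in node.children:
                if not node.age > child.age:
                    raise InputError(
                        f"node {node.name!r} (age {node.age:g}) is not strictly "
                        f"older than child {child.name!r} (age {child.age:g})"
                    )
            if node.is_leaf and abs(node.age) > ULTRAMETRIC_TOL:
                raise InputError(f"leaf {node.name!r} has nonzero age {node.age:g}")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(
        cls, newick: str, focal_species: str = DEFAULT_FOCAL_SPECIES
    ) -> "DatedTree":
        """Build a dated tree from a Newick string with branch lengths in MY.

        Node ages are computed as (maximum root-to-leaf depth) minus the
        node's own depth; the tree must be ultrametric within ``1e-6`` MY.
        """
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        droot = dtree.seed_node

        depths: dict[object, float] = {droot: 0.0}
        for dnode in dtree.preorder_node_iter():
            if dnode is droot:
                continue
            length = dnode.edge.length
            if length is None:
                raise FormatError(
                    "tree has an edge without a branch length; ages cannot be dated"
                )
            depths[dnode] = depths[dnode.parent_node] + float(length)

        leaf_depths = {
            dnode: depths[dnode] for dnode in dtree.leaf_node_iter()
        }
        max_depth = max(leaf_depths.values())
        for dnode, depth in leaf_depths.items():
            if abs(depth - max_depth) > ULTRAMETRIC_TOL:
                label = dnode.taxon.label if dnode.taxon else "<unnamed>"
                raise InputError(
                    f"tree is not ultrametric: leaf {label!r} has root-to-leaf "
                    f"depth {depth:g}, expected {max_depth:g}"
                )

        counter = iter(range(10**9))

        def convert(dnode) -> TreeNode:
            if dnode.is_leaf():
                name = dnode.taxon.label if dnode.taxon else dnode.label
                if name is None:
                    raise FormatError("tree has an unlabeled leaf")
                name = name.replace(" ", "_")
                node = TreeNode(name, 0.0)
            else:
                label = dnode.label or f"anc{next(counter)}"
                node = TreeNode(label, max_depth - depths[dnode])
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        return cls(convert(droot), focal_species)

    @classmethod
    def default(cls, focal_species: str = DEFAULT_FOCAL_SPECIES) -> "DatedTree":
        """The 8-taxon dated vertebrate tree (root 435 MY, mammal MRCA 96 MY)."""
        return cls.from_newick(DEFAULT_TREE_NEWICK, focal_species)

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    @property
    def leaves(self) -> list[TreeNode]:
        return list(self._leaves)

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self._leaves]

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def root_age(self) -> float:
        return self.root.age

    def find_leaf(self, name: str) -> TreeNode:
        for leaf in self._leaves:
            if leaf.name == name:
                return leaf
        raise InputError(f"no leaf named {name!r}")

    def path_to_leaf(self, name: str) -> list[TreeNode]:
        """Root-to-leaf node path (root first, leaf last)."""
        node = self.find_leaf(name)
        path = [node]
        while node.parent is not None:
            node = node.parent
            path.append(node)
        return path[::-1]

    # -- manipulation -------------------------------------------------------

    def restrict(self, species: Iterable[str]) -> "DatedTree":
        """Restriction to a leaf subset, suppressing unary nodes.

        Node ages are preserved, so branch durations on the restricted tree
        span the same absolute time intervals as on the full tree.  The focal
        species must be in ``species``.
        """
        keep = set(species)
        unknown = keep - set(self.leaf_names)
        if unknown:
            raise InputError(f"species not in tree: {sorted(unknown)}")
        if self.focal_species not in keep:
            raise InputError("restriction must retain the focal species")

        def prune(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                return TreeNode(node.name, node.age) if node.name in keep else None
            kept = [c for c in (prune(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            new = TreeNode(node.name, node.age)
            for child in kept:
                new.add_child(child)
            return new

        new_root = prune(self.root)
        assert new_root is not None  # keep is non-empty (contains focal)
        return DatedTree(new_root, self.focal_species)

    def newick(self) -> str:
        """Newick string with branch lengths in MY (ages recoverable)."""

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(
                f"{fmt(c)}:{node.age - c.age:g}" for c in node.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.newick() + "\n")


def read_dated_newick(
    path: str | Path, focal_species: str = DEFAULT_FOCAL_SPECIES
) -> DatedTree:
    """Read a dated Newick tree (branch lengths in MY) from ``path``."""
    return DatedTree.from_newick(Path(path).read_text(), focal_species)


# ---------------------------------------------------------------------------
# Ortholog alignments
# ---------------------------------------------------------------------------


@dataclass
class OrthologAlignment:
    """A per-protein multiple alignment of orthologous sequences.

    ``sequences`` maps species label to the aligned amino-acid string
    (20 residues plus ``'-'``); all strings share one length ``L``.
    """

    family_id: str
    sequences: dict[str, str]
    focal_species: str = DEFAULT_FOCAL_SPECIES

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError(f"family {self.family_id}: no sequences")
        lengths = {sp: len(seq) for sp, seq in self.sequences.items()}
        if len(set(lengths.values())) > 1:
            raise FormatError(
                f"family {self.family_id}: unequal aligned lengths {lengths}"
            )
        for sp, seq in self.sequences.items():
            bad = set(seq) - ALPHABET
            if bad:
                raise FormatError(
                    f"family {self.family_id}, species {sp}: invalid characters "
                    f"{sorted(bad)} (only the 20 residues and '-' are allowed)"
                )
        if self.focal_species not in self.sequences:
            raise InputError(
                f"family {self.family_id}: focal species "
                f"{self.focal_species!r} missing from alignment"
            )
        if self.focal_ungapped_length == 0:
            raise InputError(
                f"family {self.family_id}: focal sequence is all gaps"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def n_orthologs(self) -> int:
        return len(self.sequences)

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def focal_sequence(self) -> str:
        return self.sequences[self.focal_species]

    @property
    def focal_ungapped_length(self) -> int:
        return sum(1 for c in self.focal_sequence if c != GAP)

    def column(self, index: int) -> dict[str, str]:
        """Characters of alignment column ``index`` (0-based) per species."""
        return {sp: seq[index] for sp, seq in self.sequences.items()}

    def focal_to_column(self, position: int) -> int:
        """0-based column of the ``position``-th (1-based) focal residue."""
        return map_site_to_column(self, position)

    def column_to_focal(self, column: int) -> int:
        """Inverse of :meth:`focal_to_column`; errors on focal-gap columns."""
        seq = self.focal_sequence
        if not 0 <= column < self.length:
            raise CoordinateError(
                f"column {column} outside alignment of length {self.length}"
            )
        if seq[column] == GAP:
            raise CoordinateError(
                f"family {self.family_id}: focal sequence is gapped at column {column}"
            )
        return sum(1 for c in seq[: column + 1] if c != GAP)


def map_site_to_column(alignment: OrthologAlignment, position: int) -> int:
    """Map a 1-based ungapped focal position to its 0-based alignment column."""
    if position < 1:
        raise CoordinateError(f"position {position} is not 1-based")
    seen = 0
    for col, char in enumerate(alignment.focal_sequence):
        if char != GAP:
            seen += 1
            if seen == position:
                return col
    raise CoordinateError(
        f"family {alignment.family_id}: position {position} beyond ungapped "
        f"focal length {alignment.focal_ungapped_length}"
    )


def read_alignment_fasta(
    path: str | Path,
    focal_species: str = DEFAULT_FOCAL_SPECIES,
    family_id: str | None = None,
) -> OrthologAlignment:
    """Read one ortholog family from an aligned FASTA file.

    Record ids are species labels; the family id defaults to the file stem.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate species label {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return OrthologAlignment(
        family_id=family_id or path.stem,
        sequences=sequences,
        focal_species=focal_species,
    )


def write_alignment_fasta(alignment: OrthologAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sp, description="")
        for sp, seq in alignment.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Site and quantification tables (TSV)
# ---------------------------------------------------------------------------


@dataclass
class SiteRecord:
    """One phospho or control site on a focal protein.

    ``position`` is 1-based over the ungapped focal sequence; ``residue`` is
    the phospho-acceptor type (S/T/Y); ``disorder`` is a VSL2-style score in
    [0, 1]; ``module`` labels the protein's functional-module class (BFM =
    basic, VFM = vertebrate-specific, NA = unannotated).
    """

    family: str
    position: int
    residue: str
    disorder: float
    is_phospho: bool
    functional: bool = False
    polymorphic: bool = False
    known_ptm_db: bool = False
    kinase_score: float = 0.0
    module: str = "NA"


SITE_COLUMNS = [
    "family",
    "position",
    "residue",
    "disorder",
    "is_phospho",
    "functional",
    "polymorphic",
    "known_ptm_db",
    "kinase_score",
    "module",
]

_SITE_BOOL_COLUMNS = ["is_phospho", "functional", "polymorphic", "known_ptm_db"]

_MODULES = {"BFM", "VFM", "NA"}


def _coerce_bool(series: pd.Series, name: str) -> pd.Series:
    mapping = {
        "True": True, "False": False, "true": True, "false": False,
        "1": True, "0": False, 1: True, 0: False, True: True, False: False,
    }
    try:
        return series.map(mapping).astype(bool)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"column {name!r} is not boolean-coded") from exc


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    """Read a site table; validates columns, dtypes and value ranges.

    Unknown extra columns are preserved pass-through.
    """
    df = pd.read_csv(path, sep="\t", dtype={"family": str, "module": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing site-table columns {missing}")
    df["position"] = df["position"].astype(int)
    df["disorder"] = df["disorder"].astype(float)
    df["kinase_score"] = df["kinase_score"].astype(float)
    for col in _SITE_BOOL_COLUMNS:
        df[col] = _coerce_bool(df[col], col)
    _validate_sites(df, str(path))
    return df


def _validate_sites(df: pd.DataFrame, origin: str) -> None:
    bad_res = set(df["residue"]) - ACCEPTOR_RESIDUES
    if bad_res:
        raise FormatError(f"{origin}: non-acceptor residues {sorted(bad_res)}")
    if ((df["disorder"] < 0) | (df["disorder"] > 1)).any():
        raise InputError(f"{origin}: disorder scores outside [0, 1]")
    if (df["kinase_score"] < 0).any():
        raise InputError(f"{origin}: negative kinase scores")
    bad_mod = set(df["module"]) - _MODULES
    if bad_mod:
        raise FormatError(f"{origin}: unknown module labels {sorted(bad_mod)}")
    if (df["position"] < 1).any():
        raise CoordinateError(f"{origin}: positions must be 1-based (>= 1)")


def write_sites_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def quant_columns(n_tissues: int = 9) -> list[str]:
    return (
        ["family", "position"]
        + [f"tissue_{i}" for i in range(1, n_tissues + 1)]
        + ["protein_abundance", "protein_breadth"]
    )


def read_quant_tsv(path: str | Path, n_tissues: int = 9) -> pd.DataFrame:
    """Read a per-site tissue quantification table (levels >= 0; 0 = absent)."""
    df = pd.read_csv(path, sep="\t", dtype={"family": str})
    missing = [c for c in quant_columns(n_tissues) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing quant-table columns {missing}")
    tissue_cols = [f"tissue_{i}" for i in range(1, n_tissues + 1)]
    if (df[tissue_cols] < 0).any().any():
        raise InputError(f"{path}: negative phosphorylation levels")
    if (df["protein_abundance"] < 0).any():
        raise InputError(f"{path}: negative protein abundance")
    breadth = df["protein_breadth"].astype(int)
    if ((breadth < 0) | (breadth > n_tissues)).any():
        raise InputError(f"{path}: protein_breadth outside 0..{n_tissues}")
    df["protein_breadth"] = breadth
    return df


def write_quant_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def validate_sites_against_alignments(
    sites: pd.DataFrame, alignments: Mapping[str, OrthologAlignment]
) -> list[str]:
    """Check the residue-at-position invariant of every site; returns errors.

    Each site's stated residue must equal the focal-sequence character at its
    mapped alignment column (a site can never sit on a focal gap, by the
    coordinate convention).
    """
    errors: list[str] = []
    for row in sites.itertuples(index=False):
        aln = alignments.get(row.family)
        if aln is None:
            errors.append(f"{row.family}:{row.position}: unknown family")
            continue
        try:
            col = aln.focal_to_column(row.position)
        except CoordinateError as exc:
            errors.append(str(exc))
            continue
        actual = aln.focal_sequence[col]
        if actual != row.residue:
            errors.append(
                f"{row.family}:{row.position}: table says {row.residue}, "
                f"focal sequence has {actual}"
            )
    return errors
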