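"""Parsimony ancestral-state reconstruction on dated species trees.

For every alignment column the reconstruction returns, per node, the set of
residue states attainable in at least one maximally parsimonious labelling
(the MPR final sets of Fitch-style parsimony) together with the minimum
mutation count.  The gap character is a first-class 21st state, so a
gap-to-serine event counts as a genuine appearance of the acceptor.

All state changes cost 1 (no exchangeability matrix); the sets are computed
with a two-pass unit-cost dynamic program, which yields exactly the Fitch
final sets on binary trees and remains exact on the multifurcations that can
arise from tree restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import (
    GAP,
    DatedTree,
    InputError,
    OrthologAlignment,
    TreeNode,
)

_INF = 10**9

PARSIMONY_METHOD = "unit-cost-parsimony"


class TooFewSpeciesError(InputError):
    """A family with fewer than two usable species cannot be reconstructed."""


@dataclass
class AncestralStateMap:
    """Per-node MPR state sets for one alignment column.

    ``states`` maps every node of the (possibly restricted) tree to a
    non-empty frozen set of characters; ``score`` is the minimum number of
    state changes required on the tree.
    """

    states: dict[TreeNode, frozenset[str]]
    score: int
    method: str = PARSIMONY_METHOD

    def state_set(self, node: TreeNode) -> frozenset[str]:
        return self.states[node]


def fitch_reconstruct(
    tree: DatedTree, column: Mapping[str, str]
) -> AncestralStateMap:
    """Reconstruct ancestral state sets for one column.

    Parameters
    ----------
    tree:
        Dated tree whose every leaf name appears in ``column``.
    column:
        Leaf name -> single character (residue or ``'-'``).

    Returns
    -------
    AncestralStateMap
        Final state set per node plus the parsimony score.  Internal-node
        sets are the states occurring in at least one minimum-mutation
        labelling; leaf sets are the observed singletons.
    """
    missing = [leaf.name for leaf in tree.leaves if leaf.name not in column]
    if missing:
        raise InputError(f"column lacks characters for leaves {missing}")

    # Optimal internal states are always among the observed leaf states for
    # unit substitution cost, so the DP runs over the observed alphabet only.
    alphabet = sorted({column[leaf.name] for leaf in tree.leaves})
    index = {a: i for i, a in enumerate(alphabet)}
    k = len(alphabet)

    down: dict[TreeNode, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            costs = [_INF] * k
            costs[index[column[node.name]]] = 0
        else:
            costs = [0] * k
            for child in node.children:
                ccosts = down[child]
                cmin = min(ccosts)
                for i in range(k):
                    costs[i] += min(ccosts[i], cmin + 1)
        down[node] = costs

    up: dict[TreeNode, list[int]] = {tree.root: [0] * k}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        unode = up[node]
        child_contrib = {}
        for child in node.children:
            ccosts = down[child]
            cmin = min(ccosts)
            child_contrib[child] = [min(ccosts[i], cmin + 1) for i in range(k)]
        for child in node.children:
            # cost of everything outside child's subtree, given child's state:
            # route through the parent state t, paying up(parent, t), the
            # sibling subtrees below t, and the parent-child edge.
            around = [
                unode[i]
                + sum(
                    child_contrib[sib][i]
                    for sib in node.children
                    if sib is not child
                )
                for i in range(k)
            ]
            amin = min(around)
            up[child] = [min(around[i], amin + 1) for i in range(k)]

    root_down = down[tree.root]
    score = min(root_down)

    states: dict[TreeNode, frozenset[str]] = {}
    for node in down:
        totals = [down[node][i] + up[node][i] for i in range(k)]
        states[node] = frozenset(
            alphabet[i] for i in range(k) if totals[i] == score
        )
        assert states[node], "MPR state set cannot be empty"
    return AncestralStateMap(states=states, score=score)


@dataclass
class FamilyReconstruction:
    """Reconstruction of every column of one family.

    ``tree`` is the restriction of the input tree to the species present in
    the alignment (ages preserved, unary nodes suppressed); ``columns[i]`` is
    the ancestral state map of alignment column ``i``.
    """

    family_id: str
    tree: DatedTree
    columns: list[AncestralStateMap] = field(repr=False)
    species_used: list[str] = field(default_factory=list)


def restrict_tree_to_family(
    tree: DatedTree, alignment: OrthologAlignment
) -> DatedTree:
    """Restriction of ``tree`` to the species present in the alignment."""
    species = [sp for sp in alignment.species]
    unknown = set(species) - set(tree.leaf_names)
    if unknown:
        raise InputError(
            f"family {alignment.family_id}: species not in tree {sorted(unknown)}"
        )
    if len(species) < 2:
        raise TooFewSpeciesError(
            f"family {alignment.family_id}: only {len(species)} species present"
        )
    return tree.restrict(species)


def reconstruct_column(
    tree: DatedTree, alignment: OrthologAlignment, column_index: int
) -> AncestralStateMap:
    """Reconstruct a single alignment column on an already-restricted tree."""
    return fitch_reconstruct(tree, alignment.column(column_index))


def reconstruct_family(
    tree: DatedTree, alignment: OrthologAlignment
) -> FamilyReconstruction:
    """Reconstruct every column of a family on the restricted tree.

    Species missing from the alignment are dropped by tree restriction
    (suppressing unary nodes, preserving node ages).  Families with fewer
    than two species raise :class:`TooFewSpeciesError` so callers can skip
    them with a logged reason.
    """
    rtree = restrict_tree_to_family(tree, alignment)
    columns = [
        fitch_reconstruct(rtree, alignment.column(i))
        for i in range(alignment.length)
    ]
    return FamilyReconstruction(
        family_id=alignment.family_id,
        tree=rtree,
        columns=columns,
        species_used=list(alignment.species),
    )


def root_states_table(recon: FamilyReconstruction) -> Sequence[tuple[int, str, int]]:
    """Debug dump: (column, sorted root state set, score) per column."""
    out = []
    for i, col in enumerate(recon.columns):
        states = "".join(sorted(col.state_set(recon.tree.root)))
        out.append((i, states, col.score))
    return out
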