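"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, direct
formulas) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

from phosphoage.io_formats import DatedTree, TreeNode


def brute_force_parsimony(
    tree: DatedTree, column: dict[str, str], alphabet: str | None = None
) -> tuple[int, dict[TreeNode, frozenset[str]]]:
    """Minimum mutation count and per-node optimal-state sets by enumeration.

    Tries every assignment of ``alphabet`` states to every internal node and
    counts mismatched edges; the returned sets are the states each node
    takes in at least one minimum-cost labelling.
    """
    nodes = list(tree.preorder())
    internals = [n for n in nodes if not n.is_leaf]
    if alphabet is None:
        letters = sorted(set(column.values()))
    else:
        letters = sorted(set(alphabet) | set(column.values()))

    best = None
    best_sets: dict[TreeNode, set[str]] = {n: set() for n in nodes}
    for labels in itertools.product(letters, repeat=len(internals)):
        state = dict(zip(internals, labels))
        for leaf in tree.leaves:
            state[leaf] = column[leaf.name]
        cost = sum(
            1
            for node in nodes
            for child in node.children
            if state[node] != state[child]
        )
        if best is None or cost < best:
            best = cost
            best_sets = {n: {state[n]} for n in nodes}
        elif cost == best:
            for n in nodes:
                best_sets[n].add(state[n])
    assert best is not None
    return best, {n: frozenset(s) for n, s in best_sets.items()}


def enumerate_tree_shapes(n_leaves: int) -> list[tuple]:
    """All rooted binary tree shapes with exactly ``n_leaves`` leaves.

    Shapes are nested tuples; children are sorted for canonical form so
    mirror-image duplicates collapse.
    """
    if n_leaves == 1:
        return [()]
    shapes: set[tuple] = set()
    for k in range(1, n_leaves):
        for left in enumerate_tree_shapes(k):
            for right in enumerate_tree_shapes(n_leaves - k):
                shapes.add(tuple(sorted((left, right), key=repr)))
    return sorted(shapes, key=repr)


def shape_to_dated_tree(shape: tuple) -> DatedTree:
    """Materialise a shape as a DatedTree (ages = node height, leaves L0..)."""
    counter = itertools.count()
    internal_counter = itertools.count()

    def build(sub) -> tuple[TreeNode, int]:
        if sub == ():
            return TreeNode(f"L{next(counter)}", 0.0), 0
        children = [build(child) for child in sub]
        height = 1 + max(h for _, h in children)
        node = TreeNode(f"I{next(internal_counter)}", float(height))
        for child, _ in children:
            node.add_child(child)
        return node, height

    root, _ = build(shape)
    # fix ages so parents are strictly older even on unbalanced shapes
    def fix(node: TreeNode) -> float:
        if node.is_leaf:
            node.age = 0.0
            return 0.0
        node.age = 1.0 + max(fix(c) for c in node.children)
        return node.age

    fix(root)
    focal = root
    while not focal.is_leaf:
        focal = focal.children[0]
    return DatedTree(root, focal.name)


def vectorized_min_mutations(tree: DatedTree, letters: str) -> np.ndarray:
    """Brute-force minimum mutation count for *every* column over ``letters``.

    Enumerates all ``k^m`` internal labelings and all ``k^n`` leaf columns
    at once with numpy; returns an array of shape (k^n,) ordered like
    ``itertools.product(letters, repeat=n_leaves)``.
    """
    k = len(letters)
    leaves = tree.leaves
    internals = [n for n in tree.preorder() if not n.is_leaf]
    leaf_idx = {id(n): i for i, n in enumerate(leaves)}
    int_idx = {id(n): i for i, n in enumerate(internals)}
    n, m = len(leaves), len(internals)

    labs = np.array(
        list(itertools.product(range(k), repeat=m)), dtype=np.int8
    ).reshape(k**m, m)
    cols = np.array(
        list(itertools.product(range(k), repeat=n)), dtype=np.int8
    ).reshape(k**n, n)

    cost = np.zeros((k**n, k**m), dtype=np.int16)
    for node in tree.preorder():
        for child in node.children:
            if child.is_leaf:
                cost += (
                    cols[:, leaf_idx[id(child)], None]
                    != labs[None, :, int_idx[id(node)]]
                )
            else:
                cost += (
                    labs[:, int_idx[id(node)]] != labs[:, int_idx[id(child)]]
                )[None, :]
    return cost.min(axis=1)


def pearson_chi2_formula(table: np.ndarray) -> float:
    """Direct sum((O - E)^2 / E) with margin-product expected counts."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return float(((table - expected) ** 2 / expected).sum())


def fisher_2x2_enumeration(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over one margin."""
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x: int) -> float:
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))
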