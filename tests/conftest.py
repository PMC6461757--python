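"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return tree


def oracle_red(tree: dendropy.Tree) -> dict:
    """Independent RED computation by explicit path enumeration.

    Walks every parent→leaf path edge by edge to obtain the mean path
    length, instead of the implementation's postorder aggregation. Used to
    cross-check compute_red.
    """
    red = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node.parent_node
        if node.is_leaf():
            red[node] = 1.0
            continue
        dists = []
        for leaf in node.leaf_nodes():
            length = 0.0
            cur = leaf
            while cur is not parent:
                length += cur.edge.length or 0.0
                cur = cur.parent_node
            dists.append(length)
        u = sum(dists) / len(dists)
        d = node.edge.length or 0.0
        p = red[parent]
        red[node] = p + (d / u) * (1.0 - p) if u > 0 else p
    return red


def enumerate_topologies(labels: list[str]):
    """All labelled rooted binary topologies, as nested tuples.

    Built by stepwise leaf insertion into every subtree position, yielding
    (2n-3)!! topologies for n labels.
    """
    trees = [labels[0]]
    for label in labels[1:]:
        nxt = []
        for t in trees:
            for i in range(_n_subtrees(t)):
                nxt.append(_insert_at(t, label, i)[0])
        trees = nxt
    return trees


def _n_subtrees(t) -> int:
    if isinstance(t, str):
        return 1
    return 1 + _n_subtrees(t[0]) + _n_subtrees(t[1])


def _insert_at(t, label, i):
    """Replace the i-th subtree (preorder) of t by (subtree, label)."""
    if i == 0:
        return (t, label), -1
    if isinstance(t, str):
        return t, i - 1
    left, i = _insert_at(t[0], label, i - 1)
    if i < 0:
        return (left, t[1]), -1
    right, i = _insert_at(t[1], label, i)
    if i < 0:
        return (t[0], right), -1
    return t, i


def tuple_to_newick(t, lengths: dict | None = None, rng: np.random.Generator | None = None) -> str:
    """Render a tuple topology as newick with supplied or random lengths."""

    def render(node):
        if isinstance(node, str):
            name = node
        else:
            name = f"({render(node[0])},{render(node[1])})"
        length = rng.uniform(0.1, 2.0) if rng is not None else 1.0
        return f"{name}:{length:.6f}"

    return f"({render(t[0])},{render(t[1])});" if isinstance(t, tuple) else f"{t};"


@pytest.fixture
def basic_tree() -> dendropy.Tree:
    """The worked interpolation example: ((A:1,B:1)X:1,C:2)R."""
    return tree_from_newick("((A:1,B:1)X:1,C:2)R;")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
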