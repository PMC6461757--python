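"""Relative evolutionary divergence (RED) and rank normalisation.

RED places every node of a rooted tree on a [0, 1] scale — 0 at the root,
1 at every extant leaf — by linear interpolation along lineages:

    red(n) = p + (d / u) * (1 - p)

where ``p`` is the parent's RED, ``d`` the branch length from the parent to
``n``, and ``u`` the mean path length from the parent to all leaves
descending from ``n``. Because lineages evolve at different rates, RED
rather than raw depth is used to delineate taxonomic ranks: taxa at the
same rank should fall into a common RED window. Named groups whose
placement violates the window for their rank (or which are not
monophyletic) are split into suffixed subgroups, mirroring how polyphyletic
and overly divergent genera are subdivided when normalising a seed
taxonomy against a genome tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

from .io import RANKS, UnrootedTreeError, ensure_rooted, lineages_by_rank

logger = logging.getLogger(__name__)

#: ranks to which RED windows are fitted (species excluded: leaves are RED 1)
WINDOW_RANKS = ("phylum", "class", "order", "family", "genus")

DEFAULT_HALF_WIDTH = 0.1


@dataclass(frozen=True)
class REDNodeInfo:
    """RED of one node plus the quantities it was interpolated from."""

    red: float
    parent_red: float | None  # p; None at the root
    branch_length: float | None  # d; None at the root
    mean_parent_to_leaf: float | None  # u; None at the root


class REDAnnotation:
    """Per-node RED values over a rooted tree.

    Nodes are keyed by identity; leaves are additionally addressable by
    taxon label via :meth:`leaf_red`.
    """

    def __init__(self, tree: dendropy.Tree, info: dict[dendropy.Node, REDNodeInfo]):
        self.tree = tree
        self._info = info

    def red(self, node: dendropy.Node) -> float:
        return self._info[node].red

    def info(self, node: dendropy.Node) -> REDNodeInfo:
        return self._info[node]

    def leaf_red(self, label: str) -> float:
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon and leaf.taxon.label == label:
                return self._info[leaf].red
        raise KeyError(f"no leaf labelled {label!r}")

    def items(self):
        return self._info.items()


@dataclass(frozen=True)
class RankWindow:
    """Acceptable RED interval for a taxonomic rank (median ± half width)."""

    rank: str
    median_red: float
    half_width: float = DEFAULT_HALF_WIDTH

    @property
    def low(self) -> float:
        return max(0.0, self.median_red - self.half_width)

    @property
    def high(self) -> float:
        return min(1.0, self.median_red + self.half_width)

    def contains(self, red: float) -> bool:
        return self.low <= red <= self.high


@dataclass
class MonophylyReport:
    """Outcome of a monophyly check for one named group of leaves."""

    taxon: str
    is_monophyletic: bool
    mrca: dendropy.Node
    subclades: list[dendropy.Node]  # maximal member-only subtrees, all members covered


@dataclass
class TaxonAssignment:
    """One normalised taxon: a monophyletic node with a rank-checked RED."""

    name: str
    rank: str
    node: dendropy.Node
    red_value: float
    status: str  # kept | split_child | renamed
    genomes: tuple[str, ...]
    in_window: bool


def _leaf_sets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset({node.taxon.label})
        else:
            sets[node] = frozenset().union(*(sets[c] for c in node.child_nodes()))
    return sets


def compute_red(tree: dendropy.Tree, outgroup: Sequence[str] | None = None) -> REDAnnotation:
    """Annotate every node of a rooted tree with its RED value.

    The root is 0 and every leaf exactly 1; internal nodes interpolate as
    ``p + (d/u)(1-p)``. Zero-length internal branches inherit the parent
    RED (equivalent to collapsing them into a polytomy first). Polytomies
    are handled natively. Raises :class:`UnrootedTreeError` for unrooted
    input and ``ValueError`` for degenerate geometry (u = 0 with d > 0).
    """
    tree = ensure_rooted(tree, outgroup=list(outgroup) if outgroup else None)
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("RED requires a tree with at least 2 leaves")

    # mean path length from each node to its descendant leaves, by postorder
    mean_below: dict[dendropy.Node, float] = {}
    n_below: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mean_below[node] = 0.0
            n_below[node] = 1
        else:
            total = 0.0
            count = 0
            for child in node.child_nodes():
                d = child.edge.length or 0.0
                total += n_below[child] * (d + mean_below[child])
                count += n_below[child]
            mean_below[node] = total / count
            n_below[node] = count

    info: dict[dendropy.Node, REDNodeInfo] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            info[node] = REDNodeInfo(0.0, None, None, None)
            continue
        p = info[node.parent_node].red
        d = node.edge.length or 0.0
        u = d + mean_below[node]
        if node.is_leaf():
            red = 1.0
        elif u <= 0.0:
            if d > 0.0:
                label = node.label or f"node(leaves={len(node.leaf_nodes())})"
                raise ValueError(f"degenerate star geometry at {label}: u = 0 with d > 0")
            red = p  # zero-length internal edge == collapsed polytomy
        else:
            red = p + (d / u) * (1.0 - p)
        info[node] = REDNodeInfo(red=red, parent_red=p, branch_length=d, mean_parent_to_leaf=u)
    return REDAnnotation(tree, info)


def fit_rank_windows(
    annotation: REDAnnotation,
    seed_taxonomy: Mapping[str, str],
    half_width: float = DEFAULT_HALF_WIDTH,
    ranks: Iterable[str] = WINDOW_RANKS,
) -> dict[str, RankWindow]:
    """Fit per-rank RED windows from the placements of seed taxa.

    Each seed taxon at a rank is placed at the RED of the MRCA of its
    genomes; the rank's window is the median of those placements ± the half
    width. Ranks with no seed taxa get no window (logged).
    """
    by_rank = lineages_by_rank(seed_taxonomy)
    leaf_sets = _leaf_sets(annotation.tree)
    tree_leaves = leaf_sets[annotation.tree.seed_node]
    windows: dict[str, RankWindow] = {}
    for rank in ranks:
        taxa = by_rank.get(rank, {})
        reds = []
        for taxon, members in sorted(taxa.items()):
            present = members & tree_leaves
            if not present:
                continue
            node = _mrca(annotation.tree, leaf_sets, present)
            reds.append(annotation.red(node))
        if not reds:
            logger.warning("no seed taxa at rank %s; window absent", rank)
            continue
        reds.sort()
        mid = len(reds) // 2
        median = reds[mid] if len(reds) % 2 else 0.5 * (reds[mid - 1] + reds[mid])
        windows[rank] = RankWindow(rank=rank, median_red=median, half_width=half_width)
    return windows


def _mrca(
    tree: dendropy.Tree,
    leaf_sets: Mapping[dendropy.Node, frozenset[str]],
    members: frozenset[str] | set[str],
) -> dendropy.Node:
    """Smallest node whose leaf set contains all members."""
    members = frozenset(members)
    best = tree.seed_node
    changed = True
    while changed:
        changed = False
        for child in best.child_nodes():
            if members <= leaf_sets[child]:
                best = child
                changed = True
                break
    return best


def detect_polyphyly(
    tree: dendropy.Tree, taxon: str, members: Iterable[str]
) -> MonophylyReport:
    """Check whether a named group of leaves is monophyletic.

    If not, report the minimal set of maximal subtrees containing only
    members (each member belongs to exactly one reported subclade).
    """
    members = frozenset(members)
    if not members:
        raise ValueError(f"taxon {taxon!r}: empty member set")
    leaf_sets = _leaf_sets(tree)
    missing = members - leaf_sets[tree.seed_node]
    if missing:
        raise ValueError(f"taxon {taxon!r}: members not in tree: {sorted(missing)}")
    mrca = _mrca(tree, leaf_sets, members)
    mono = leaf_sets[mrca] == members
    # maximal member-only nodes: pure nodes whose parent is impure
    pure = {node: leaf_sets[node] <= members for node in leaf_sets}
    subclades = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        if pure[node]:
            if leaf_sets[node] & members:
                subclades.append(node)
        else:
            stack.extend(reversed(node.child_nodes()))
    subclades = _ladder_sort(subclades, leaf_sets)
    return MonophylyReport(taxon=taxon, is_monophyletic=mono, mrca=mrca, subclades=subclades)


def _ladder_sort(nodes, leaf_sets):
    """Descending clade size, then alphabetical smallest leaf label."""
    return sorted(nodes, key=lambda n: (-len(leaf_sets[n]), min(leaf_sets[n])))


def normalise_taxonomy(
    annotation: REDAnnotation,
    seed_taxonomy: Mapping[str, str],
    windows: Mapping[str, RankWindow],
) -> list[TaxonAssignment]:
    """Normalise a seed taxonomy into monophyletic, rank-consistent taxa.

    Per rank with an available window, each seed taxon is first reduced to
    its maximal member-only subclades (resolving polyphyly); each subclade
    whose RED falls below the rank window is recursively replaced by its
    children until the window is met. Clades that land *above* the window
    cannot be fixed by splitting and are kept but flagged
    (``in_window=False``). Split products are suffixed 1..n in ladder order
    (descending size, then alphabetical first leaf). The output at each
    rank partitions exactly the input genomes of that rank, and rerunning
    on the output taxonomy is a fixed point.
    """
    tree = annotation.tree
    leaf_sets = _leaf_sets(tree)
    by_rank = lineages_by_rank(seed_taxonomy)
    assignments: list[TaxonAssignment] = []
    for rank in RANKS:
        window = windows.get(rank)
        taxa = by_rank.get(rank)
        if window is None or not taxa:
            continue
        for taxon, members in sorted(taxa.items()):
            present = frozenset(members) & leaf_sets[tree.seed_node]
            if not present:
                continue
            report = detect_polyphyly(tree, taxon, present)
            resolved: list[dendropy.Node] = []
            for sub in report.subclades:
                resolved.extend(_resolve_red(sub, annotation, window))
            resolved = _ladder_sort(resolved, leaf_sets)
            single_unchanged = len(resolved) == 1 and leaf_sets[resolved[0]] == present
            for i, node in enumerate(resolved, start=1):
                red = annotation.red(node)
                assignments.append(
                    TaxonAssignment(
                        name=taxon if single_unchanged else f"{taxon}{i}",
                        rank=rank,
                        node=node,
                        red_value=red,
                        status="kept" if single_unchanged else "split_child",
                        genomes=tuple(sorted(leaf_sets[node])),
                        in_window=window.contains(red) or node.is_leaf(),
                    )
                )
    return assignments


def _resolve_red(
    node: dendropy.Node, annotation: REDAnnotation, window: RankWindow
) -> list[dendropy.Node]:
    """Recursively split a clade until its RED enters the rank window.

    Below-window clades descend into their children; leaves and
    above-window clades terminate the recursion (the latter flagged by the
    caller).
    """
    red = annotation.red(node)
    if node.is_leaf() or red >= window.low:
        return [node]
    out: list[dendropy.Node] = []
    for child in node.child_nodes():
        out.extend(_resolve_red(child, annotation, window))
    return out


def assignments_to_table(assignments: Sequence[TaxonAssignment]):
    """Flatten assignments into a genome-per-row pandas DataFrame."""
    import pandas as pd

    rows = []
    for a in assignments:
        for genome in a.genomes:
            rows.append(
                {
                    "genome": genome,
                    "rank": a.rank,
                    "taxon": a.name,
                    "red": a.red_value,
                    "status": a.status,
                    "in_window": a.in_window,
                }
            )
    return pd.DataFrame(rows)


def decorate_tree(tree: dendropy.Tree, assignments: Sequence[TaxonAssignment]) -> None:
    """Attach taxon names to node labels as ``label|taxon`` decorations."""
    for a in assignments:
        existing = a.node.label
        tag = f"{a.rank[0]}__{a.name}"
        a.node.label = f"{existing}|{tag}" if existing else tag
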