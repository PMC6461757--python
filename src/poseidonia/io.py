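"""Readers and writers for the plain-text formats the pipeline consumes.

Trees are newick (dendropy), tabular data are tab-separated (pandas), and
seed taxonomies are two-column TSV files mapping a genome id to a
semicolon-delimited lineage string with GTDB-style rank prefixes
(``d__``, ``p__``, ``c__``, ``o__``, ``f__``, ``g__``, ``s__``).
"""

from __future__ import annotations

import os
from typing import Mapping

import dendropy
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = {
    "d__": "domain",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}


class UnrootedTreeError(ValueError):
    """Raised when an operation requiring a rooted tree receives one without
    an unambiguous root and no outgroup was supplied."""


def read_tree(path: str | os.PathLike) -> dendropy.Tree:
    """Read a newick tree, preserving underscores in labels."""
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def write_tree(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=False,
        unquoted_underscores=True,
    )


def ensure_rooted(tree: dendropy.Tree, outgroup: list[str] | None = None) -> dendropy.Tree:
    """Validate that *tree* is rooted, optionally rooting it with an outgroup.

    A tree is accepted as rooted when its seed node is bifurcating or it is
    explicitly flagged rooted. If ``outgroup`` leaf labels are given, the tree
    is re-rooted on the edge above their MRCA. The tree is never rooted by
    guesswork.
    """
    if outgroup:
        tree.is_rooted = True  # MRCA is taken relative to the seed node
        mrca = tree.mrca(taxon_labels=list(outgroup))
        if mrca is tree.seed_node:
            raise UnrootedTreeError(
                "outgroup spans the current root; choose a proper subset of leaves"
            )
        length = mrca.edge.length or 0.0
        tree.reroot_at_edge(mrca.edge, length1=length / 2.0, length2=length / 2.0)
        tree.is_rooted = True
        return tree
    if tree.is_rooted or tree.seed_node.num_child_nodes() == 2:
        tree.is_rooted = True
        return tree
    raise UnrootedTreeError(
        "tree has a multifurcating, unflagged root; supply an outgroup or a rooted tree"
    )


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a semicolon-delimited lineage string into ``{rank: name}``.

    Prefixed tokens (``g__TaxonA``) map by prefix; bare tokens map
    positionally from domain downwards. Empty tokens (``g__``) are skipped.
    """
    out: dict[str, str] = {}
    tokens = [t.strip() for t in lineage.split(";") if t.strip()]
    for i, token in enumerate(tokens):
        prefix = token[:3]
        if prefix in RANK_PREFIXES:
            name = token[3:]
            if name:
                out[RANK_PREFIXES[prefix]] = name
        elif i < len(RANKS):
            out[RANKS[i]] = token
    return out


def read_seed_taxonomy(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV of (genome id, lineage string).

    Raises ``ValueError`` if one genome appears with conflicting lineages.
    """
    taxonomy: dict[str, str] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["genome", "lineage"], dtype=str)
    for genome, lineage in zip(df["genome"], df["lineage"]):
        if genome in taxonomy and taxonomy[genome] != lineage:
            raise ValueError(f"conflicting seed lineages for genome {genome!r}")
        taxonomy[genome] = lineage
    return taxonomy


def lineages_by_rank(
    seed_taxonomy: Mapping[str, str],
) -> dict[str, dict[str, set[str]]]:
    """Invert a genome→lineage map to ``{rank: {taxon: genome set}}``."""
    out: dict[str, dict[str, set[str]]] = {r: {} for r in RANKS}
    for genome, lineage in seed_taxonomy.items():
        for rank, name in parse_lineage(lineage).items():
            out[rank].setdefault(name, set()).add(genome)
    return {r: taxa for r, taxa in out.items() if taxa}


def read_table(path: str | os.PathLike, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t")
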