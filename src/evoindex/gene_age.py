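"""Gene-age assignment by simplified Dollo phylostratigraphy.

A gene observed in a focal species and a set of other species is assumed to
have originated once, at the most recent common ancestor of the focal species
and all carriers, and to have been lost (never regained) on lineages where it
is absent. On a dated ultrametric species tree the age of that origin node is
the gene's evolutionary age A_i: time before present since emergence. Genes
private to the focal species fall in the youngest stratum and get A_i = 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import UltrametricityError, ValidationError

DEFAULT_ULTRAMETRIC_TOL = 1e-6


@dataclass
class SpeciesTree:
    """A rooted, dated (ultrametric) species tree with a designated focal leaf."""

    tree: dendropy.Tree
    focal: str

    @classmethod
    def from_newick(cls, newick: str, focal: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls(tree, focal)

    @classmethod
    def from_file(cls, path: str | Path, focal: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
        return cls(tree, focal)

    def __post_init__(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise ValidationError("species tree leaf names must be unique")
        if self.focal not in labels:
            raise ValidationError(
                f"focal species {self.focal!r} is not a leaf of the tree"
            )

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def node_ages_from_tree(
    stree: SpeciesTree, tol: float = DEFAULT_ULTRAMETRIC_TOL
) -> dict[dendropy.Node, float]:
    """Age of every node as distance to its descendant leaves (leaves age 0).

    Raises :class:`UltrametricityError` reporting the worst per-node spread in
    leaf distances when the tree is not ultrametric within ``tol`` (relative
    to tree height, with an absolute floor of ``tol``).
    """
    ages: dict[dendropy.Node, float] = {}
    worst = 0.0
    worst_node = None
    for node in stree.tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
            continue
        child_ages = [
            ages[ch] + (ch.edge.length if ch.edge.length is not None else 0.0)
            for ch in node.child_nodes()
        ]
        spread = max(child_ages) - min(child_ages)
        if spread > worst:
            worst, worst_node = spread, node
        ages[node] = max(child_ages)
    height = max(ages.values()) if ages else 0.0
    if worst > max(tol, tol * height):
        label = worst_node.taxon.label if worst_node.taxon else (worst_node.label or "<internal>")
        raise UltrametricityError(
            f"tree is not ultrametric: worst leaf-distance spread {worst:.6g} "
            f"at node {label!r} exceeds tolerance {max(tol, tol * height):.3g}",
            worst_deviation=worst,
        )
    return ages


def focal_path_nodes(stree: SpeciesTree) -> list[dendropy.Node]:
    """Nodes on the focal-leaf-to-root path, ordered leaf first, root last."""
    node = stree.tree.find_node_with_taxon_label(stree.focal)
    path = []
    while node is not None:
        path.append(node)
        node = node.parent_node
    return path


def focal_path_node_ages(
    stree: SpeciesTree, tol: float = DEFAULT_ULTRAMETRIC_TOL
) -> list[float]:
    """Ages of the focal-path nodes, youngest (0, the focal leaf) to root."""
    ages = node_ages_from_tree(stree, tol=tol)
    return [ages[n] for n in focal_path_nodes(stree)]


@dataclass
class PresenceAbsence:
    """Genes x species boolean ortholog-occurrence matrix.

    The focal column must be all True (every focal gene is observable) and the
    species names must be a subset of the tree's leaves when joined.
    """

    data: pd.DataFrame  # bool, genes x species

    def __post_init__(self) -> None:
        self.data = self.data.astype(bool)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceAbsence":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(int).astype(bool))

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.astype(int)
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def assign_gene_ages(
    pa: PresenceAbsence,
    stree: SpeciesTree,
    tol: float = DEFAULT_ULTRAMETRIC_TOL,
) -> pd.DataFrame:
    """Dollo origin node and age per gene.

    The origin is the MRCA of the focal species and every carrier — i.e. the
    deepest focal-path node whose clade contains a carrier. Genes present only
    in the focal species get the focal leaf itself (age 0, youngest stratum).

    Returns a DataFrame indexed by gene id with columns ``origin_node`` and
    ``age``. Raises when a species is missing from the tree or a gene is
    absent from the focal species.
    """
    species = list(pa.data.columns)
    leaves = set(stree.leaf_labels())
    unknown = [s for s in species if s not in leaves]
    if unknown:
        raise ValidationError(f"species absent from tree: {unknown[:5]}")
    if stree.focal not in species:
        raise ValidationError(f"focal species {stree.focal!r} missing from matrix")
    absent_focal = pa.data.index[~pa.data[stree.focal]].tolist()
    if absent_focal:
        raise ValidationError(
            f"genes absent from focal species {stree.focal!r}: {absent_focal[:5]}"
        )

    path = focal_path_nodes(stree)
    ages_all = node_ages_from_tree(stree, tol=tol)
    path_ages = np.array([ages_all[n] for n in path])
    path_labels = [
        (n.taxon.label if n.taxon else (n.label or f"node@{path_ages[i]:g}"))
        for i, n in enumerate(path)
    ]

    # Depth (focal-path index) at which each leaf attaches to the focal path:
    # the MRCA of {focal, leaf} is the first focal-path ancestor containing it.
    path_index = {id(n): i for i, n in enumerate(path)}
    attach = np.empty(len(species), dtype=int)
    for j, sp in enumerate(species):
        node = stree.tree.find_node_with_taxon_label(sp)
        while id(node) not in path_index:
            node = node.parent_node
        attach[j] = path_index[id(node)]

    mat = pa.data.to_numpy()
    # deepest attach index among carriers (focal itself attaches at 0)
    origin_idx = np.where(mat, attach[None, :], -1).max(axis=1)
    return pd.DataFrame(
        {
            "origin_node": [path_labels[i] for i in origin_idx],
            "age": path_ages[origin_idx],
        },
        index=pa.data.index.rename("gene_id"),
    )


def write_gene_ages(ages: pd.DataFrame, path: str | Path) -> None:
    ages.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")
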