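"""Splitting genome-labeled gene trees into clade-specific orthologous groups.

A gene tree over leaves from ``S`` distinct genomes is carved into csCOGs
(clade-specific clusters of orthologous genes) by repeatedly removing the
clade that maximizes the coverage-paralogy tradeoff index

    S_C^2 / (P_C * S)

where the clade holds ``P_C`` leaves from ``S_C`` genomes.  The index rewards
broad genome coverage (``S_C / S``) and penalizes within-clade paralogy
(``P_C / S_C``).  When the maximizing clade is the root of the remaining
tree, the whole remainder becomes the final group and the iteration stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy

__all__ = [
    "GeneTreeNode",
    "GeneTree",
    "CladeScore",
    "CsCOGPartition",
    "read_gene_tree",
    "gene_tree_from_newick",
    "clade_statistics",
    "extract_cscogs",
]


@dataclass(eq=False)
class GeneTreeNode:
    """Lightweight rooted-tree node; leaves carry (sequence_id, genome_id)."""

    children: list["GeneTreeNode"] = field(default_factory=list)
    sequence_id: str | None = None
    genome_id: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["GeneTreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class GeneTree:
    root: GeneTreeNode

    @property
    def leaf_records(self) -> list[tuple[str, str]]:
        return [(lf.sequence_id, lf.genome_id) for lf in self.root.leaves()]

    @property
    def n_genomes(self) -> int:
        return len({g for _, g in self.leaf_records})


@dataclass(frozen=True)
class CladeScore:
    node: GeneTreeNode
    P_C: int
    S_C: int
    S: int
    postorder_position: int

    @property
    def paralogy_ratio(self) -> float:
        return self.P_C / self.S_C

    @property
    def coverage(self) -> float:
        return self.S_C / self.S

    @property
    def index(self) -> float:
        return self.S_C**2 / (self.P_C * self.S)


@dataclass
class CsCOGPartition:
    """Extracted csCOGs in extraction order; together they partition the leaves."""

    cscogs: list[list[tuple[str, str]]]

    @property
    def n_cscogs(self) -> int:
        return len(self.cscogs)

    def as_frozensets(self) -> set[frozenset]:
        return {frozenset(group) for group in self.cscogs}


def _parse_leaf_label(label: str, genome_delimiter: str = "|") -> tuple[str, str]:
    """Split a leaf label into (sequence_id, genome_id).

    The genome id is the token after the last delimiter; a label without the
    delimiter is its own genome id (one sequence per genome).
    """
    if genome_delimiter in label:
        return label, label.rsplit(genome_delimiter, 1)[1]
    return label, label


def _convert(dnode: dendropy.Node, genome_delimiter: str) -> GeneTreeNode:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
        seq_id, genome_id = _parse_leaf_label(label, genome_delimiter)
        if not genome_id:
            raise ValueError(f"leaf {label!r} has an empty genome id")
        return GeneTreeNode(sequence_id=seq_id, genome_id=genome_id)
    return GeneTreeNode(
        children=[_convert(c, genome_delimiter) for c in dnode.child_nodes()]
    )


def gene_tree_from_newick(
    newick: str,
    genome_delimiter: str = "|",
    midpoint_root_unrooted: bool = True,
) -> GeneTree:
    """Parse a Newick string into a :class:`GeneTree`.

    Trees with a basal multifurcation (the usual representation of unrooted
    trees) are midpoint-rooted first, matching how trees from unrooted
    maximum-likelihood builders are normally consumed.
    """
    dtree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    if midpoint_root_unrooted and len(dtree.seed_node.child_nodes()) > 2:
        for edge in dtree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 1.0
        dtree.reroot_at_midpoint(update_bipartitions=False)
    return GeneTree(root=_convert(dtree.seed_node, genome_delimiter))


def read_gene_tree(path: str | Path, genome_delimiter: str = "|") -> GeneTree:
    return gene_tree_from_newick(
        Path(path).read_text(), genome_delimiter=genome_delimiter
    )


def _postorder(node: GeneTreeNode):
    for c in node.children:
        yield from _postorder(c)
    yield node


def clade_statistics(tree: GeneTree, total_genomes: int | None = None) -> list[CladeScore]:
    """Per-node (P_C, S_C) and derived ratios in one post-order pass.

    ``total_genomes`` (``S``) defaults to the genome count of this tree; during
    iterative extraction it is pinned to the original tree's count.
    """
    if tree.root is None:
        raise ValueError("empty tree")
    S = total_genomes if total_genomes is not None else tree.n_genomes
    if S < 1:
        raise ValueError("tree has no genomes")
    scores: list[CladeScore] = []
    genome_sets: dict[int, set[str]] = {}
    leaf_counts: dict[int, int] = {}
    for pos, node in enumerate(_postorder(tree.root)):
        if node.is_leaf:
            genomes = {node.genome_id}
            count = 1
        else:
            genomes = set()
            count = 0
            for c in node.children:
                genomes |= genome_sets[id(c)]
                count += leaf_counts[id(c)]
        genome_sets[id(node)] = genomes
        leaf_counts[id(node)] = count
        scores.append(
            CladeScore(node=node, P_C=count, S_C=len(genomes), S=S, postorder_position=pos)
        )
    return scores


def _best_clade(scores: list[CladeScore]) -> CladeScore:
    # Max index; ties broken by larger S_C, then smaller P_C, then earlier
    # post-order position.  Deterministic.
    return min(
        scores,
        key=lambda s: (-s.index, -s.S_C, s.P_C, s.postorder_position),
    )


def _detach(root: GeneTreeNode, target: GeneTreeNode) -> GeneTreeNode | None:
    """Remove ``target``'s subtree; suppress unifurcations.  Returns new root."""
    if root is target:
        return None
    if any(c is target for c in root.children):
        root.children = [c for c in root.children if c is not target]
    else:
        new_children = []
        for c in root.children:
            kept = _detach(c, target)
            if kept is not None:
                new_children.append(kept)
        root.children = new_children
    if root.is_leaf and root.sequence_id is None:
        return None  # internal node left childless
    if len(root.children) == 1 and root.sequence_id is None:
        return root.children[0]
    return root


def extract_cscogs(
    tree: GeneTree,
    freeze_total_genomes: bool = True,
    min_clade_size: int = 1,
) -> CsCOGPartition:
    """Iteratively carve csCOGs out of a gene tree.

    Each round scores every clade (leaves included, so orphan sequences can
    become singleton groups), removes the maximal-index clade, and repeats on
    the pruned tree; when the maximum sits at the root, the remaining tree is
    emitted as the final csCOG.  ``S`` stays fixed at the original tree's
    genome count unless ``freeze_total_genomes=False``, which recomputes it
    each round.
    """
    S0 = tree.n_genomes
    root = tree.root
    groups: list[list[tuple[str, str]]] = []
    while root is not None:
        current = GeneTree(root=root)
        S = S0 if freeze_total_genomes else current.n_genomes
        scores = [
            s
            for s in clade_statistics(current, total_genomes=S)
            if s.P_C >= min_clade_size or s.node is root
        ]
        best = _best_clade(scores)
        groups.append([(lf.sequence_id, lf.genome_id) for lf in best.node.leaves()])
        if best.node is root:
            break
        root = _detach(root, best.node)
    return CsCOGPartition(cscogs=groups)
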