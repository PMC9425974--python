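"""Synthetic fixtures with known ground truth for every pipeline stage.

The generators emulate the shapes of real inputs at controlled parameter
settings: protein families diverging from a consensus under a star-tree
substitution model, genome-labeled gene trees with planted whole-subtree
duplications, binary presence/absence histories on a species tree, and
nucleotide sequences with planted tandem repeats.  All generators are
deterministic under a fixed seed and return the ground truth alongside the
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .scoring import AMINO_ACIDS, FamilyAlignment, default_score_model

__all__ = [
    "SimulationSpec",
    "simulate_family_alignment",
    "plant_msr_sequence",
    "simulate_labeled_gene_tree",
    "simulate_presence_history",
]


@dataclass
class SimulationSpec:
    """Parameters of the synthetic-family generator.

    ``theta`` is the per-site substitution probability away from the family
    consensus: 0 gives an invariant family, values near 1 give columns close
    to random assortments of the background distribution.
    """

    seed: int = 0
    n_sequences: int = 10
    n_columns: int = 100
    theta: float = 0.1
    background: np.ndarray | None = None  # defaults to the scoring background
    genomes: list[str] | None = None  # defaults to one genome per sequence

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError(f"theta must lie in [0, 1]; got {self.theta}")
        if self.background is None:
            self.background = default_score_model().background
        if self.genomes is None:
            self.genomes = [f"g{i}" for i in range(self.n_sequences)]
        if len(self.genomes) != self.n_sequences:
            raise ValueError("genomes list must match n_sequences")


def simulate_family_alignment(
    spec: SimulationSpec, family_id: str = "fam"
) -> tuple[FamilyAlignment, float]:
    """Star-tree family: consensus from the background, i.i.d. substitutions.

    Each sequence substitutes each site independently with probability
    ``theta``, drawing the replacement from the background distribution (the
    replacement may coincide with the consensus residue).  Returns the
    alignment and the true ``theta``.
    """
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    consensus = rng.choice(aa, size=spec.n_columns, p=spec.background)
    rows = []
    for i in range(spec.n_sequences):
        mutate = rng.random(spec.n_columns) < spec.theta
        replacements = rng.choice(aa, size=spec.n_columns, p=spec.background)
        residues = np.where(mutate, replacements, consensus)
        rows.append((f"{family_id}_s{i}", spec.genomes[i], "".join(residues)))
    return FamilyAlignment(family_id=family_id, rows=rows), spec.theta


def plant_msr_sequence(
    length: int,
    motif: str,
    copies: int,
    position: int,
    seed: int = 0,
) -> tuple[str, tuple[int, int] | None]:
    """Uniform random nucleotide background with a planted tandem array.

    Returns the sequence and the truth interval ``[position, position +
    copies*len(motif))`` (``None`` when ``copies == 0``).
    """
    rng = np.random.default_rng(seed)
    insert = motif * copies
    if position < 0 or position + len(insert) > length:
        raise ValueError("planted repeat does not fit inside the sequence")
    seq = rng.choice(list("ACGT"), size=length)
    if not insert:
        return "".join(seq), None
    seq[position : position + len(insert)] = list(insert)
    return "".join(seq), (position, position + len(insert))


def _random_topology(labels: list[str], rng: np.random.Generator):
    """Random rooted binary topology by iterative joining; nested-list nodes."""
    nodes: list = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = [nodes[i], nodes[j]]
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    return nodes[0]


def _to_newick(node, leaf_namer) -> str:
    if isinstance(node, str):
        return leaf_namer(node)
    return "(" + ",".join(_to_newick(c, leaf_namer) for c in node) + ")"


def simulate_labeled_gene_tree(
    genomes: list[str],
    duplication_events: int = 0,
    seed: int = 0,
    at_root: bool = False,
) -> tuple[str, list[set[tuple[str, str]]]]:
    """Gene tree = random species topology plus whole-subtree duplications.

    Each duplication replaces a random node (the root when ``at_root`` is
    set) with a bifurcation of two copies of its subtree; leaves of the two
    copies get distinct sequence ids.  The true ortholog partition keeps
    pre- and post-duplication copies apart.  Note that the coverage-paralogy
    index deliberately absorbs *small* duplications into one inclusive group,
    so only duplications of genome-rich subtrees (e.g. ``at_root=True``) are
    expected to be recovered as separate groups.  Returns a Newick string
    with leaf labels ``<sequence_id>|<genome_id>`` and the true partition as
    sets of (sequence_id, genome_id) pairs.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    rng = np.random.default_rng(seed)
    tree = _random_topology(list(genomes), rng)

    def all_nodes(node, acc):
        acc.append(node)
        if isinstance(node, list):
            for c in node:
                all_nodes(c, acc)
        return acc

    def tag(node, suffix):
        # Deep-copy a subtree, tagging leaf genomes with a copy suffix.
        if isinstance(node, str):
            return f"{node}@{suffix}"
        return [tag(c, suffix) for c in node]

    # A duplication at a node replaces it by (copyA, copyB).  Copy tags
    # accumulate, so each leaf's tag chain identifies its ortholog group.
    for event in range(duplication_events):
        nodes = all_nodes(tree, [])
        target = tree if at_root else nodes[rng.integers(len(nodes))]
        dup = [tag(target, f"{event}a"), tag(target, f"{event}b")]
        if target is tree:
            tree = dup
        else:

            def replace(node):
                if isinstance(node, list):
                    for idx, c in enumerate(node):
                        if c is target:
                            node[idx] = dup
                            return True
                        if replace(c):
                            return True
                return False

            replace(tree)

    counter = [0]
    records: list[tuple[str, str, str]] = []  # (label, genome, group_key)

    def namer(tagged: str) -> str:
        genome = tagged.split("@", 1)[0]
        group_key = tagged[len(genome) :]  # the copy-tag chain
        seq_id = f"{genome}_p{counter[0]}"
        counter[0] += 1
        records.append((seq_id, genome, group_key))
        return f"{seq_id}|{genome}"

    newick = _to_newick(tree, namer) + ";"
    groups: dict[str, set[tuple[str, str]]] = {}
    for seq_id, genome, key in records:
        groups.setdefault(key, set()).add((f"{seq_id}|{genome}", genome))
    return newick, list(groups.values())


def simulate_presence_history(
    tree: dendropy.Tree,
    gain_rate: float,
    loss_rate: float,
    seed: int = 0,
    root_present: bool = True,
) -> tuple[dict[str, float], list[tuple[str, str, str]]]:
    """Binary presence process along a rooted species tree.

    Starting from the root state, each edge flips absence to presence with
    probability ``gain_rate`` and presence to absence with probability
    ``loss_rate``.  Returns the node states emitted as 0/1 posteriors (by
    node label) and the exact event list as (parent_label, child_label,
    'gain'|'loss'); a present root contributes the origination event
    ('<root-origination>', root_label, 'gain').
    """
    from .gainloss import ROOT_LABEL, node_name

    if not (0 <= gain_rate <= 1 and 0 <= loss_rate <= 1):
        raise ValueError("rates must be probabilities")
    rng = np.random.default_rng(seed)
    states: dict[str, float] = {}
    events: list[tuple[str, str, str]] = []
    root = tree.seed_node
    states[node_name(root)] = 1.0 if root_present else 0.0
    if root_present:
        events.append((ROOT_LABEL, node_name(root), "gain"))
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = states[node_name(node.parent_node)]
        u = rng.random()
        if parent_state == 0.0:
            state = 1.0 if u < gain_rate else 0.0
            if state == 1.0:
                events.append((node_name(node.parent_node), node_name(node), "gain"))
        else:
            state = 0.0 if u < loss_rate else 1.0
            if state == 0.0:
                events.append((node_name(node.parent_node), node_name(node), "loss"))
        states[node_name(node)] = state
    return states, events
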