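"""Gain/loss interpretation of ancestral-presence posterior probabilities.

Given a rooted species tree and, for one gene family, a posterior probability
of presence at every node (as produced by ancestral phyletic-pattern
reconstruction), parent-to-child differences of at least 0.5 are read as
discrete gain (positive) or loss (negative) events.  Continuous gain and
loss totals are the sums of positive and negative differences, respectively.
The family is ancestral in the clade when the root posterior is >= 0.5;
otherwise it is classed by where its earliest (closest-to-root) gain falls:
an internal edge (intermediate acquisition) or a terminal edge.

Origination is represented by a virtual edge leading into the root from
absence (parent probability 0), so a family present at the root registers one
gain there; totals are reported both with and without this root term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

__all__ = [
    "PresencePosterior",
    "Event",
    "HistorySummary",
    "read_species_tree",
    "read_posteriors",
    "infer_discrete_events",
    "total_gains_losses",
    "classify_ancestrality",
    "summarize_history",
]

EVENT_THRESHOLD = 0.5
ROOT_LABEL = "<root-origination>"


def node_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


@dataclass
class PresencePosterior:
    """Per-node presence posteriors for one family on a rooted species tree."""

    family_id: str
    tree: dendropy.Tree
    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        for name, p in self.probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"posterior for node {name!r} outside [0, 1]: {p}"
                )
        missing = [
            node_name(n)
            for n in self.tree.preorder_node_iter()
            if node_name(n) not in self.probabilities
        ]
        if missing:
            raise ValueError(f"nodes without posteriors: {missing}")

    def prob(self, node: dendropy.Node) -> float:
        return self.probabilities[node_name(node)]


@dataclass(frozen=True)
class Event:
    parent: str  # ROOT_LABEL for the virtual origination edge
    child: str
    kind: str  # "gain" | "loss"
    delta: float
    child_depth: int  # edges from root to the child node
    terminal: bool  # the child is a leaf


@dataclass(frozen=True)
class HistorySummary:
    family_id: str
    n_gain_events: int
    n_loss_events: int
    gain_total: float
    loss_total: float
    gain_total_no_root: float
    ancestral: bool
    ancestrality_class: str
    events: tuple[Event, ...] = field(default=())


def ensure_node_labels(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign deterministic labels (``n0``, ``n1``, ...) to unlabeled nodes."""
    counter = 0
    for node in tree.preorder_node_iter():
        if not node_name(node):
            node.label = f"n{counter}"
        counter += 1
    return tree


def read_species_tree(path: str | Path) -> dendropy.Tree:
    """Rooted Newick species tree; unlabeled internal nodes get ``n<i>`` labels."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return ensure_node_labels(tree)


def read_species_tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return ensure_node_labels(tree)


def read_posteriors(
    path: str | Path, tree: dendropy.Tree
) -> dict[str, PresencePosterior]:
    """TSV of (family_id, node_label, probability) -> per-family posteriors."""
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "node_label": str})
    required = {"family_id", "node_label", "probability"}
    if not required.issubset(df.columns):
        raise ValueError(f"posterior table must have columns {sorted(required)}")
    out = {}
    for fam, sub in df.groupby("family_id"):
        probs = dict(zip(sub["node_label"], sub["probability"].astype(float)))
        out[fam] = PresencePosterior(family_id=fam, tree=tree, probabilities=probs)
    return out


def _edges_with_depth(tree: dendropy.Tree):
    """Yield (parent, child, child_depth) over all real tree edges."""
    depth = {id(tree.seed_node): 0}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            depth[id(child)] = depth[id(node)] + 1
            yield node, child, depth[id(child)]


def infer_discrete_events(
    pp: PresencePosterior, include_root: bool = True
) -> list[Event]:
    """Discrete events: |parent - child| differences >= 0.5, signed.

    With ``include_root`` (default) a root posterior >= 0.5 contributes one
    gain on the virtual origination edge.
    """
    events: list[Event] = []
    root = pp.tree.seed_node
    if include_root:
        p_root = pp.prob(root)
        if p_root >= EVENT_THRESHOLD:
            events.append(
                Event(
                    parent=ROOT_LABEL,
                    child=node_name(root),
                    kind="gain",
                    delta=p_root,
                    child_depth=0,
                    terminal=root.is_leaf(),
                )
            )
    for parent, child, d in _edges_with_depth(pp.tree):
        delta = pp.prob(child) - pp.prob(parent)
        if delta >= EVENT_THRESHOLD:
            kind = "gain"
        elif delta <= -EVENT_THRESHOLD:
            kind = "loss"
        else:
            continue
        events.append(
            Event(
                parent=node_name(parent),
                child=node_name(child),
                kind=kind,
                delta=delta,
                child_depth=d,
                terminal=child.is_leaf(),
            )
        )
    return events


def total_gains_losses(pp: PresencePosterior) -> tuple[float, float, float]:
    """(gain_total, loss_total, gain_total_no_root).

    ``gain_total`` sums positive parent-to-child posterior differences plus
    the root posterior (virtual origination edge); ``loss_total`` sums the
    magnitudes of negative differences.
    """
    gain = 0.0
    loss = 0.0
    for parent, child, _ in _edges_with_depth(pp.tree):
        delta = pp.prob(child) - pp.prob(parent)
        if delta > 0:
            gain += delta
        else:
            loss -= delta
    root_term = pp.prob(pp.tree.seed_node)
    return gain + root_term, loss, gain


def classify_ancestrality(pp: PresencePosterior) -> str:
    """'ancestral' | 'intermediate' | 'terminal' | 'unclassified'.

    Root posterior >= 0.5 is ancestral.  Otherwise the gain event closest to
    the root decides: terminal if it lies on a leaf edge, intermediate on an
    internal edge.  Families without any gain event are unclassified (the
    phyletic pattern admits no specific gain point).
    """
    if pp.prob(pp.tree.seed_node) >= EVENT_THRESHOLD:
        return "ancestral"
    gains = [
        e for e in infer_discrete_events(pp, include_root=False) if e.kind == "gain"
    ]
    if not gains:
        return "unclassified"
    deepest = min(gains, key=lambda e: (e.child_depth, e.terminal))
    return "terminal" if deepest.terminal else "intermediate"


def summarize_history(pp: PresencePosterior) -> HistorySummary:
    events = infer_discrete_events(pp, include_root=True)
    gain_total, loss_total, gain_no_root = total_gains_losses(pp)
    ancestral = pp.prob(pp.tree.seed_node) >= EVENT_THRESHOLD
    return HistorySummary(
        family_id=pp.family_id,
        n_gain_events=sum(e.kind == "gain" for e in events),
        n_loss_events=sum(e.kind == "loss" for e in events),
        gain_total=gain_total,
        loss_total=loss_total,
        gain_total_no_root=gain_no_root,
        ancestral=ancestral,
        ancestrality_class=classify_ancestrality(pp),
        events=tuple(events),
    )
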