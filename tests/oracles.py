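"""Independent brute-force oracles used by the test suite.

These re-derive the quantities under test with explicit loops and elementary
arithmetic, sharing no code path with the library implementation.
"""

from __future__ import annotations

from varcog.scoring import AMINO_ACIDS


def oracle_column_scores(residues, weights, score_dict):
    """Q_x for every candidate amino acid by explicit summation.

    Gap weights are renormalized over the non-gap residues first.
    """
    pairs = [
        (r, w) for r, w in zip(residues, weights) if r in AMINO_ACIDS
    ]
    total = sum(w for _, w in pairs)
    pairs = [(r, w / total) for r, w in pairs]
    q = {}
    for x in AMINO_ACIDS:
        q[x] = sum(w * score_dict[r][x] for r, w in pairs)
    return q


def oracle_consensus(residues, weights, score_dict, tol=1e-9):
    q = oracle_column_scores(residues, weights, score_dict)
    # Ties (within floating-point noise) resolved by alphabetical order.
    q_max = max(q.values())
    best = next(x for x in AMINO_ACIDS if q[x] >= q_max - tol)
    return best, q[best]


def oracle_homogeneity(residues, weights, score_dict, freq_dict, clamp=True):
    q = oracle_column_scores(residues, weights, score_dict)
    c, q_c = oracle_consensus(residues, weights, score_dict)
    q_r = sum(freq_dict[b] * q[b] for b in AMINO_ACIDS)
    h = (q_c - q_r) / (score_dict[c][c] - q_r)
    return max(h, 0.0) if clamp else h


def oracle_smooth(h_values, b):
    """Direct double-loop Gaussian smoothing with end truncation."""
    import math

    n = len(h_values)
    out = []
    for i in range(n):
        num = 0.0
        den = 0.0
        for j in range(n):
            k = math.exp(-(((j - i) / b) ** 2))
            num += h_values[j] * k
            den += k
        out.append(num / den)
    return out


def oracle_binomial_tail(L, k, n, A=4):
    """Exact rational upper binomial tail with t = L - k + 1 trials."""
    from fractions import Fraction
    from math import comb

    t = L - k + 1
    p = Fraction(1, A**k)
    if n <= 0:
        return 1.0
    if n > t:
        return 0.0
    tail = sum(comb(t, i) * p**i * (1 - p) ** (t - i) for i in range(n, t + 1))
    return float(tail)


# ---------------------------------------------------------------------------
# csCOG extraction oracle on nested-tuple trees.


def tuple_tree_from_newick(newick):
    """Parse a (rooted) Newick string into nested tuples of leaf labels."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

    def conv(node):
        if node.is_leaf():
            return node.taxon.label if node.taxon else node.label
        return tuple(conv(c) for c in node.child_nodes())

    return conv(tree.seed_node)


def _tuple_leaves(node):
    if isinstance(node, str):
        return [node]
    out = []
    for c in node:
        out.extend(_tuple_leaves(c))
    return out


def _tuple_clades(node, acc):
    """All clades in post-order as (node, leaves)."""
    if isinstance(node, tuple):
        for c in node:
            _tuple_clades(c, acc)
    acc.append((node, _tuple_leaves(node)))
    return acc


def _genome_of(leaf_label, delimiter="|"):
    return leaf_label.rsplit(delimiter, 1)[1] if delimiter in leaf_label else leaf_label


def _tuple_remove(node, target_id):
    """Rebuild the tree without the subtree whose id() is target_id."""
    if id(node) == target_id:
        return None
    if isinstance(node, str):
        return node
    kept = []
    for c in node:
        r = _tuple_remove(c, target_id)
        if r is not None:
            kept.append(r)
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return tuple(kept)


def oracle_extract_cscogs(newick, delimiter="|"):
    """Exhaustive re-evaluation of every clade each round.

    Returns the partition as a list of frozensets of leaf labels, in
    extraction order.
    """
    tree = tuple_tree_from_newick(newick)
    S = len({_genome_of(lf, delimiter) for lf in _tuple_leaves(tree)})
    groups = []
    while tree is not None:
        clades = _tuple_clades(tree, [])
        best = None
        best_key = None
        for pos, (node, leaves) in enumerate(clades):
            P_C = len(leaves)
            S_C = len({_genome_of(lf, delimiter) for lf in leaves})
            index = S_C * S_C / (P_C * S)
            key = (-index, -S_C, P_C, pos)
            if best_key is None or key < best_key:
                best_key = key
                best = node
        groups.append(frozenset(_tuple_leaves(best)))
        if best is tree:
            break
        tree = _tuple_remove(tree, id(best))
    return groups
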