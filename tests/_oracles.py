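"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (exhaustive
enumeration, per-column censuses, path sums on the raw tree structure)
without calling the implementation paths they check.
"""

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Tree structure helpers (independent of supermatrixqc internals)
# ---------------------------------------------------------------------------

def edges_and_leaves(tree):
    """(splits, leaf labels, attachment map) of a dendropy tree.

    splits: list of frozensets, the leaf set on the far side of each edge
    (child side, rooted at the seed node).  attachment: leaf label -> id of
    the node its pendant edge attaches to.
    """
    below = {}
    splits = []
    attach = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            attach[node.taxon.label] = id(node.parent_node)
        else:
            acc = set()
            for c in node.child_nodes():
                acc |= below[c]
            below[node] = frozenset(acc)
        if node.parent_node is not None:
            splits.append(below[node])
    leaves = frozenset(lbl for s in splits for lbl in s) | below[tree.seed_node]
    return splits, frozenset(leaves), attach


def brute_force_max_subtree(tree, taxon_of, seq_lengths=None):
    """Exhaustive search for the maximally inclusive subtree.

    Candidates: for every edge, the leaf sets on both sides; plus the full
    leaf set.  Validity: every taxon with >= 2 leaves in the candidate must
    either form a clade of the candidate (some edge side that is a subset
    of the candidate equals it; for the full-tree candidate either side
    counts) or have all its leaves attached to one node.  Objective:
    (leaves, taxa, total non-gap length), ties to the lexicographically
    smallest label set.
    """
    seq_lengths = seq_lengths or {}
    splits, leaves, attach = edges_and_leaves(tree)
    sides = set(splits) | {leaves - s for s in splits}
    candidates = set(sides) | {leaves}

    def valid(cand):
        groups = {}
        for lbl in cand:
            groups.setdefault(taxon_of(lbl), set()).add(lbl)
        if cand == leaves:
            clades = sides
        else:
            clades = {x for x in sides if x <= cand}
        for labels in groups.values():
            if len(labels) == 1:
                continue
            labels = frozenset(labels)
            if labels in clades:
                continue
            if len({attach[lbl] for lbl in labels}) == 1:
                continue
            return False
        return True

    best = None
    best_key = None
    for cand in candidates:
        if not cand or not valid(cand):
            continue
        taxa = {taxon_of(lbl) for lbl in cand}
        key = (len(cand), len(taxa), sum(seq_lengths.get(l, 0) for l in cand))
        if (best is None or key > best_key
                or (key == best_key and tuple(sorted(cand)) < tuple(sorted(best)))):
            best, best_key = cand, key
    return set(best) if best else set()


def path_distance_matrix(tree):
    """All-pairs leaf path lengths via explicit root-to-leaf paths."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = path
    labels = sorted(paths)
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pi = paths[labels[i]]
        pj = paths[labels[j]]
        shared = {id(x) for x in pi} & {id(x) for x in pj}
        d = sum(x.edge.length for x in pi if id(x) not in shared)
        d += sum(x.edge.length for x in pj if id(x) not in shared)
        mat[i, j] = mat[j, i] = d
    return labels, mat


# ---------------------------------------------------------------------------
# Column censuses
# ---------------------------------------------------------------------------

def census_missing(rows):
    """Per-row and overall percent of '-'/'X' cells, by direct counting."""
    per = []
    total = 0
    cells = 0
    for row in rows:
        m = sum(1 for c in row if c in "-X")
        per.append(100.0 * m / len(row))
        total += m
        cells += len(row)
    return per, 100.0 * total / cells


def census_parsimony_informative(rows):
    n = 0
    for col in zip(*rows):
        counts = {}
        for c in col:
            if c not in "-X":
                counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            n += 1
    return n


def census_gappy_columns(rows, max_gap_fraction):
    keep = []
    for j, col in enumerate(zip(*rows)):
        gaps = sum(1 for c in col if c == "-")
        if gaps / len(col) <= max_gap_fraction:
            keep.append(j)
    return keep
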