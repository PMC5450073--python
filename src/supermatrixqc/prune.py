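"""Tree-based paralog pruning and gene-occupancy filtering.

Reduces each orthogroup to at most one putatively orthologous sequence per
taxon using its gene tree: branches with low support are collapsed into
polytomies, the maximally inclusive subtree in which every taxon is
represented by at most one sequence (or by an in-paralog clade) is
retained, and within each in-paralog set only the longest sequence is
kept.  Orthogroups are then filtered by gene occupancy (minimum fraction
of taxa present).

Support values are read from internal node labels of the Newick gene
trees and must lie in [0, 1].  Sequences falling outside the chosen
subtree are treated as putative paralogs and discarded.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable

import dendropy

from .align import AlignedOrthogroup, DEFAULT_DELIMITER, taxon_of

DEFAULT_SUPPORT_THRESHOLD = 0.7


# ---------------------------------------------------------------------------
# Gene-tree helpers
# ---------------------------------------------------------------------------

def read_gene_tree(path_or_newick: str, from_string: bool = False) -> dendropy.Tree:
    """Read a Newick gene tree, keeping support values as node labels."""
    kwargs = dict(schema="newick", suppress_internal_node_taxa=True,
                  preserve_underscores=True)
    if from_string:
        return dendropy.Tree.get(data=path_or_newick, **kwargs)
    return dendropy.Tree.get(path=str(path_or_newick), **kwargs)


def _support_of(node: dendropy.Node) -> float | None:
    label = node.label
    if label is None or label == "":
        return None
    try:
        value = float(label)
    except ValueError:
        return None
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"support value {value} outside [0, 1]")
    return value


def dedupe_records(orthogroup: AlignedOrthogroup) -> AlignedOrthogroup:
    """Collapse records with identical (taxon, residues); first ID wins."""
    seen: set[tuple[str, str]] = set()
    kept = []
    for r in orthogroup.records:
        key = (r.taxon_id, r.residues)
        if key in seen:
            continue
        seen.add(key)
        kept.append(r)
    return AlignedOrthogroup(orthogroup.locus_id, kept)


def collapse_low_support(tree: dendropy.Tree,
                         threshold: float = DEFAULT_SUPPORT_THRESHOLD) -> dendropy.Tree:
    """Contract internal edges with support strictly below ``threshold``.

    Edges without a parseable support value are kept.  Returns a new tree.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        support = _support_of(node)
        if support is not None and support < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


# ---------------------------------------------------------------------------
# Maximally inclusive subtree (PhyloTreePruner core)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SubtreeResult:
    """Outcome of the maximally inclusive subtree search."""

    leaf_labels: list[str]
    in_paralogs: dict[str, list[str]]  # taxon -> all retained sequence IDs (>1)
    usable: bool


class _Adj:
    """Undirected adjacency view of a dendropy tree."""

    def __init__(self, tree: dendropy.Tree):
        self.neighbors: dict[int, list[int]] = {}
        self.label: dict[int, str | None] = {}
        nodes = list(tree.preorder_node_iter())
        self.ids = {id(n): i for i, n in enumerate(nodes)}
        for i, n in enumerate(nodes):
            self.neighbors.setdefault(i, [])
            self.label[i] = n.taxon.label if n.taxon is not None else None
            for c in n.child_nodes():
                j = self.ids[id(c)]
                self.neighbors[i].append(j)
                self.neighbors.setdefault(j, []).append(i)
        self.leaves = [i for i in self.neighbors if self.label[i] is not None]

    def component_structure(self, root: int, blocked: int | None):
        """DFS from ``root`` avoiding ``blocked``: returns (leafsets-below,
        children map) for the component viewed as rooted at ``root``."""
        below: dict[int, frozenset] = {}
        children: dict[int, list[int]] = {}
        order = []
        stack = [(root, blocked)]
        while stack:
            node, parent = stack.pop()
            order.append(node)
            kids = [n for n in self.neighbors[node] if n != parent]
            children[node] = kids
            for k in kids:
                stack.append((k, node))
        for node in reversed(order):
            if not children[node]:
                lbl = self.label[node]
                below[node] = frozenset([lbl]) if lbl is not None else frozenset()
            else:
                acc: set = set()
                for k in children[node]:
                    acc |= below[k]
                if self.label[node] is not None:
                    acc.add(self.label[node])
                below[node] = frozenset(acc)
        return below, children


def _candidate_valid(below, children, root, taxon_groups, whole_tree=False):
    """Check the one-per-taxon / in-paralog condition within one component.

    ``taxon_groups``: taxon -> frozenset of its leaf labels in the component
    (only taxa with >= 2 leaves need checking).  For the whole-tree
    candidate the tree is unrooted, so either side of an edge counts as a
    clade.
    """
    clades = set(below.values())
    if whole_tree:
        everything = below[root]
        clades |= {everything - c for c in list(clades)}
    for taxon, labels in taxon_groups.items():
        if labels in clades:
            continue  # forms a clade within the subtree
        # part of the same polytomy: all leaves attach to one common node
        attach = set()
        for node, kids in children.items():
            for k in kids:
                if not children[k] and below[k] and next(iter(below[k])) in labels:
                    attach.add(node)
        # the component root itself may be a leaf
        if not children[root] and below[root] <= labels:
            attach.add(root)
        if len(attach) != 1:
            return False
    return True


def max_inclusive_subtree(
    tree: dendropy.Tree,
    taxon_for_label: Callable[[str], str] | None = None,
    sequence_lengths: dict[str, int] | None = None,
) -> SubtreeResult:
    """Largest subtree with <= 1 sequence per taxon (in-paralogs excepted).

    Every directed edge of the unrooted tree defines a candidate subtree;
    the whole tree is also a candidate.  A candidate is valid when each
    taxon contributes at most one sequence, except taxa whose sequences
    within the candidate form a clade or attach to one polytomy
    (in-paralogs), which may contribute all of them.  Ties break by more
    leaves, more distinct taxa, greater total non-gap residue count (when
    ``sequence_lengths`` is given), then lexicographically smallest leaf
    label set.
    """
    taxon_for_label = taxon_for_label or (lambda s: taxon_of(s, DEFAULT_DELIMITER))
    sequence_lengths = sequence_lengths or {}
    adj = _Adj(tree)
    if len(adj.leaves) == 0:
        return SubtreeResult([], {}, usable=False)

    taxon_by_label = {adj.label[i]: taxon_for_label(adj.label[i]) for i in adj.leaves}

    # candidates: (root, blocked) pairs = directed edges, plus the whole tree
    candidates = [(0, None)]
    for i, nbrs in adj.neighbors.items():
        for j in nbrs:
            candidates.append((j, i))

    def evaluate(root, blocked):
        below, children = adj.component_structure(root, blocked)
        labels = below[root]
        if not labels:
            return None
        groups: dict[str, set] = {}
        for lbl in labels:
            groups.setdefault(taxon_by_label[lbl], set()).add(lbl)
        multi = {t: frozenset(ls) for t, ls in groups.items() if len(ls) > 1}
        if multi and not _candidate_valid(below, children, root, multi,
                                          whole_tree=blocked is None):
            return None
        return labels, groups

    best = None
    best_key = None
    for root, blocked in candidates:
        res = evaluate(root, blocked)
        if res is None:
            continue
        labels, groups = res
        key = (
            len(labels),
            len(groups),
            sum(sequence_lengths.get(l, 0) for l in labels),
        )
        if best is None or key > best_key or (
            key == best_key and tuple(sorted(labels)) < tuple(sorted(best[0]))
        ):
            best, best_key = (labels, groups), key

    if best is None:
        return SubtreeResult([], {}, usable=False)
    labels, groups = best
    in_paralogs = {t: sorted(ls) for t, ls in groups.items() if len(ls) > 1}
    return SubtreeResult(sorted(labels), in_paralogs, usable=len(groups) >= 2)


# ---------------------------------------------------------------------------
# Orthogroup pruning
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PruneReport:
    locus_id: str
    n_leaves_in: int
    n_leaves_retained: int
    n_in_paralogs_collapsed: int
    taxa_retained: list[str]
    usable: bool


def prune_orthogroup(
    orthogroup: AlignedOrthogroup,
    tree: dendropy.Tree,
    threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    delimiter: str = DEFAULT_DELIMITER,
) -> tuple[AlignedOrthogroup, PruneReport]:
    """Full pruning: collapse low support, keep the maximally inclusive
    subtree, keep the longest sequence per in-paralog set, drop all-gap
    columns.  At most one record per taxon survives."""
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    record_ids = {r.sequence_id for r in orthogroup.records}
    if not leaf_labels <= record_ids:
        missing = sorted(leaf_labels - record_ids)[:5]
        raise ValueError(f"tree leaves without alignment records: {missing}")

    collapsed = collapse_low_support(tree, threshold)
    lengths = {r.sequence_id: r.nongap_length() for r in orthogroup.records}
    res = max_inclusive_subtree(
        collapsed,
        taxon_for_label=lambda s: taxon_of(s, delimiter),
        sequence_lengths=lengths,
    )
    keep = set(res.leaf_labels)
    collapsed_count = 0
    for taxon, ids in res.in_paralogs.items():
        # longest (most non-gap residues); ties to the smaller sequence ID
        winner = sorted(ids, key=lambda i: (-lengths.get(i, 0), i))[0]
        for i in ids:
            if i != winner:
                keep.discard(i)
                collapsed_count += 1
    pruned = orthogroup.subset(keep).drop_all_gap_columns()
    report = PruneReport(
        locus_id=orthogroup.locus_id,
        n_leaves_in=len([lf for lf in tree.leaf_node_iter()]),
        n_leaves_retained=len(keep),
        n_in_paralogs_collapsed=collapsed_count,
        taxa_retained=sorted(pruned.taxa()),
        usable=res.usable,
    )
    return pruned, report


def prune_tree_to_leaves(tree: dendropy.Tree, labels) -> dendropy.Tree | None:
    """Induced subtree on the given leaf labels (None when < 2 remain)."""
    labels = set(labels)
    keep = [t for t in tree.taxon_namespace if t.label in labels]
    if len(keep) < 2:
        return None
    work = tree.clone(depth=1)
    work.retain_taxa(keep)
    return work


def occupancy_min_taxa(fraction: float, n_total_taxa: int) -> int:
    """Smallest integer >= fraction * n_total_taxa."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if n_total_taxa < 1:
        raise ValueError("n_total_taxa must be >= 1")
    return int(math.ceil(fraction * n_total_taxa - 1e-9))


def occupancy_filter(
    orthogroups: list[AlignedOrthogroup], fraction: float, n_total_taxa: int
) -> tuple[list[AlignedOrthogroup], int]:
    """Keep orthogroups present in at least ``ceil(fraction * n)`` taxa."""
    min_taxa = occupancy_min_taxa(fraction, n_total_taxa)
    kept = [og for og in orthogroups if len(og.taxa()) >= min_taxa]
    return kept, min_taxa


def prune_report_tsv(reports: list[PruneReport], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "locus": r.locus_id,
                "leaves_in": r.n_leaves_in,
                "leaves_retained": r.n_leaves_retained,
                "in_paralogs_collapsed": r.n_in_paralogs_collapsed,
                "n_taxa": len(r.taxa_retained),
                "usable": r.usable,
            }
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)
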