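"""Per-locus branch-length and compositional heterogeneity diagnostics.

Branch-length indices computed on each gene tree:

* ``avg_pd`` — mean pairwise patristic distance between leaves;
* ``tip_root_sd`` — sample standard deviation of root-to-tip path lengths
  after midpoint rooting;
* ``lb_index`` — dispersion (sample SD) of per-taxon long-branch (LB)
  scores, where ``LB_i = 100 * (meanPD_i / grand-mean PD - 1)``.

Compositional indices computed on each alignment (gaps and ``X`` excluded
from all counts):

* ``chisq`` — Pearson chi-square test of residue-composition homogeneity
  across taxa (no continuity correction; unobserved residues dropped);
* ``rcfv`` — relative composition frequency variability, the mean over
  taxa of the summed absolute deviations of per-taxon residue frequencies
  from the across-taxon mean frequencies.

Loci are eliminated in two stages: first any locus at or above
``median + 1.5 * IQR`` on any branch-length index, then — with quantiles
recomputed on the survivors — any locus with chi-square p < alpha or an
IQR-flagged RCFV.
"""

from __future__ import annotations

import dataclasses
import warnings

import dendropy
import numpy as np
from scipy.stats import chi2 as chi2_dist

from .align import AlignedOrthogroup, MISSING_CODE

BRANCH_INDICES = ("avg_pd", "tip_root_sd", "lb_index")


@dataclasses.dataclass
class IQRRule:
    """Outlier rule: flag values >= median + multiplier * IQR."""

    multiplier: float = 1.5

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")


@dataclasses.dataclass
class LocusDiagnostics:
    locus_id: str
    avg_pd: float
    tip_root_sd: float
    lb_index: float
    rcfv: float
    chisq_p: float
    eliminated_by: set = dataclasses.field(default_factory=set)


# ---------------------------------------------------------------------------
# Branch-length indices
# ---------------------------------------------------------------------------

def _leaf_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """All-pairs patristic distance matrix via a single postorder pass."""
    labels: list[str] = []
    carry: dict = {}  # node -> list of (leaf index, distance to node)
    pairs: list[tuple[int, int, float]] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            idx = len(labels)
            labels.append(node.taxon.label)
            carry[node] = [(idx, 0.0)]
        else:
            groups = []
            for child in node.child_nodes():
                bl = child.edge.length
                if bl is None:
                    raise ValueError("tree has a missing branch length")
                groups.append([(i, d + bl) for i, d in carry.pop(child)])
            merged = []
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i, di in groups[gi]:
                        for j, dj in groups[gj]:
                            pairs.append((i, j, di + dj))
                merged.extend(groups[gi])
            carry[node] = merged
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j, d in pairs:
        mat[i, j] = mat[j, i] = d
    return labels, mat


def patristic_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """(leaf labels, symmetric path-length matrix)."""
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("need at least 2 leaves")
    return _leaf_distances(tree)


def lb_scores(tree: dendropy.Tree) -> dict[str, float]:
    """Per-taxon LB score: percentage deviation of the taxon's mean
    pairwise patristic distance from the tree-wide mean."""
    labels, mat = patristic_distances(tree)
    n = len(labels)
    if n < 3:
        raise ValueError("LB scores need at least 3 leaves")
    row_means = mat.sum(axis=1) / (n - 1)
    grand = row_means.mean()
    if grand <= 0:
        raise ValueError("all branch lengths are zero; LB score undefined")
    return {lbl: 100.0 * (rm / grand - 1.0) for lbl, rm in zip(labels, row_means)}


def tip_to_root_sd(tree: dendropy.Tree) -> float:
    """Sample SD of root-to-tip distances.

    A rooted input (bifurcating root) keeps its root; an unrooted input
    (root degree > 2) is midpoint-rooted first.
    """
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves")
    work = tree.clone(depth=1)
    for edge in work.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    _, mat = _leaf_distances(work)
    if mat.max() <= 0:
        return 0.0
    if len(work.seed_node.child_nodes()) > 2:
        work.reroot_at_midpoint(update_bipartitions=False)
    depths = []
    for leaf in work.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    return float(np.std(depths, ddof=1))


def locus_branch_indices(tree: dendropy.Tree) -> tuple[float, float, float]:
    """(avg_pd, tip_root_sd, lb_index) for one gene tree."""
    labels, mat = patristic_distances(tree)
    n = len(labels)
    if n < 3:
        raise ValueError("branch indices need at least 3 leaves")
    iu = np.triu_indices(n, k=1)
    avg_pd = float(mat[iu].mean())
    scores = np.array(list(lb_scores(tree).values())) if avg_pd > 0 else np.zeros(n)
    lb_index = float(np.std(scores, ddof=1))
    return avg_pd, tip_to_root_sd(tree), lb_index


# ---------------------------------------------------------------------------
# Compositional indices
# ---------------------------------------------------------------------------

def _residue_counts(orthogroup: AlignedOrthogroup) -> tuple[list[str], np.ndarray]:
    """Per-taxon residue counts (20 columns), dropping zero-count taxa."""
    codes = orthogroup.codes()
    taxa, counts = [], []
    for rec, row in zip(orthogroup.records, codes):
        c = np.bincount(row[row < MISSING_CODE], minlength=20).astype(float)
        if c.sum() == 0:
            warnings.warn(
                f"taxon {rec.taxon_id!r} has no countable residues in "
                f"{orthogroup.locus_id!r}; dropped", RuntimeWarning)
            continue
        taxa.append(rec.taxon_id)
        counts.append(c)
    return taxa, np.array(counts) if counts else np.zeros((0, 20))


def composition_chisq(orthogroup: AlignedOrthogroup) -> tuple[float, int, float]:
    """Pearson chi-square homogeneity test of residue composition.

    Returns (statistic, df, p).  Residues absent from the whole locus are
    excluded from the table and the degrees of freedom.
    """
    taxa, counts = _residue_counts(orthogroup)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa with countable residues")
    counts = counts[:, counts.sum(axis=0) > 0]
    r, c = counts.shape
    if c < 2:
        return 0.0, 0, 1.0
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = float(cells.sum())
    df = (r - 1) * (c - 1)
    p = float(chi2_dist.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def rcfv(orthogroup: AlignedOrthogroup) -> float:
    """Relative composition frequency variability across taxa."""
    taxa, counts = _residue_counts(orthogroup)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa with countable residues")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    mu = freqs.mean(axis=0)
    return float(np.abs(freqs - mu).sum() / len(taxa))


# ---------------------------------------------------------------------------
# Elimination rules
# ---------------------------------------------------------------------------

def iqr_flags(values, rule: IQRRule = IQRRule()) -> np.ndarray:
    """Flag values >= median + multiplier * IQR (type-7 quantiles).

    With all values equal the IQR is 0 and *every* value is flagged;
    callers skip filtering on an index when its IQR is 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for stable quartiles")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    cutoff = med + rule.multiplier * (q3 - q1)
    return values >= cutoff


def _safe_iqr_flags(values, rule: IQRRule) -> np.ndarray:
    """IQR flags that skip degenerate inputs: NaN values (indices undefined
    for a locus) are never flagged, and an IQR of 0 disables the index."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 4:
        return np.zeros(values.size, dtype=bool)
    q1, med, q3 = np.quantile(finite, [0.25, 0.5, 0.75])
    if q3 - q1 <= 0:
        return np.zeros(values.size, dtype=bool)
    cutoff = med + rule.multiplier * (q3 - q1)
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(values), values >= cutoff, False)


def compute_diagnostics(
    orthogroups: list[AlignedOrthogroup], trees: list[dendropy.Tree]
) -> list[LocusDiagnostics]:
    """Branch-length and compositional indices for each (locus, tree) pair."""
    out = []
    for og, tree in zip(orthogroups, trees):
        if len(tree.leaf_nodes()) >= 3:
            avg_pd, trsd, lb = locus_branch_indices(tree)
        else:
            # two-taxon loci carry no branch-heterogeneity signal
            avg_pd = trsd = lb = float("nan")
        stat, df, p = composition_chisq(og)
        out.append(LocusDiagnostics(og.locus_id, avg_pd, trsd, lb, rcfv(og), p))
    return out


def filter_loci(
    diagnostics: list[LocusDiagnostics],
    alpha: float = 0.05,
    rule: IQRRule = IQRRule(),
) -> tuple[list[str], list[LocusDiagnostics]]:
    """Two-stage elimination.

    Stage 1 removes loci IQR-flagged on any branch-length index; stage 2,
    with quantiles recomputed on the stage-1 survivors, removes loci with
    chi-square p < alpha or an IQR-flagged RCFV.  Returns (retained locus
    IDs, diagnostics annotated with elimination causes).
    """
    flag_name = {"avg_pd": "PD", "tip_root_sd": "TIPROOT", "lb_index": "LB"}
    for idx in BRANCH_INDICES:
        vals = [getattr(d, idx) for d in diagnostics]
        for d, fl in zip(diagnostics, _safe_iqr_flags(vals, rule)):
            if fl:
                d.eliminated_by.add(flag_name[idx])
    survivors = [d for d in diagnostics if not d.eliminated_by]

    for d in survivors:
        if d.chisq_p < alpha:
            d.eliminated_by.add("CHI2")
    rcfv_vals = [d.rcfv for d in survivors]
    if survivors:
        for d, fl in zip(survivors, _safe_iqr_flags(rcfv_vals, rule)):
            if fl:
                d.eliminated_by.add("RCFV")
    retained = [d.locus_id for d in diagnostics if not d.eliminated_by]
    return retained, diagnostics


def diagnostics_tsv(diagnostics: list[LocusDiagnostics], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "locus": d.locus_id,
                "avg_pd": d.avg_pd,
                "tip_root_sd": d.tip_root_sd,
                "lb_index": d.lb_index,
                "rcfv": d.rcfv,
                "chisq_p": d.chisq_p,
                "eliminated_by": ",".join(sorted(d.eliminated_by)) or "-",
            }
            for d in diagnostics
        ]
    ).to_csv(path, sep="\t", index=False)
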