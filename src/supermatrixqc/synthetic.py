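"""Seeded synthetic phylogenomic datasets with recorded ground truth.

Emulates the statistical structure a transcriptome-based supermatrix
pipeline has to cope with: a Yule species tree; per-locus gene trees with
Poisson duplication/loss (the source of in- and out-paralogs); amino-acid
alignments simulated along each gene tree; one or more long-branch taxa
(pendant edges scaled up); a subset of loci in which designated taxa drift
toward a biased residue composition; terminal truncation of some sequences
(partial contigs); and Beta-distributed per-taxon locus occupancy.

Every generator is a pure function of its arguments including the seed,
and every emitted sequence is traceable to exactly one gene-tree leaf in
the truth tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import dendropy
import numpy as np

from .align import AA_INDEX, AlignedOrthogroup, Record, write_orthogroup
from .likelihood import simulate_along_tree
from .models import N_STATES, get_model

#: Default compositional attractor for biased taxa: hydrophobic enrichment.
DEFAULT_BIAS_TARGET = np.zeros(N_STATES)
for _a in "AILMV":
    DEFAULT_BIAS_TARGET[AA_INDEX[_a]] = 0.2


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticConfig:
    """Study-condition knobs for one synthetic dataset."""

    n_taxa: int = 20
    n_loci: int = 100
    locus_length_range: tuple[int, int] = (120, 300)
    birth_rate: float = 1.0
    duplication_rate: float = 0.2
    loss_rate: float = 0.2
    long_branch_taxa: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"t01": 5.0})
    biased_taxa: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"t05": 0.5, "t06": 0.5})
    biased_loci_fraction: float = 0.3
    occupancy_alpha: float = 2.0
    occupancy_beta: float = 1.0
    nni_noise_prob: float = 0.1
    truncation_prob: float = 0.1
    truncation_max_fraction: float = 0.3
    model: str = "LG"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_loci < 1:
            raise ValueError("need n_taxa >= 2 and n_loci >= 1")
        lo, hi = self.locus_length_range
        if not (0 < lo <= hi):
            raise ValueError("locus_length_range must satisfy 0 < min <= max")
        for rate in (self.birth_rate, self.duplication_rate, self.loss_rate):
            if rate < 0:
                raise ValueError("rates must be non-negative")
        for frac in (self.biased_loci_fraction, self.nni_noise_prob,
                     self.truncation_prob, self.truncation_max_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.occupancy_alpha <= 0 or self.occupancy_beta <= 0:
            raise ValueError("occupancy Beta parameters must be positive")
        if any(m <= 1 for m in self.long_branch_taxa.values()):
            raise ValueError("long-branch multipliers must exceed 1")
        if any(not 0.0 <= b <= 1.0 for b in self.biased_taxa.values()):
            raise ValueError("bias intensities must be in [0, 1]")
        names = set(taxon_names(self.n_taxa))
        unknown = (set(self.long_branch_taxa) | set(self.biased_taxa)) - names
        if unknown:
            raise ValueError(f"unknown taxa in config: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "locus_length_range" in data:
            data["locus_length_range"] = tuple(data["locus_length_range"])
        return cls(**data)


def taxon_names(n_taxa: int) -> list[str]:
    width = max(2, len(str(n_taxa)))
    return [f"t{i + 1:0{width}d}" for i in range(n_taxa)]


@dataclasses.dataclass
class LocusTruth:
    locus_id: str
    gene_tree: dendropy.Tree            # full tree, pre-masking
    is_primary: dict[str, bool]         # sequence id -> true-ortholog flag
    retained: dict[str, bool]           # sequence id -> survived occupancy mask
    biased: bool
    seed: int


@dataclasses.dataclass
class SyntheticTruth:
    species_tree: dendropy.Tree
    loci: list[LocusTruth]
    long_branch_taxa: dict[str, float]
    biased_taxa: dict[str, float]
    seed: int


@dataclasses.dataclass
class SyntheticDataset:
    orthogroups: list[AlignedOrthogroup]   # post-masking
    gene_trees: list[dendropy.Tree]        # post-masking, with supports
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(n_taxa: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Yule (pure-birth) tree scaled to unit height; ultrametric, binary."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    times = {root: 0.0}
    tips = [root]
    t = 0.0
    while len(tips) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        node = tips.pop(rng.integers(len(tips)))
        times[node] = t
        for _ in range(2):
            child = node.new_child()
            tips.append(child)
    present = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    names = taxon_names(n_taxa)
    for leaf in tips:
        times[leaf] = present
    height = present - times[root]
    # deterministic label order: assign along a preorder traversal
    idx = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.taxon = ns.new_taxon(names[idx])
            idx += 1
        if node.parent_node is not None:
            node.edge.length = (times[node] - times[node.parent_node]) / height
    return tree


def _node_times(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    times = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            times[node] = times[node.parent_node] + (node.edge.length or 0.0)
    return times


# ---------------------------------------------------------------------------
# Gene trees under duplication/loss
# ---------------------------------------------------------------------------

class _GNode:
    __slots__ = ("children", "time", "kind", "taxon", "new_copy", "label")

    def __init__(self, time, kind, taxon=None):
        self.children: list["_GNode"] = []
        self.time = time
        self.kind = kind            # "speciation" | "duplication" | "leaf"
        self.taxon = taxon
        self.new_copy = False       # root of a duplicated (paralogous) lineage
        self.label = None


def simulate_gene_tree(species_tree: dendropy.Tree, duplication_rate: float,
                       loss_rate: float, seed: int):
    """Evolve a gene tree inside the species tree under independent Poisson
    duplication and loss.

    Returns ``(tree, is_primary, n_duplications)`` or ``None`` when every
    copy is lost.  Leaves are labelled ``taxon|cN``; ``is_primary`` marks
    leaves that descend from the root copy without any duplicated lineage
    on the path (a mutually orthologous, at-most-one-per-taxon set).
    """
    if duplication_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    total = duplication_rate + loss_rate
    times = _node_times(species_tree)

    def along_branch(sn: dendropy.Node, t_start: float):
        end = times[sn]
        w = rng.exponential(1.0 / total) if total > 0 else np.inf
        if t_start + w >= end - 1e-15 or total == 0:
            return arrive(sn, end)
        t_event = t_start + w
        if rng.random() < duplication_rate / total:
            original = along_branch(sn, t_event)
            copy = along_branch(sn, t_event)
            if copy is not None:
                copy.new_copy = True
            alive = [c for c in (original, copy) if c is not None]
            if not alive:
                return None
            if len(alive) == 1:
                return alive[0]
            node = _GNode(t_event, "duplication")
            node.children = alive
            return node
        return None  # loss

    def arrive(sn: dendropy.Node, end: float):
        if sn.is_leaf():
            return _GNode(end, "leaf", taxon=sn.taxon.label)
        kids = [along_branch(c, end) for c in sn.child_nodes()]
        alive = [k for k in kids if k is not None]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        node = _GNode(end, "speciation")
        node.children = alive
        return node

    root = arrive(species_tree.seed_node, 0.0)
    if root is None or root.kind == "leaf":
        return None

    # copy indices per taxon, in a deterministic traversal order
    counters: dict[str, int] = {}
    is_primary: dict[str, bool] = {}
    n_dup = 0

    ns = dendropy.TaxonNamespace()
    out = dendropy.Tree(taxon_namespace=ns)

    def build(gnode: _GNode, dnode: dendropy.Node, on_paralog_path: bool):
        nonlocal n_dup
        on_paralog_path = on_paralog_path or gnode.new_copy
        if gnode.kind == "leaf":
            counters[gnode.taxon] = counters.get(gnode.taxon, 0) + 1
            label = f"{gnode.taxon}|c{counters[gnode.taxon]}"
            gnode.label = label
            dnode.taxon = ns.new_taxon(label)
            is_primary[label] = not on_paralog_path
            return
        if gnode.kind == "duplication":
            n_dup += 1
            dnode.label = None
        for child in gnode.children:
            dchild = dnode.new_child()
            dchild.edge.length = child.time - gnode.time
            build(child, dchild, on_paralog_path)

    build(root, out.seed_node, False)
    return out, is_primary, n_dup


def perturb_gene_tree(tree: dendropy.Tree, nni_prob: float, seed: int) -> dendropy.Tree:
    """Optional topological noise: each internal edge is NNI-swapped with
    probability ``nni_prob`` and given a Uniform(0,1) support; untouched
    internal edges get support 1.0."""
    rng = np.random.default_rng(seed)
    work = tree.clone(depth=1)
    for node in work.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        parent = node.parent_node
        siblings = [c for c in parent.child_nodes() if c is not node]
        if len(node.child_nodes()) == 2 and siblings and rng.random() < nni_prob:
            a = node.child_nodes()[int(rng.integers(2))]
            s = siblings[int(rng.integers(len(siblings)))]
            ea, es = a.edge.length, s.edge.length
            node.remove_child(a)
            parent.remove_child(s)
            node.add_child(s)
            parent.add_child(a)
            a.edge.length, s.edge.length = ea, es
            node.label = f"{rng.uniform():.3f}"
        else:
            node.label = "1.000"
    return work


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def simulate_biased_alignment(
    gene_tree, model, length: int,
    rate_multipliers: dict[str, float] | None = None,
    bias_target: np.ndarray | None = None,
    bias_intensity: float = 0.0,
    biased_taxa=(),
    seed: int = 0,
    locus_id: str = "locus",
) -> AlignedOrthogroup:
    """Alignment along a gene tree with optional long-branch and bias effects.

    Pendant edges of taxa in ``rate_multipliers`` evolve with scaled length;
    pendant edges of ``biased_taxa`` evolve under the same exchangeabilities
    but equilibrium ``(1 - b) * pi + b * bias_target``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= bias_intensity <= 1.0:
        raise ValueError("bias_intensity must be in [0, 1]")
    rate_multipliers = rate_multipliers or {}
    if any(m <= 0 for m in rate_multipliers.values()):
        raise ValueError("rate multipliers must be positive")
    if isinstance(model, str):
        model = get_model(model)
    taxon_models = {}
    if bias_intensity > 0 and biased_taxa:
        target = DEFAULT_BIAS_TARGET if bias_target is None else np.asarray(bias_target, float)
        pi = (1.0 - bias_intensity) * model.frequencies + bias_intensity * target
        biased_model = model.with_frequencies(np.maximum(pi, 1e-8))
        taxon_models = {t: biased_model for t in biased_taxa}
    return simulate_along_tree(
        gene_tree, model, length, seed, locus_id=locus_id,
        rate_multipliers=rate_multipliers, taxon_models=taxon_models)


def _truncate_records(og: AlignedOrthogroup, prob: float, max_fraction: float,
                      rng: np.random.Generator) -> AlignedOrthogroup:
    """Emulate partial contigs: gap out a random prefix or suffix."""
    if prob <= 0 or max_fraction <= 0:
        return og
    recs = []
    for r in og.records:
        if rng.random() < prob:
            cut = int(rng.integers(1, max(2, int(len(r.residues) * max_fraction) + 1)))
            if rng.random() < 0.5:
                residues = "-" * cut + r.residues[cut:]
            else:
                residues = r.residues[:-cut] + "-" * cut
            recs.append(dataclasses.replace(r, residues=residues))
        else:
            recs.append(r)
    return AlignedOrthogroup(og.locus_id, recs)


# ---------------------------------------------------------------------------
# Occupancy mask
# ---------------------------------------------------------------------------

def apply_occupancy_mask(
    orthogroups: list[AlignedOrthogroup],
    occupancy_alpha: float,
    occupancy_beta: float,
    seed: int,
) -> tuple[list[AlignedOrthogroup], dict[str, set]]:
    """Per locus, retain each taxon with Beta(alpha, beta) probability.

    Returns the reduced loci (empty ones dropped) and the truth mask
    ``locus_id -> retained taxon set``.
    """
    if occupancy_alpha <= 0 or occupancy_beta <= 0:
        raise ValueError("Beta parameters must be positive")
    rng = np.random.default_rng(seed)
    masked, mask = [], {}
    for og in orthogroups:
        taxa = og.taxa()
        probs = rng.beta(occupancy_alpha, occupancy_beta, size=len(taxa))
        draws = rng.random(len(taxa))
        keep_taxa = {t for t, p, u in zip(taxa, probs, draws) if u < p}
        mask[og.locus_id] = keep_taxa
        kept = AlignedOrthogroup(
            og.locus_id, [r for r in og.records if r.taxon_id in keep_taxa])
        if kept.records:
            masked.append(kept)
    return masked, mask


def _prune_tree_to_labels(tree: dendropy.Tree, labels: set) -> dendropy.Tree | None:
    from .prune import prune_tree_to_leaves

    return prune_tree_to_leaves(tree, labels)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig, out_dir=None) -> SyntheticDataset:
    """Simulate a full dataset; optionally write FASTA/Newick/truth files.

    All randomness derives from ``config.seed`` through named substreams,
    so identical configs give byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    sub = {name: int(s) for name, s in zip(
        ("species", "loci", "mask"), rng.integers(2 ** 31, size=3))}
    species = simulate_species_tree(config.n_taxa, config.birth_rate, sub["species"])
    model = get_model(config.model)
    locus_rng = np.random.default_rng(sub["loci"])

    loci: list[LocusTruth] = []
    orthogroups: list[AlignedOrthogroup] = []
    gene_trees: list[dendropy.Tree] = []
    width = len(str(config.n_loci))
    for i in range(config.n_loci):
        locus_id = f"og{i + 1:0{width}d}"
        lseed = int(locus_rng.integers(2 ** 31))
        lrng = np.random.default_rng(lseed)
        sim = simulate_gene_tree(
            species, config.duplication_rate, config.loss_rate,
            int(lrng.integers(2 ** 31)))
        if sim is None:
            continue
        tree, is_primary, _ = sim
        for leaf in tree.leaf_node_iter():  # long-branch taxa: scale pendant edges
            taxon = leaf.taxon.label.split("|", 1)[0]
            if taxon in config.long_branch_taxa:
                leaf.edge.length *= config.long_branch_taxa[taxon]
        length = int(lrng.integers(config.locus_length_range[0],
                                   config.locus_length_range[1] + 1))
        biased = bool(lrng.random() < config.biased_loci_fraction) and bool(config.biased_taxa)
        intensity = max(config.biased_taxa.values()) if biased else 0.0
        og = simulate_biased_alignment(
            tree, model, length,
            bias_intensity=intensity,
            biased_taxa=list(config.biased_taxa) if biased else (),
            seed=int(lrng.integers(2 ** 31)),
            locus_id=locus_id,
        )
        og = _truncate_records(og, config.truncation_prob,
                               config.truncation_max_fraction, lrng)
        noisy = perturb_gene_tree(tree, config.nni_noise_prob,
                                  int(lrng.integers(2 ** 31)))
        loci.append(LocusTruth(locus_id, tree, is_primary,
                               {sid: True for sid in is_primary}, biased, lseed))
        orthogroups.append(og)
        gene_trees.append(noisy)

    masked, mask = apply_occupancy_mask(
        orthogroups, config.occupancy_alpha, config.occupancy_beta, sub["mask"])
    kept_ids = {og.locus_id for og in masked}
    final_ogs, final_trees, final_loci = [], [], []
    for og, tree, lt in zip(orthogroups, gene_trees, loci):
        if og.locus_id not in kept_ids:
            continue
        keep_taxa = mask[og.locus_id]
        for sid in lt.retained:
            lt.retained[sid] = sid.split("|", 1)[0] in keep_taxa
        masked_og = next(m for m in masked if m.locus_id == og.locus_id)
        labels = {r.sequence_id for r in masked_og.records}
        pruned_tree = _prune_tree_to_labels(tree, labels)
        if pruned_tree is None:
            continue
        final_ogs.append(masked_og)
        final_trees.append(pruned_tree)
        final_loci.append(lt)

    truth = SyntheticTruth(species, final_loci, dict(config.long_branch_taxa),
                           dict(config.biased_taxa), config.seed)
    dataset = SyntheticDataset(final_ogs, final_trees, truth)
    if out_dir is not None:
        write_dataset(dataset, out_dir, config)
    return dataset


def write_dataset(dataset: SyntheticDataset, out_dir, config: SyntheticConfig) -> str:
    """Write per-locus FASTA + Newick, truth tables and a digest manifest.

    Returns the manifest digest (stable across identical configs).
    """
    os.makedirs(os.path.join(out_dir, "loci"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "trees"), exist_ok=True)
    digest = hashlib.sha256()
    for og, tree in zip(dataset.orthogroups, dataset.gene_trees):
        fa = os.path.join(out_dir, "loci", f"{og.locus_id}.fasta")
        write_orthogroup(og, fa)
        nwk = tree.as_string(schema="newick", suppress_rooting=True)
        with open(os.path.join(out_dir, "trees", f"{og.locus_id}.nwk"), "w") as fh:
            fh.write(nwk)
        with open(fa, "rb") as fh:
            digest.update(fh.read())
        digest.update(nwk.encode())

    rows = ["locus\tsequence_id\ttaxon\tis_primary\tretained"]
    for lt in dataset.truth.loci:
        for sid in sorted(lt.is_primary):
            rows.append("\t".join([
                lt.locus_id, sid, sid.split("|", 1)[0],
                str(int(lt.is_primary[sid])), str(int(lt.retained[sid]))]))
    seq_table = "\n".join(rows) + "\n"
    with open(os.path.join(out_dir, "truth_sequences.tsv"), "w") as fh:
        fh.write(seq_table)
    digest.update(seq_table.encode())

    rows = ["locus\tbiased\tseed"]
    for lt in dataset.truth.loci:
        rows.append(f"{lt.locus_id}\t{int(lt.biased)}\t{lt.seed}")
    locus_table = "\n".join(rows) + "\n"
    with open(os.path.join(out_dir, "truth_loci.tsv"), "w") as fh:
        fh.write(locus_table)
    digest.update(locus_table.encode())

    with open(os.path.join(out_dir, "species_tree.nwk"), "w") as fh:
        fh.write(dataset.truth.species_tree.as_string(
            schema="newick", suppress_rooting=True))

    manifest = {
        "n_loci": len(dataset.orthogroups),
        "seed": config.seed,
        "digest": digest.hexdigest(),
        "long_branch_taxa": config.long_branch_taxa,
        "biased_taxa": config.biased_taxa,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest["digest"]
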