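"""End-to-end pipeline: simulate/load -> dedupe -> prune -> occupancy ->
diagnose/filter -> trim -> concatenate -> summarize (+ optional topology
tests), with per-stage logging and a reproducible manifest.

Stage order follows the construction procedure the package implements:
paralog pruning first, occupancy filtering on the pruned taxon counts,
locus-diagnostic elimination on the survivors, then gappy-site removal per
locus and concatenation.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os

import dendropy

from . import diagnostics as diag
from . import prune as prune_mod
from . import supermatrix as sm
from .align import AlignedOrthogroup, read_orthogroup
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("supermatrixqc")


@dataclasses.dataclass
class PipelineConfig:
    synthetic: SyntheticConfig | None = None
    input_loci_dir: str | None = None
    input_trees_dir: str | None = None
    occupancy_fractions: tuple[float, ...] = (0.5,)
    support_threshold: float = 0.7
    iqr_multiplier: float = 1.5
    chisq_alpha: float = 0.05
    gap_fraction: float = 0.5
    apply_locus_filter: bool = True
    apply_trim: bool = True
    n_total_taxa: int | None = None
    out_dir: str = "smqc_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synthetic is None and self.input_loci_dir is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        for f in self.occupancy_fractions:
            if not 0.0 < f <= 1.0:
                raise ValueError("occupancy fractions must be in (0, 1]")
        if not 0.0 <= self.support_threshold <= 1.0:
            raise ValueError("support threshold must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "synthetic" in data and data["synthetic"] is not None:
            syn = dict(data["synthetic"])
            if "locus_length_range" in syn:
                syn["locus_length_range"] = tuple(syn["locus_length_range"])
            data["synthetic"] = SyntheticConfig(**syn)
        if "occupancy_fractions" in data:
            data["occupancy_fractions"] = tuple(data["occupancy_fractions"])
        return cls(**data)


def load_inputs(config: PipelineConfig):
    """(orthogroups, gene trees) from the synthetic generator or from disk."""
    if config.input_loci_dir is not None:
        ogs, trees = [], []
        for fa in sorted(glob.glob(os.path.join(config.input_loci_dir, "*.fa*"))):
            og = read_orthogroup(fa)
            tree_path = None
            if config.input_trees_dir is not None:
                for ext in (".nwk", ".tre", ".treefile"):
                    cand = os.path.join(config.input_trees_dir, og.locus_id + ext)
                    if os.path.exists(cand):
                        tree_path = cand
                        break
            if tree_path is None:
                raise FileNotFoundError(f"no gene tree found for locus {og.locus_id}")
            ogs.append(og)
            trees.append(prune_mod.read_gene_tree(tree_path))
        return ogs, trees
    dataset = generate_dataset(config.synthetic)
    return dataset.orthogroups, dataset.gene_trees


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    orthogroups, trees = load_inputs(config)
    n_input = len(orthogroups)
    log.info("loaded %d loci", n_input)

    deduped = [prune_mod.dedupe_records(og) for og in orthogroups]

    pruned, pruned_trees, reports = [], [], []
    for og, tree in zip(deduped, trees):
        # deduplication may drop identical in-paralog copies still present
        # as gene-tree leaves; reduce the tree to the surviving sequences
        ids = {r.sequence_id for r in og.records}
        if any(lf.taxon.label not in ids for lf in tree.leaf_node_iter()):
            reduced = prune_mod.prune_tree_to_leaves(tree, ids)
            if reduced is None:
                log.info("locus %s too small after deduplication", og.locus_id)
                continue
            tree = reduced
        p, rep = prune_mod.prune_orthogroup(og, tree, config.support_threshold)
        reports.append(rep)
        if not rep.usable:
            log.info("locus %s unusable after pruning", og.locus_id)
            continue
        kept = {r.sequence_id for r in p.records}
        ptree = prune_mod.prune_tree_to_leaves(tree, kept)
        if ptree is None:
            continue
        pruned.append(p)
        pruned_trees.append(ptree)
    prune_mod.prune_report_tsv(reports, os.path.join(config.out_dir, "prune_report.tsv"))

    all_taxa = sorted({t for og in pruned for t in og.taxa()})
    n_total = config.n_total_taxa or len(all_taxa)
    tree_by_locus = {og.locus_id: t for og, t in zip(pruned, pruned_trees)}

    manifest = {
        "seed": config.seed,
        "n_input_loci": n_input,
        "n_pruned_loci": len(pruned),
        "n_total_taxa": n_total,
        "matrices": {},
    }

    for fraction in config.occupancy_fractions:
        label = f"occ{int(round(fraction * 100))}"
        occ, min_taxa = prune_mod.occupancy_filter(pruned, fraction, n_total)
        stage = {"fraction": fraction, "min_taxa": min_taxa, "n_after_occupancy": len(occ)}
        loci = occ
        if config.apply_locus_filter and len(loci) >= 4:
            dlist = diag.compute_diagnostics(
                loci, [tree_by_locus[o.locus_id] for o in loci])
            retained_ids, dlist = diag.filter_loci(
                dlist, alpha=config.chisq_alpha,
                rule=diag.IQRRule(config.iqr_multiplier))
            diag.diagnostics_tsv(
                dlist, os.path.join(config.out_dir, f"{label}_diagnostics.tsv"))
            loci = [o for o in loci if o.locus_id in set(retained_ids)]
        stage["n_after_diagnostics"] = len(loci)
        if config.apply_trim:
            loci = [sm.remove_gappy_sites(o, config.gap_fraction) for o in loci]
            loci = [o for o in loci if o.length > 0]
        stage["n_after_trim"] = len(loci)
        if not loci:
            manifest["matrices"][label] = stage
            continue
        matrix = sm.concatenate(loci)
        summary = sm.summarize(matrix)
        stage["summary"] = summary.to_row()
        sm.write_fasta(matrix, os.path.join(config.out_dir, f"{label}.fasta"))
        sm.write_phylip(matrix, os.path.join(config.out_dir, f"{label}.phy"))
        sm.write_partitions(matrix, os.path.join(config.out_dir, f"{label}.partitions"))
        manifest["matrices"][label] = stage

    payload = json.dumps(manifest, sort_keys=True, indent=2)
    manifest["digest"] = hashlib.sha256(payload.encode()).hexdigest()
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return manifest
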