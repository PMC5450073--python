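import math

import numpy as np
import pytest

from conftest import make_orthogroup
from supermatrixqc.align import read_orthogroup
from supermatrixqc.diagnostics import lb_scores, rcfv
from supermatrixqc.models import get_model
from supermatrixqc.synthetic import (
    SyntheticConfig,
    apply_occupancy_mask,
    generate_dataset,
    simulate_biased_alignment,
    simulate_gene_tree,
    simulate_species_tree,
    taxon_names,
)


def newick(tree):
    return tree.as_string(schema="newick", suppress_rooting=True)


def unrooted_splits(tree):
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits = set()
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is not None and 1 < len(below[node]) < len(leaves) - 1:
            splits.add(min(below[node], leaves - below[node], key=sorted))
    return splits


class TestSpeciesTree:
    def test_rejects_degenerate_sizes(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, 1.0, 0)
        with pytest.raises(ValueError):
            simulate_species_tree(5, 0.0, 0)

    def test_two_taxa_ultrametric(self):
        tree = simulate_species_tree(2, 1.0, 3)
        depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
        assert depths[0] == pytest.approx(depths[1], abs=1e-12)

    def test_unit_height_and_ultrametricity(self):
        tree = simulate_species_tree(12, 1.0, 9)
        depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
        assert all(d == pytest.approx(1.0, abs=1e-9) for d in depths)
        assert len(tree.leaf_nodes()) == 12

    def test_seeded_determinism(self):
        t1 = simulate_species_tree(8, 1.0, 42)
        t2 = simulate_species_tree(8, 1.0, 42)
        assert newick(t1) == newick(t2)
        t3 = simulate_species_tree(8, 1.0, 43)
        assert newick(t1) != newick(t3)

    def test_cherry_count_matches_yule_expectation(self):
        # E[#cherries] = n/3 for a Yule tree
        n, reps = 50, 500
        counts = []
        for seed in range(reps):
            tree = simulate_species_tree(n, 1.0, 10_000 + seed)
            cherries = 0
            for node in tree.postorder_internal_node_iter():
                kids = node.child_nodes()
                if len(kids) == 2 and all(k.is_leaf() for k in kids):
                    cherries += 1
            counts.append(cherries)
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(reps)
        assert abs(mean - n / 3) < 3 * se


class TestGeneTree:
    def test_no_events_reproduces_species_tree(self):
        sp = simulate_species_tree(10, 1.0, 5)
        tree, is_primary, n_dup = simulate_gene_tree(sp, 0.0, 0.0, 1)
        assert n_dup == 0
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        assert labels == sorted(f"{t}|c1" for t in taxon_names(10))
        assert all(is_primary.values())
        strip = {f"{t}|c1": t for t in taxon_names(10)}
        got = {frozenset(strip[x] for x in s) for s in unrooted_splits(tree)}
        assert got == unrooted_splits(sp)

    def test_loss_only_removes_taxa(self):
        sp = simulate_species_tree(10, 1.0, 5)
        seen_absent = False
        for seed in range(30):
            sim = simulate_gene_tree(sp, 0.0, 1.5, seed)
            if sim is None:
                seen_absent = True
                continue
            tree, _, n_dup = sim
            assert n_dup == 0
            taxa = {lf.taxon.label.split("|")[0] for lf in tree.leaf_node_iter()}
            if len(taxa) < 10:
                seen_absent = True
        assert seen_absent

    def test_copy_number_matches_birth_death_expectation(self):
        # E[copies per taxon] = exp((dup - loss) * height) = 1 at dup == loss
        sp = simulate_species_tree(6, 1.0, 2)
        reps = 1000
        counts = []
        for seed in range(reps):
            sim = simulate_gene_tree(sp, 0.3, 0.3, 50_000 + seed)
            per_taxon = dict.fromkeys(taxon_names(6), 0)
            if sim is not None:
                for lf in sim[0].leaf_node_iter():
                    per_taxon[lf.taxon.label.split("|")[0]] += 1
            counts.append(np.mean(list(per_taxon.values())))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(reps)
        assert abs(mean - 1.0) < 3 * se


class TestBiasedAlignment:
    def test_zero_branch_lengths_give_identical_rows(self):
        tree = "((A:0,B:0):0,C:0,D:0);"
        og = simulate_biased_alignment(tree, get_model("LG"), 40, seed=4)
        assert len({r.residues for r in og.records}) == 1

    def test_invalid_arguments(self):
        tree = "(A:1,B:1,C:1);"
        with pytest.raises(ValueError):
            simulate_biased_alignment(tree, get_model("LG"), 0, seed=1)
        with pytest.raises(ValueError):
            simulate_biased_alignment(tree, get_model("LG"), 10,
                                      bias_intensity=1.5, biased_taxa=["A"], seed=1)

    def test_saturation_identity_approaches_squared_frequencies(self):
        # long star branches under Poisson: pairwise identity -> sum pi^2 = 0.05
        tree = "(" + ",".join(f"T{i}:15.0" for i in range(8)) + ");"
        og = simulate_biased_alignment(tree, get_model("Poisson"), 3000, seed=8)
        codes = og.codes()
        idents = []
        for i in range(8):
            for j in range(i + 1, 8):
                idents.append(np.mean(codes[i] == codes[j]))
        n_pairs_sites = len(idents) * 3000
        se = math.sqrt(0.05 * 0.95 / n_pairs_sites)
        assert abs(np.mean(idents) - 0.05) < 6 * se  # pairs share draws

    def test_bias_raises_rcfv_in_most_paired_replicates(self):
        tree = "(" + ",".join(f"T{i}:1.0" for i in range(8)) + ");"
        biased_taxa = [f"T{i}" for i in range(4)]
        wins = 0
        for seed in range(20):
            base = simulate_biased_alignment(tree, get_model("LG"), 300, seed=seed)
            biased = simulate_biased_alignment(
                tree, get_model("LG"), 300, bias_intensity=0.7,
                biased_taxa=biased_taxa, seed=seed)
            if rcfv(biased) > rcfv(base):
                wins += 1
        assert wins >= 17


class TestOccupancyMask:
    def _loci(self, n_loci=40, n_taxa=10):
        return [
            make_orthogroup(f"og{i}", [(f"{t}|c1", "MKLV") for t in taxon_names(n_taxa)])
            for i in range(n_loci)
        ]

    def test_extreme_alpha_retains_everything(self):
        loci = self._loci()
        masked, mask = apply_occupancy_mask(loci, 1e6, 1.0, seed=1)
        assert len(masked) == len(loci)
        assert all(m.n_records == 10 for m in masked)

    def test_seeded_determinism(self):
        loci = self._loci()
        _, m1 = apply_occupancy_mask(loci, 2.0, 1.0, seed=7)
        _, m2 = apply_occupancy_mask(loci, 2.0, 1.0, seed=7)
        assert m1 == m2

    def test_uniform_beta_mean_occupancy_is_half(self):
        loci = self._loci(n_loci=500, n_taxa=40)
        masked, mask = apply_occupancy_mask(loci, 1.0, 1.0, seed=11)
        total = sum(len(v) for v in mask.values())
        n = 500 * 40
        # mean retention alpha/(alpha+beta) = 0.5; Beta-Bernoulli variance
        p_hat = total / n
        se = math.sqrt(0.25 / n) * 2  # conservative (overdispersed) bound
        assert abs(p_hat - 0.5) < 3 * se


class TestGenerateDataset:
    CFG = dict(n_taxa=8, n_loci=25, locus_length_range=(60, 100),
               duplication_rate=0.3, loss_rate=0.3,
               long_branch_taxa={"t01": 5.0}, biased_taxa={"t03": 0.5},
               model="Poisson")

    def test_deterministic_digest(self, tmp_path):
        from supermatrixqc.synthetic import write_dataset

        cfg = SyntheticConfig(seed=7, **self.CFG)
        d1 = generate_dataset(cfg, out_dir=tmp_path / "a")
        d2 = generate_dataset(cfg, out_dir=tmp_path / "b")
        import json

        m1 = json.load(open(tmp_path / "a" / "manifest.json"))
        m2 = json.load(open(tmp_path / "b" / "manifest.json"))
        assert m1["digest"] == m2["digest"]
        assert m1["n_loci"] == len(d1.orthogroups)

    def test_roundtrip_through_readers_and_traceability(self, tmp_path):
        cfg = SyntheticConfig(seed=3, **self.CFG)
        ds = generate_dataset(cfg, out_dir=tmp_path)
        for og in ds.orthogroups[:5]:
            back = read_orthogroup(tmp_path / "loci" / f"{og.locus_id}.fasta")
            assert [r.sequence_id for r in back.records] == \
                [r.sequence_id for r in og.records]
            assert [r.residues for r in back.records] == \
                [r.residues for r in og.records]
        truth_by_locus = {lt.locus_id: lt for lt in ds.truth.loci}
        for og in ds.orthogroups:
            lt = truth_by_locus[og.locus_id]
            for r in og.records:
                assert r.sequence_id in lt.is_primary  # maps to a gene-tree leaf

    def test_long_branch_taxon_has_largest_mean_lb_score(self):
        cfg = SyntheticConfig(seed=5, n_taxa=8, n_loci=40,
                              locus_length_range=(60, 80),
                              duplication_rate=0.0, loss_rate=0.0,
                              long_branch_taxa={"t02": 6.0}, biased_taxa={},
                              occupancy_alpha=1e6, nni_noise_prob=0.0,
                              model="Poisson")
        ds = generate_dataset(cfg)
        sums = {}
        counts = {}
        for tree in ds.gene_trees:
            for label, score in lb_scores(tree).items():
                taxon = label.split("|")[0]
                sums[taxon] = sums.get(taxon, 0.0) + score
                counts[taxon] = counts.get(taxon, 0) + 1
        means = {t: sums[t] / counts[t] for t in sums}
        assert max(means, key=means.get) == "t02"

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_taxa=1)
        with pytest.raises(ValueError):
            SyntheticConfig(locus_length_range=(10, 5))
        with pytest.raises(ValueError):
            SyntheticConfig(long_branch_taxa={"nope": 5.0})
        with pytest.raises(ValueError):
            SyntheticConfig(biased_taxa={"t01": 1.5})
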