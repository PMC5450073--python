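import numpy as np
import pytest

from _oracles import brute_force_max_subtree
from conftest import make_orthogroup, parse_tree, random_bl_tree
from supermatrixqc.align import taxon_of
from supermatrixqc.prune import (
    collapse_low_support,
    dedupe_records,
    max_inclusive_subtree,
    occupancy_filter,
    occupancy_min_taxa,
    prune_orthogroup,
    read_gene_tree,
)


class TestDedupe:
    def test_identical_within_taxon_collapsed_first_id_wins(self):
        og = make_orthogroup("x", [("A|c1", "MKL"), ("A|c2", "MKL"), ("A|c3", "MKV")])
        out = dedupe_records(og)
        assert [r.sequence_id for r in out.records] == ["A|c1", "A|c3"]

    def test_identical_across_taxa_kept(self):
        og = make_orthogroup("x", [("A|c1", "MKL"), ("B|c1", "MKL")])
        assert dedupe_records(og).n_records == 2

    def test_matches_pairwise_census_and_is_fixed_point(self, rng):
        residues = ["MK", "ML", "MV"]
        rows = []
        for i in range(10):
            taxon = f"t{rng.integers(3)}"
            rows.append((f"{taxon}|c{i}", residues[rng.integers(3)]))
        og = make_orthogroup("x", rows)
        out = dedupe_records(og)
        expected = len({(t.split('|')[0], r) for t, r in rows})
        assert out.n_records == expected
        again = dedupe_records(out)
        assert [r.sequence_id for r in again.records] == \
            [r.sequence_id for r in out.records]


class TestCollapseLowSupport:
    def test_full_support_unchanged(self):
        tree = read_gene_tree("((A:1,B:1)1.0:1,(C:1,D:1)1.0:1);", from_string=True)
        out = collapse_low_support(tree, 0.7)
        assert len(out.internal_edges(exclude_seed_edge=True)) == \
            len(tree.internal_edges(exclude_seed_edge=True))

    @pytest.mark.parametrize("support,n_internal", [("0.69", 0), ("0.70", 1)])
    def test_strict_threshold_boundary(self, support, n_internal):
        tree = read_gene_tree(f"((A:1,B:1){support}:1,C:1,D:1);", from_string=True)
        out = collapse_low_support(tree, 0.7)
        internal = [e for e in out.preorder_internal_edge_iter(exclude_seed_edge=True)]
        assert len(internal) == n_internal
        assert {lf.taxon.label for lf in out.leaf_node_iter()} == {"A", "B", "C", "D"}

    def test_malformed_support_rejected(self):
        tree = read_gene_tree("((A:1,B:1)1.5:1,C:1,D:1);", from_string=True)
        with pytest.raises(ValueError):
            collapse_low_support(tree, 0.7)

    def test_edge_count_matches_support_census(self, rng):
        for rep in range(20):
            tree = random_bl_tree(rng, 10)
            kept = 0
            for node in tree.preorder_node_iter():
                if node.is_leaf() or node.parent_node is None:
                    continue
                sup = rng.random()
                node.label = f"{sup:.4f}"
                if sup >= 0.7:
                    kept += 1
            out = collapse_low_support(tree, 0.7)
            n_internal = sum(
                1 for nd in out.preorder_node_iter()
                if not nd.is_leaf() and nd.parent_node is not None)
            assert n_internal == kept

    def test_idempotent(self, rng):
        tree = random_bl_tree(rng, 8)
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node.parent_node is not None:
                node.label = f"{rng.random():.4f}"
        once = collapse_low_support(tree, 0.7)
        twice = collapse_low_support(once, 0.7)
        assert once.as_string(schema="newick") == twice.as_string(schema="newick")


class TestMaxInclusiveSubtree:
    def test_single_copy_tree_returned_whole(self):
        tree = read_gene_tree("((A|c1:1,B|c1:1):1,(C|c1:1,D|c1:1):1);",
                              from_string=True)
        res = max_inclusive_subtree(tree)
        assert res.leaf_labels == ["A|c1", "B|c1", "C|c1", "D|c1"]
        assert res.in_paralogs == {}
        assert res.usable

    def test_sister_in_paralogs_retained(self):
        tree = read_gene_tree("((A|c1:1,A|c2:1):1,B|c1:1,C|c1:1);", from_string=True)
        res = max_inclusive_subtree(tree)
        assert res.leaf_labels == ["A|c1", "A|c2", "B|c1", "C|c1"]
        assert res.in_paralogs == {"A": ["A|c1", "A|c2"]}

    def test_out_paralog_discarded(self):
        # A's second copy is far from the first: only one side can keep A
        tree = read_gene_tree("((A|c1:1,B|c1:1):1,(A|c2:1,C|c1:1):1,D|c1:1);",
                              from_string=True)
        res = max_inclusive_subtree(tree)
        labels = set(res.leaf_labels)
        assert len(labels) == 4
        assert len([l for l in labels if l.startswith("A|")]) == 1

    def test_single_taxon_flagged_unusable(self):
        tree = read_gene_tree("((A|c1:1,A|c2:1):1,A|c3:1,A|c4:1);", from_string=True)
        res = max_inclusive_subtree(tree)
        assert not res.usable

    def test_matches_exhaustive_enumeration(self, rng):
        mismatches = 0
        for rep in range(200):
            n = int(rng.integers(4, 9))
            tree = random_bl_tree(rng, n, multifurcate_prob=0.3)
            # relabel leaves: random taxon assignment, <= 3 copies per taxon
            counts = {}
            for leaf in tree.leaf_node_iter():
                while True:
                    taxon = f"s{rng.integers(1, 5)}"
                    if counts.get(taxon, 0) < 3:
                        break
                counts[taxon] = counts.get(taxon, 0) + 1
                leaf.taxon.label = f"{taxon}|c{counts[taxon]}"
            res = max_inclusive_subtree(tree)
            expected = brute_force_max_subtree(tree, lambda s: taxon_of(s))
            if set(res.leaf_labels) != expected:
                mismatches += 1
        assert mismatches == 0


class TestPruneOrthogroup:
    def test_one_per_taxon_input_unchanged(self):
        og = make_orthogroup("x", [("A|c1", "MKL"), ("B|c1", "MKV"), ("C|c1", "MRL")])
        tree = read_gene_tree("((A|c1:1,B|c1:1):1,C|c1:1);", from_string=True)
        out, report = prune_orthogroup(og, tree)
        assert [r.sequence_id for r in out.records] == ["A|c1", "B|c1", "C|c1"]
        assert report.usable

    def test_longest_in_paralog_kept(self):
        long_seq = "M" * 120 + "-" * 30
        short_seq = "M" * 80 + "-" * 70
        og = make_orthogroup("x", [
            ("A|c1", short_seq), ("A|c2", long_seq),
            ("B|c1", "K" * 150), ("C|c1", "R" * 150)])
        tree = read_gene_tree("((A|c1:1,A|c2:1):1,B|c1:1,C|c1:1);", from_string=True)
        out, report = prune_orthogroup(og, tree)
        ids = {r.sequence_id for r in out.records}
        assert ids == {"A|c2", "B|c1", "C|c1"}
        assert report.n_in_paralogs_collapsed == 1

    def test_idempotent_on_own_output(self):
        og = make_orthogroup("x", [
            ("A|c1", "MK--"), ("A|c2", "MKLV"), ("B|c1", "MKLV"), ("C|c1", "MRLV")])
        tree = read_gene_tree("((A|c1:1,A|c2:1):1,B|c1:1,C|c1:1);", from_string=True)
        out1, _ = prune_orthogroup(og, tree)
        subtree = read_gene_tree("(A|c2:1,B|c1:1,C|c1:1);", from_string=True)
        out2, _ = prune_orthogroup(out1, subtree)
        assert [r.sequence_id for r in out2.records] == \
            [r.sequence_id for r in out1.records]

    def test_missing_record_for_leaf_raises(self):
        og = make_orthogroup("x", [("A|c1", "MK")])
        tree = read_gene_tree("(A|c1:1,B|c1:1,C|c1:1);", from_string=True)
        with pytest.raises(ValueError):
            prune_orthogroup(og, tree)

    def test_all_gap_columns_dropped(self):
        og = make_orthogroup("x", [
            ("A|c1", "M-K-"), ("A|c2", "M-KV"), ("B|c1", "M-KV"), ("C|c1", "M-RV")])
        tree = read_gene_tree("((A|c1:1,A|c2:1):1,B|c1:1,C|c1:1);", from_string=True)
        out, _ = prune_orthogroup(og, tree)
        assert out.length == 3  # column 2 was all-gap


class TestOccupancy:
    @pytest.mark.parametrize("fraction,n,expected", [
        (0.25, 40, 10), (0.5, 40, 20), (0.75, 40, 30), (1.0, 40, 40),
        (0.25, 37, 10), (0.5, 37, 19), (0.75, 37, 28),
        (0.75, 39, 30),
    ])
    def test_min_taxa_reproduces_published_counts(self, fraction, n, expected):
        assert occupancy_min_taxa(fraction, n) == expected

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            occupancy_min_taxa(0.0, 40)
        with pytest.raises(ValueError):
            occupancy_min_taxa(1.2, 40)

    def _random_loci(self, rng, n_loci=30, n_taxa=12):
        loci = []
        for i in range(n_loci):
            k = int(rng.integers(2, n_taxa + 1))
            taxa = rng.choice(n_taxa, size=k, replace=False)
            loci.append(make_orthogroup(
                f"og{i}", [(f"t{j}|c1", "MK") for j in sorted(taxa)]))
        return loci

    def test_full_occupancy_keeps_only_complete_loci(self, rng):
        loci = self._random_loci(rng)
        kept, min_taxa = occupancy_filter(loci, 1.0, 12)
        assert min_taxa == 12
        assert all(len(og.taxa()) == 12 for og in kept)

    def test_monotone_in_fraction(self, rng):
        loci = self._random_loci(rng)
        counts = [len(occupancy_filter(loci, f, 12)[0])
                  for f in (0.25, 0.5, 0.75, 1.0)]
        assert counts == sorted(counts, reverse=True)
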