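import math

import numpy as np
import pytest

from conftest import make_orthogroup, parse_tree
from supermatrixqc.likelihood import (
    LTree,
    TreeLikelihood,
    estimate_distances,
    log_likelihood,
    ml_search,
    nj_tree,
    optimize_branch_lengths,
    select_model,
    simulate_along_tree,
)
from supermatrixqc.models import default_candidates, get_model

POISSON = get_model("Poisson")


def poisson_pair_lnl(t, n_match, n_mismatch):
    """Closed-form 20-state Jukes-Cantor-type two-sequence log-likelihood."""
    p_same = 1 / 20 + (19 / 20) * math.exp(-20 * t / 19)
    p_diff = (1 - p_same) / 19
    return n_match * math.log(p_same / 20) + n_mismatch * math.log(p_diff / 20)


class TestLogLikelihood:
    def test_identical_single_site_zero_branches(self):
        og = make_orthogroup("x", [("A", "C"), ("B", "C")])
        assert log_likelihood("(A:0,B:0);", og, POISSON) == pytest.approx(
            math.log(1 / 20), abs=1e-12)

    @pytest.mark.parametrize("t", [0.01, 0.1, 0.5, 1.0, 2.0, 5.0])
    def test_two_taxon_poisson_closed_form(self, t):
        og = make_orthogroup("x", [("A", "ACDEF"), ("B", "ACDEW")])
        lnl = log_likelihood(f"(A:{t / 2},B:{t / 2});", og, POISSON)
        assert lnl == pytest.approx(poisson_pair_lnl(t, 4, 1), abs=1e-8)

    def test_pattern_compression_is_exact(self, rng):
        tree = "((A:0.2,B:0.3):0.1,(C:0.15,D:0.4):0.1);"
        aln = simulate_along_tree(tree, get_model("WAG", alpha=0.8), 400, seed=11)
        m = get_model("LG", alpha=0.5)
        assert log_likelihood(tree, aln, m, compress=True) == pytest.approx(
            log_likelihood(tree, aln, m, compress=False), abs=1e-10)

    def test_missing_data_is_ambiguous(self):
        og = make_orthogroup("x", [("A", "C-"), ("B", "CX")])
        lnl = log_likelihood("(A:0.1,B:0.1);", og, POISSON)
        # a fully ambiguous column contributes lnL 0
        one = make_orthogroup("x", [("A", "C"), ("B", "C")])
        assert lnl == pytest.approx(log_likelihood("(A:0.1,B:0.1);", one, POISSON))

    def test_leaf_taxon_mismatch_raises(self):
        og = make_orthogroup("x", [("A", "C"), ("B", "C")])
        with pytest.raises(ValueError):
            log_likelihood("(A:0.1,Z:0.1);", og, POISSON)


class TestDistances:
    def test_identical_sequences_zero(self):
        og = make_orthogroup("x", [("A", "ACDEF"), ("B", "ACDEF")])
        _, d = estimate_distances(og, POISSON)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-8)
        assert d[0, 0] == 0.0

    def test_matches_closed_form_inversion(self):
        # p mismatches out of n -> d = -(19/20) ln(1 - 20p/19)
        seq_a = "A" * 80 + "C" * 20
        seq_b = "A" * 80 + "D" * 20
        og = make_orthogroup("x", [("A", seq_a), ("B", seq_b)])
        _, d = estimate_distances(og, POISSON)
        p = 0.2
        expected = -(19 / 20) * math.log(1 - 20 * p / 19)
        assert d[0, 1] == pytest.approx(expected, abs=1e-6)

    def test_disjoint_pair_capped_with_warning(self):
        og = make_orthogroup("x", [("A", "AC--"), ("B", "--DE")])
        with pytest.warns(RuntimeWarning):
            _, d = estimate_distances(og, POISSON, max_distance=7.5)
        assert d[0, 1] == 7.5


class TestNeighborJoining:
    TRUE = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.07,E:0.25);"

    def _additive_matrix(self):
        from _oracles import path_distance_matrix

        return path_distance_matrix(parse_tree(self.TRUE))

    def test_recovers_additive_tree(self):
        labels, mat = self._additive_matrix()
        tree = LTree.from_dendropy(nj_tree(labels, mat))
        assert tree.is_monophyletic({"A", "B"})
        assert tree.is_monophyletic({"C", "D"})
        from _oracles import path_distance_matrix

        labels2, mat2 = path_distance_matrix(tree.to_dendropy())
        assert labels2 == labels
        assert np.allclose(mat2, mat, atol=1e-6)

    def test_order_invariance(self):
        labels, mat = self._additive_matrix()
        perm = [4, 2, 0, 3, 1]
        t1 = LTree.from_dendropy(nj_tree(labels, mat))
        t2 = LTree.from_dendropy(
            nj_tree([labels[i] for i in perm], mat[np.ix_(perm, perm)]))
        leaves = frozenset(labels)
        s1 = {min(s, leaves - s, key=sorted) for s in t1.splits() if 1 < len(s) < 4}
        s2 = {min(s, leaves - s, key=sorted) for s in t2.splits() if 1 < len(s) < 4}
        assert s1 == s2


class TestBranchOptimization:
    def test_lnl_never_decreases_and_recovers_lengths(self):
        true = "((A:0.12,B:0.31):0.08,(C:0.22,D:0.05):0.11,E:0.27);"
        aln = simulate_along_tree(true, POISSON, 10000, seed=7)
        perturbed = "((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5,E:0.5);"
        tl = TreeLikelihood(perturbed, aln, POISSON)
        start = tl.lnl()
        lnls = [start]
        for _ in range(6):
            lnls.append(tl._optimize_sweep(1e-6))
        assert all(b >= a - 1e-6 for a, b in zip(lnls, lnls[1:]))
        opt, lnl = optimize_branch_lengths(true, aln, POISSON)
        fitted = {}
        for node in LTree.from_dendropy(opt).postorder():
            if node.is_leaf:
                fitted[node.label] = node.length
        truth = {"A": 0.12, "B": 0.31, "C": 0.22, "E": 0.27}
        for taxon, t_true in truth.items():
            assert fitted[taxon] == pytest.approx(t_true, rel=0.10)

    def test_restart_at_optimum_is_stable(self):
        true = "((A:0.1,B:0.2):0.1,(C:0.2,D:0.1):0.1);"
        aln = simulate_along_tree(true, POISSON, 1000, seed=3)
        t1, lnl1 = optimize_branch_lengths(true, aln, POISSON)
        _, lnl2 = optimize_branch_lengths(t1, aln, POISSON)
        assert lnl2 == pytest.approx(lnl1, abs=1e-3)


class TestMLSearch:
    TRUE = "((A:0.1,B:0.1):0.15,(C:0.1,D:0.1):0.15,(E:0.1,F:0.1):0.15);"

    def test_topology_recovery_with_strong_signal(self):
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            aln = simulate_along_tree(self.TRUE, POISSON, 5000, seed=1000 + rep)
            tree, _ = ml_search(aln, POISSON)
            lt = LTree.from_dendropy(tree)
            if all(lt.is_monophyletic(p) for p in ({"A", "B"}, {"C", "D"}, {"E", "F"})):
                hits += 1
        assert hits >= 9

    def test_constrained_search_respects_constraint_and_is_nested(self):
        aln = simulate_along_tree(self.TRUE, POISSON, 800, seed=5)
        tree_u, lnl_u = ml_search(aln, POISSON)
        constraint = {"A", "F"}  # violated by the generating tree
        tree_c, lnl_c = ml_search(aln, POISSON, constraint=constraint)
        assert LTree.from_dendropy(tree_c).is_monophyletic(constraint)
        assert lnl_u >= lnl_c - 1e-6

    def test_constraint_taxa_must_exist(self):
        aln = simulate_along_tree(self.TRUE, POISSON, 100, seed=5)
        with pytest.raises(ValueError):
            ml_search(aln, POISSON, constraint={"A", "ZZ"})


class TestModelSelection:
    def test_single_candidate_and_tie_break(self):
        const = make_orthogroup("x", [(t, "AAAA") for t in "ABCD"])
        cands = default_candidates()
        assert select_model(const, [cands[2]]) == cands[2].name
        # exactly tied candidates (same likelihood surface): first one wins
        from supermatrixqc.models import SubstitutionModel

        twin = SubstitutionModel("PoissonTwin", POISSON.exchangeabilities,
                                 POISSON.frequencies)
        assert select_model(const, [POISSON, twin]) == "Poisson"
        assert select_model(const, [twin, POISSON]) == "PoissonTwin"
        with pytest.raises(ValueError):
            select_model(const, [])

    def test_recovers_generating_model_once(self):
        tree = "((A:0.15,B:0.2):0.1,(C:0.25,D:0.1):0.1,(E:0.2,F:0.15):0.1);"
        aln = simulate_along_tree(tree, get_model("WAG"), 2000, seed=77)
        assert select_model(aln, default_candidates()) == "WAG"


class TestSimulation:
    def test_zero_branch_lengths_clone_root(self):
        tree = "((A:0,B:0):0,(C:0,D:0):0);"
        aln = simulate_along_tree(tree, get_model("LG"), 50, seed=9)
        rows = {r.residues for r in aln.records}
        assert len(rows) == 1

    def test_seeded_determinism(self):
        tree = "((A:0.3,B:0.2):0.1,(C:0.1,D:0.4):0.1);"
        a1 = simulate_along_tree(tree, get_model("JTT"), 200, seed=42)
        a2 = simulate_along_tree(tree, get_model("JTT"), 200, seed=42)
        assert [r.residues for r in a1.records] == [r.residues for r in a2.records]

    def test_saturation_reaches_equilibrium(self):
        tree = "(" + ",".join(f"T{i}:20.0" for i in range(6)) + ");"
        aln = simulate_along_tree(tree, POISSON, 4000, seed=13)
        codes = aln.codes()
        freqs = np.bincount(codes.ravel(), minlength=20)[:20] / codes.size
        assert np.abs(freqs - 0.05).max() < 0.01
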