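"""NJ, NNI search, bootstrap supports, collapsing, and position ranges."""

import numpy as np
import pytest

from stratadate.mlct import (
    _splits,
    bootstrap_supports,
    collapse_low_support,
    jc_distance_matrix,
    ml_search,
    nj_tree,
    read_support_tree,
    w_position_range,
)
from stratadate.seqmodels import SubstitutionModel
from stratadate.simulate import default_model, gametolog_tree, simulate_alignment
from stratadate.trees import SpeciesTree, TreeError, parse_newick, write_newick


def splits_of(tree):
    taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    return _splits(tree, taxa)


class TestNeighborJoining:
    def test_additive_matrix_recovers_tree(self):
        # distances on ((a,b),(c,d)) with internal branch 0.3
        true = parse_newick("((a:0.1,b:0.2):0.15,(c:0.25,d:0.05):0.15);")
        labels = ["a", "b", "c", "d"]
        # path distances
        d = np.array([
            [0.0, 0.3, 0.65, 0.45],
            [0.3, 0.0, 0.75, 0.55],
            [0.65, 0.75, 0.0, 0.3],
            [0.45, 0.55, 0.3, 0.0],
        ])
        t = nj_tree(d, labels)
        assert splits_of(t) == splits_of(true)  # RF distance 0

    def test_three_taxa_unique_topology(self):
        t = nj_tree(np.array([[0, 1, 2], [1, 0, 2.2], [2, 2.2, 0]]),
                    ["a", "b", "c"])
        assert len(t.leaf_nodes()) == 3
        assert splits_of(t) == set()

    def test_ultrametric_matrix_nonnegative_lengths(self):
        d = np.array([
            [0.0, 0.2, 0.6, 1.0],
            [0.2, 0.0, 0.6, 1.0],
            [0.6, 0.6, 0.0, 1.0],
            [1.0, 1.0, 1.0, 0.0],
        ])
        t = nj_tree(d, list("abcd"))
        for e in t.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0

    def test_invalid_matrices(self):
        with pytest.raises(TreeError, match="symmetric"):
            nj_tree(np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]]), list("abc"))
        with pytest.raises(TreeError, match="diagonal"):
            nj_tree(np.array([[0.1, 1], [1, 0]]), list("ab"))
        with pytest.raises(TreeError, match="3 taxa"):
            nj_tree(np.zeros((2, 2)), list("ab"))


class TestMLSearch:
    truth = "(((a:0.05,b:0.05):0.05,(c:0.05,d:0.05):0.05):0.05,(e:0.05,f:0.1):0.05);"

    def _sim(self, seed, L=2000):
        tree = parse_newick(self.truth)
        return simulate_alignment(tree, SubstitutionModel(family="JC69"), L,
                                  seed=seed)

    def test_recovers_true_topology(self):
        model = SubstitutionModel(family="JC69")
        true_splits = splits_of(parse_newick(self.truth))
        hits = 0
        for seed in range(5):
            aln = self._sim(seed)
            d, labels = jc_distance_matrix(aln)
            start = nj_tree(d, labels)
            tree, lnl = ml_search(aln, model, start)
            hits += splits_of(tree) == true_splits
        assert hits >= 4

    def test_optimal_start_left_unchanged(self):
        aln = self._sim(17)
        model = SubstitutionModel(family="JC69")
        start = parse_newick(self.truth)
        tree, _ = ml_search(aln, model, start)
        assert splits_of(tree) == splits_of(start)

    def test_lnl_not_below_start(self):
        aln = self._sim(23)
        model = SubstitutionModel(family="JC69")
        d, labels = jc_distance_matrix(aln)
        start = nj_tree(d, labels)
        from stratadate.mlct import _optimized_lnl
        start_lnl = _optimized_lnl(parse_newick(write_newick(start)), aln, model)
        _, lnl = ml_search(aln, model, start)
        assert lnl >= start_lnl - 1e-6


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self):
        tree = parse_newick(TestMLSearch.truth)
        aln = simulate_alignment(tree, SubstitutionModel(family="JC69"), 500,
                                 seed=3)
        st = bootstrap_supports(aln, B=1, seed=1)
        sups = [n.support for n in st.preorder_node_iter()
                if getattr(n, "support", None) is not None]
        assert sups and set(sups) <= {0.0, 1.0}

    def test_clean_data_high_supports(self):
        tree = parse_newick(TestMLSearch.truth)
        aln = simulate_alignment(tree, SubstitutionModel(family="JC69"), 5000,
                                 seed=5)
        st = bootstrap_supports(aln, B=50, seed=2)
        assert splits_of(st) == splits_of(tree)
        for n in st.preorder_node_iter():
            if getattr(n, "support", None) is not None:
                assert n.support >= 0.95

    def test_taxon_order_invariance(self):
        tree = parse_newick(TestMLSearch.truth)
        aln = simulate_alignment(tree, SubstitutionModel(family="JC69"), 800,
                                 seed=7)
        perm = aln.subset(list(reversed(aln.labels)))
        s1 = bootstrap_supports(aln, B=20, seed=9)
        s2 = bootstrap_supports(perm, B=20, seed=9)
        sup1 = {frozenset(l.taxon.label for l in n.leaf_iter()): n.support
                for n in s1.preorder_node_iter()
                if getattr(n, "support", None) is not None}
        sup2 = {frozenset(l.taxon.label for l in n.leaf_iter()): n.support
                for n in s2.preorder_node_iter()
                if getattr(n, "support", None) is not None}
        shared = set(sup1) & set(sup2)
        assert shared
        for k in shared:
            assert sup1[k] == pytest.approx(sup2[k], abs=0.25)

    def test_invalid_b(self):
        tree = parse_newick(TestMLSearch.truth)
        aln = simulate_alignment(tree, SubstitutionModel(family="JC69"), 100,
                                 seed=1)
        with pytest.raises(ValueError):
            bootstrap_supports(aln, B=0, seed=1)


class TestCollapse:
    nwk = "(((a,b)0.9,(c,d)0.6)0.8,(e,f)0.3);"

    def test_threshold_zero_is_identity(self):
        t = read_support_tree(self.nwk)
        c = collapse_low_support(t, threshold=0.0)
        assert splits_of(c) == splits_of(read_support_tree(self.nwk))

    def test_threshold_above_one_gives_star(self):
        t = read_support_tree(self.nwk)
        c = collapse_low_support(t, threshold=1.1)
        assert splits_of(c) == set()
        assert len(c.leaf_nodes()) == 6

    def test_mixed_supports_hand_checked(self):
        # supports {0.9, 0.8, 0.6, 0.3}: exactly the 0.6 and 0.3 branches go,
        # leaving the hand-drawn tree (((a,b),c,d),e,f)
        t = read_support_tree(self.nwk)
        c = collapse_low_support(t, threshold=0.70)
        # the 0.6 (cd) and 0.3 (ef) branches are contracted; the surviving
        # 0.9 and 0.8 branches encode (away from taxon 'a') the splits
        # ab|cdef -> {cdef} and abcd|ef -> {ef}
        assert splits_of(c) == {frozenset("cdef"), frozenset("ef")}

    def test_exact_threshold_kept(self):
        # comparison is strict: support exactly 0.70 survives
        t = read_support_tree("(((a,b)0.7,(c,d)0.699):1.0,(e,f)0.8);")
        c = collapse_low_support(t, threshold=0.7)
        got = splits_of(c)
        assert frozenset("cdef") in got or frozenset("ef") in got
        assert frozenset("cd") not in got  # 0.699 collapsed
        # the 0.7 branch (ab | rest) must still be resolved
        assert any(s == frozenset("cdef") for s in got)

    def test_percent_scale_autodetected(self):
        t = read_support_tree("(((a,b)95,(c,d)40)80,(e,f)30);")
        sups = sorted(n.support for n in t.preorder_node_iter()
                      if getattr(n, "support", None) is not None)
        assert sups == [0.3, 0.4, 0.8, 0.95]


class TestPositionRange:
    def test_fully_resolved_tree_pins_scenario(self, ref_tree, ref_scenarios):
        gene = ref_scenarios.dendropy_trees()[3]  # scenario 4 topology
        assert w_position_range(gene, ref_scenarios) == (4, 4)

    def test_star_tree_compatible_with_everything(self, ref_scenarios):
        labels = ref_scenarios.tip_labels
        star = parse_newick("(" + ",".join(labels) + ");")
        assert w_position_range(star, ref_scenarios) == (1, 12)

    def test_w_in_sylvioidea_polytomy_spans_internal_indices(self, ref_tree,
                                                             ref_scenarios):
        # W resolved inside the Sylvioidea clade but its position within
        # collapsed: compatible exactly with the Sylvioidea-internal indices
        syl = ["A_arundinaceus", "A_stentoreus", "A_palustris", "I_opaca",
               "L_luscinioides", "P_biarmicus", "A_arundinaceus_W"]
        rest = ["P_major", "T_guttata", "L_coronata", "M_undulatus",
                "G_gallus", "D_novaehollandiae", "A_carolinensis"]
        nwk = "((" + ",".join(syl) + ")," + ",".join(rest) + ");"
        gene = parse_newick(nwk)
        lo, hi = w_position_range(gene, ref_scenarios)
        # brute-force compatibility oracle over all scenarios
        gene_splits = _splits(gene, frozenset(syl + rest))
        expect = [k for k, t in enumerate(ref_scenarios.dendropy_trees(), 1)
                  if gene_splits <= _splits(t, frozenset(syl + rest))]
        assert (lo, hi) == (min(expect), max(expect)) == (1, 6)

    def test_incompatible_tree_raises_naming_split(self, ref_tree, ref_scenarios):
        # W nested inside a non-focal clade conflicts with every scenario
        labels = [l for l in ref_scenarios.tip_labels
                  if l not in ("G_gallus", "A_arundinaceus_W")]
        nwk = "((G_gallus,A_arundinaceus_W)," + ",".join(labels) + ");"
        with pytest.raises(TreeError, match="incompatible"):
            w_position_range(parse_newick(nwk), ref_scenarios)

    def test_collapsing_never_shrinks_range(self, ref_tree, ref_scenarios):
        # compatibility is monotone under collapsing
        gene, _ = gametolog_tree(ref_tree, t_rc=10.0)
        full = w_position_range(gene, ref_scenarios)
        # collapse the two shallowest internal nodes
        t = parse_newick(write_newick(gene))
        inner = [n for n in t.postorder_node_iter()
                 if not n.is_leaf() and n.parent_node is not None]
        for n in inner[:2]:
            n.edge.collapse()
        wider = w_position_range(t, ref_scenarios)
        assert wider[0] <= full[0] <= full[1] <= wider[1]

    def test_end_to_end_on_simulated_gene(self, ref_tree, ref_scenarios):
        tree, truth = gametolog_tree(ref_tree, t_rc=100.0)
        aln = simulate_alignment(tree, default_model(), 2000, seed=3)
        st = bootstrap_supports(aln, B=100, seed=5)
        coll = collapse_low_support(st, 0.70)
        lo, hi = w_position_range(coll, ref_scenarios)
        assert lo <= truth <= hi
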