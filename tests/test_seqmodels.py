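"""Likelihood engine: closed forms, an exhaustive-state oracle, optimization."""

import itertools

import numpy as np
import pytest

from stratadate.seqmodels import (
    Alignment,
    AlignmentError,
    SubstitutionModel,
    TreeLikelihood,
    empirical_base_frequencies,
    fit_model,
    optimize_branch_lengths,
    site_log_likelihoods,
)
from stratadate.trees import parse_newick, write_newick


def exhaustive_site_lnl(aln, tree, model):
    """Oracle: sum over all internal-state assignments, per site."""
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    rates, w = model.category_rates_weights()
    lam, left, right = model.eigensystem()
    out = []
    for s in range(aln.length):
        masks = {l: aln.tip_partials(l)[:, s] for l in aln.labels}
        lik_cats = []
        for rc in rates:
            P = {
                id(n): left @ np.diag(np.exp(lam * rc * n.edge.length)) @ right
                for n in nodes if n.parent_node is not None
            }
            lik = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                st = {id(n): a for n, a in zip(internals, assign)}
                pr = model.pi[st[id(tree.seed_node)]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    if n.is_leaf():
                        pr *= P[id(n)][st[id(n.parent_node)]] @ masks[n.taxon.label]
                    else:
                        pr *= P[id(n)][st[id(n.parent_node)], st[id(n)]]
                lik += pr
            lik_cats.append(lik)
        mix = float(np.dot(w, lik_cats))
        if model.pinv > 0:
            inv = sum(
                model.pi[b] * np.prod([masks[l][b] for l in aln.labels])
                for b in range(4)
            )
            mix = (1 - model.pinv) * mix + model.pinv * inv
        out.append(np.log(mix))
    return np.array(out)


def random_alignment(rng, labels, L, chars="ACGT"):
    return Alignment(labels, ["".join(rng.choice(list(chars), L)) for _ in labels])


class TestAlignment:
    def test_fasta_roundtrip(self, tmp_path, rng):
        aln = random_alignment(rng, ["a", "b", "c"], 30, chars="ACGTN-")
        p = tmp_path / "x.fasta"
        aln.to_fasta(p)
        back = Alignment.from_fasta(p)
        assert back.labels == aln.labels
        assert back.sequences == aln.sequences

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError, match="unequal"):
            Alignment(["a", "b"], ["ACGT", "ACG"])

    def test_ambiguity_masks(self):
        aln = Alignment(["a"], ["RN-"])
        tp = aln.tip_partials("a")
        assert tp[:, 0].tolist() == [1, 0, 1, 0]  # R = A or G
        assert tp[:, 1].tolist() == [1, 1, 1, 1]
        assert tp[:, 2].tolist() == [1, 1, 1, 1]

    def test_empirical_frequencies_ignore_missing(self):
        aln = Alignment(["a", "b"], ["AAAA", "NNNN"])
        pi = empirical_base_frequencies(aln, pseudocount=0.0)
        assert pi[0] == pytest.approx(1.0)


class TestModel:
    def test_rate_matrix_properties(self):
        for fam, kw in [("JC69", {}), ("HKY85", {"kappa": 4.0}),
                        ("TN93", {"kappa1": 5.0, "kappa2": 2.0}),
                        ("GTR", {"exch": [1.2, 2.5, 0.8, 1.1, 3.0, 1.0],
                                 "pi": [0.3, 0.2, 0.25, 0.25]})]:
            m = SubstitutionModel(family=fam, **kw)
            q = m.q_matrix()
            assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
            assert np.allclose(m.pi @ q, 0, atol=1e-12)  # stationarity
            assert -np.dot(m.pi, np.diag(q)) == pytest.approx(1.0)

    def test_pmat_rows_sum_to_one(self):
        m = SubstitutionModel(family="GTR", exch=[1.2, 2.5, 0.8, 1.1, 3.0, 1.0],
                              pi=[0.3, 0.2, 0.25, 0.25], alpha=0.5)
        P = m.pmats(np.array([0.0, 0.1, 2.0]))
        assert np.allclose(P.sum(axis=3), 1.0, atol=1e-10)
        assert np.allclose(P[0, 0], np.eye(4), atol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            SubstitutionModel(family="F81")
        with pytest.raises(ValueError):
            SubstitutionModel(pinv=1.0)
        with pytest.raises(ValueError):
            SubstitutionModel(alpha=-1.0)


class TestSiteLikelihoods:
    def test_single_tip_is_log_pi(self):
        m = SubstitutionModel(family="HKY85", pi=[0.4, 0.3, 0.2, 0.1])
        aln = Alignment(["a"], ["ACGT"])
        tree = parse_newick("(a);")
        ll = site_log_likelihoods(aln, tree, m)
        assert np.allclose(ll, np.log(m.pi))

    def test_two_tip_jc_closed_form(self):
        t = 0.2
        m = SubstitutionModel(family="JC69")
        tree = parse_newick("(a:0.1,b:0.1);")
        same = site_log_likelihoods(Alignment(["a", "b"], ["A", "A"]), tree, m)[0]
        diff = site_log_likelihoods(Alignment(["a", "b"], ["A", "C"]), tree, m)[0]
        assert same == pytest.approx(np.log(0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3))),
                                     abs=1e-12)
        assert diff == pytest.approx(np.log(0.25 * (0.25 - 0.25 * np.exp(-4 * t / 3))),
                                     abs=1e-12)

    @pytest.mark.parametrize("family,kw", [
        ("JC69", {}),
        ("GTR", {"exch": [1.2, 2.5, 0.8, 1.1, 3.0, 1.0],
                 "pi": [0.3, 0.2, 0.25, 0.25], "alpha": 0.7, "pinv": 0.15}),
    ])
    def test_matches_exhaustive_oracle(self, family, kw, rng):
        m = SubstitutionModel(family=family, **kw)
        aln = random_alignment(rng, list("abcd"), 12, chars="ACGTN-")
        tree = parse_newick("((a:0.1,b:0.3):0.15,(c:0.2,d:0.08):0.05);")
        mine = site_log_likelihoods(aln, tree, m)
        oracle = exhaustive_site_lnl(aln, tree, m)
        assert np.max(np.abs(mine - oracle)) < 1e-9

    def test_root_placement_invariance(self, rng):
        # reversible model: likelihood identical for any rooting of the
        # same unrooted tree
        m = SubstitutionModel(family="HKY85", kappa=3.0,
                              pi=[0.3, 0.2, 0.25, 0.25], alpha=0.9)
        aln = random_alignment(rng, list("abcd"), 40)
        t1 = parse_newick("((a:0.1,b:0.3):0.06,(c:0.2,d:0.08):0.09);")
        t2 = parse_newick("(a:0.04,(b:0.3,(c:0.2,d:0.08):0.15):0.06);")
        l1 = site_log_likelihoods(aln, t1, m).sum()
        l2 = site_log_likelihoods(aln, t2, m).sum()
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_single_category_gamma_reduces_to_none(self, rng):
        aln = random_alignment(rng, list("abc"), 25)
        tree = parse_newick("((a:0.1,b:0.2):0.05,c:0.15);")
        base = SubstitutionModel(family="HKY85", kappa=2.5)
        g1 = SubstitutionModel(family="HKY85", kappa=2.5, alpha=0.37, ncat=1)
        assert site_log_likelihoods(aln, tree, base).sum() == pytest.approx(
            site_log_likelihoods(aln, tree, g1).sum(), abs=1e-12)

    def test_missing_taxon_raises(self):
        aln = Alignment(["a", "b"], ["AC", "GT"])
        tree = parse_newick("((a:0.1,b:0.1):0.1,zz:0.2);")
        with pytest.raises(AlignmentError, match="zz"):
            site_log_likelihoods(aln, tree, SubstitutionModel(family="JC69"))


class TestBranchOptimization:
    def test_identical_sequences_shrink_branches(self):
        aln = Alignment(list("abc"), ["ACGTACGT"] * 3)
        tree = parse_newick("((a:0.3,b:0.3):0.3,c:0.3);")
        m = SubstitutionModel(family="JC69")
        tree, lnl, _ = optimize_branch_lengths(aln, tree, m)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length < 1e-6

    def test_two_taxon_jc_ml_distance(self, rng):
        L = 1000
        a = rng.choice(list("ACGT"), L)
        b = a.copy()
        flip = rng.random(L) < 0.15
        b[flip] = rng.choice(list("ACGT"), int(flip.sum()))
        aln = Alignment(["x", "y"], ["".join(a), "".join(b)])
        p = np.mean(a != b)
        tree = parse_newick("(x:0.05,y:0.05);")
        tree, _, _ = optimize_branch_lengths(aln, tree,
                                             SubstitutionModel(family="JC69"))
        total = sum(e.length for e in tree.preorder_edge_iter() if e.length)
        assert total == pytest.approx(-0.75 * np.log(1 - 4 * p / 3), abs=1e-6)

    def test_local_optimality(self, rng):
        aln = random_alignment(rng, list("abcd"), 300)
        tree = parse_newick("((a:0.1,b:0.3):0.15,(c:0.2,d:0.08):0.05);")
        m = SubstitutionModel(family="HKY85", kappa=2.0)
        tree, lnl, _ = optimize_branch_lengths(aln, tree, m, xatol=1e-6)
        eng = TreeLikelihood(tree, aln, m)
        base = eng.lnl()
        for i in eng.free_edges:
            for f in (0.9, 1.1):
                saved = eng.blens[i]
                eng.blens[i] = max(saved * f, 1e-9)
                assert eng.lnl() <= base + 1e-6
                eng.blens[i] = saved

    def test_returned_lnl_not_below_start(self, rng):
        aln = random_alignment(rng, list("abcde"), 100)
        tree = parse_newick("(((a:0.5,b:0.01):0.3,(c:0.9,d:0.02):0.1):0.2,e:0.4);")
        m = SubstitutionModel(family="JC69")
        start = site_log_likelihoods(aln, tree, m).sum()
        _, lnl, _ = optimize_branch_lengths(aln, tree, m)
        assert lnl >= start - 1e-9


class TestFitModel:
    def test_hky_kappa_recovery(self):
        from stratadate.simulate import simulate_alignment

        truth = SubstitutionModel(family="HKY85", kappa=4.0,
                                  pi=[0.3, 0.2, 0.2, 0.3])
        tree = parse_newick("((a:0.15,b:0.2):0.1,(c:0.12,d:0.25):0.08);")
        aln = simulate_alignment(tree, truth, 4000, seed=5)
        fitted = fit_model(aln, tree, family="HKY85")
        assert abs(fitted.kappa - 4.0) / 4.0 < 0.15

    def test_equal_frequency_data(self, rng):
        from stratadate.simulate import simulate_alignment

        tree = parse_newick("(a:0.2,b:0.2);")
        aln = simulate_alignment(tree, SubstitutionModel(family="JC69"), 4000, seed=3)
        fitted = fit_model(aln, tree, family="HKY85")
        assert np.allclose(fitted.pi, 0.25, atol=0.02)

    def test_pinv_stays_in_bounds(self, rng):
        aln = random_alignment(rng, list("abcd"), 200)
        tree = parse_newick("((a:0.1,b:0.3):0.15,(c:0.2,d:0.08):0.05);")
        fitted = fit_model(aln, tree, family="HKY85", fit_pinv=True)
        assert 0 <= fitted.pinv < 1

    def test_degenerate_alignment_warns(self):
        aln = Alignment(list("ab"), ["ACGT", "ACGT"])
        tree = parse_newick("(a:0.1,b:0.1);")
        with pytest.warns(UserWarning, match="degenerate"):
            fit_model(aln, tree, family="HKY85")
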