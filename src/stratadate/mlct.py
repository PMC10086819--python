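"""The ML collapsed-tree (ML_CT) approach to reading off t_RC ranges.

A gene tree is estimated (neighbor joining plus NNI hill-climbing under
the likelihood engine), bootstrap supports are attached by site
resampling, weakly supported branches (< 0.7 by default) are collapsed
into polytomies, and the resulting cladogram is compared against the
scenario set: every scenario whose topology refines the collapsed gene
tree is compatible, and the [min, max] compatible index is the gene's
tree-position range on the discrete t_RC scale.
"""

from __future__ import annotations

import numpy as np
import dendropy
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .seqmodels import Alignment, SubstitutionModel, TreeLikelihood
from .trees import ScenarioSet, TreeError, parse_newick, write_newick

__all__ = [
    "jc_distance_matrix",
    "nj_tree",
    "ml_search",
    "bootstrap_supports",
    "collapse_low_support",
    "w_position_range",
    "read_support_tree",
]


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

def jc_distance_matrix(aln: Alignment):
    """Jukes–Cantor corrected pairwise distances over shared unambiguous
    sites; saturated pairs (p >= 3/4) are capped at a large finite value."""
    n = aln.n_taxa
    plain = {1: 0, 2: 1, 4: 2, 8: 3}
    codes = np.full(aln.masks.shape, -1, dtype=int)
    for m, b in plain.items():
        codes[aln.masks == m] = b
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            tot = int(ok.sum())
            p = float(np.mean(codes[i][ok] != codes[j][ok])) if tot else 0.0
            if p >= 0.749:
                dist = 5.0
            else:
                dist = -0.75 * np.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return d, list(aln.labels)


def nj_tree(d: np.ndarray, labels) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix (>= 3 taxa);
    exact on additive matrices.  Negative branch lengths are clamped to 0."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise TreeError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise TreeError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise TreeError("distance matrix must have a zero diagonal")
    if d.shape[0] < 3:
        raise TreeError("need at least 3 taxa for neighbor joining")
    dm = DistanceMatrix(d, ids=list(labels))
    sk = _skbio_nj(dm)
    tree = parse_newick(str(sk).strip())
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            e.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# NNI hill-climbing ML search
# ---------------------------------------------------------------------------

def _nni_neighbors(tree: dendropy.Tree):
    """Yield cloned trees one rooted-NNI move away (covers the unrooted
    NNI neighborhood of a binary tree)."""
    newick = write_newick(tree)
    base = parse_newick(newick)
    internal = [
        n for n in base.preorder_node_iter()
        if (not n.is_leaf()) and n.parent_node is not None
    ]
    for idx, _ in enumerate(internal):
        for which in (0, 1):
            t = parse_newick(newick)
            nodes = [
                n for n in t.preorder_node_iter()
                if (not n.is_leaf()) and n.parent_node is not None
            ]
            v = nodes[idx]
            u = v.parent_node
            sibs = [c for c in u.child_nodes() if c is not v]
            if not sibs:
                continue
            c = sibs[0]
            a = v.child_nodes()[which]
            # swap subtrees a (child of v) and c (sibling of v)
            u.remove_child(c)
            v.remove_child(a)
            u.add_child(a)
            v.add_child(c)
            yield t


def _optimized_lnl(tree, aln, model, max_sweeps=4):
    eng = TreeLikelihood(tree, aln, model)
    lnl, _ = eng.optimize_branches(tol=1e-7, max_sweeps=max_sweeps)
    eng.write_lengths_to_tree()
    return lnl


def ml_search(aln: Alignment, model: SubstitutionModel, start_tree: dendropy.Tree,
              tol: float = 1e-3, max_rounds: int = 20):
    """Greedy NNI hill climb from ``start_tree``.

    Each round evaluates all NNI neighbors (branch lengths re-optimized)
    and takes the best improving move; stops when no move improves the
    log-likelihood by more than ``tol``.  Returns ``(tree, lnl)`` with
    lnl >= the start tree's optimized lnl.
    """
    current = parse_newick(write_newick(start_tree))
    cur_lnl = _optimized_lnl(current, aln, model)
    for _ in range(max_rounds):
        best, best_lnl = None, cur_lnl
        for cand in _nni_neighbors(current):
            lnl = _optimized_lnl(cand, aln, model)
            if lnl > best_lnl + tol:
                best, best_lnl = cand, lnl
        if best is None:
            break
        current, cur_lnl = best, best_lnl
    return current, cur_lnl


# ---------------------------------------------------------------------------
# Bootstrap supports
# ---------------------------------------------------------------------------

def _leafset(node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def _splits(tree: dendropy.Tree, subset: frozenset) -> set[frozenset]:
    """Non-trivial unrooted splits restricted to ``subset``, each encoded
    as the side not containing the reference (lexicographically smallest)
    taxon."""
    ref = min(subset)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _leafset(node) & subset
        other = subset - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(frozenset(other if ref in side else side))
    return out


def bootstrap_supports(aln: Alignment, B: int, seed=None,
                       tree: dendropy.Tree | None = None) -> dendropy.Tree:
    """Attach site-resampling bootstrap supports to a gene tree.

    Replicate trees are neighbor-joining trees on JC distances of B
    column-resampled alignments; the support of an internal branch of
    ``tree`` (default: the NJ tree of the full alignment) is the fraction
    of replicates containing its split.  Supports are stored on internal
    nodes as ``node.support`` in [0, 1] (and mirrored into node labels).
    Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if tree is None:
        d, labels = jc_distance_matrix(aln)
        tree = nj_tree(d, labels)
    taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    L = aln.length
    for _ in range(B):
        idx = rng.integers(0, L, size=L)
        rep = Alignment(aln.labels, ["".join(s[i] for i in idx) for s in aln.sequences])
        d, labels = jc_distance_matrix(rep)
        for split in _splits(nj_tree(d, labels), taxa):
            counts[split] = counts.get(split, 0) + 1
    ref = min(taxa)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _leafset(node)
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            node.support = None
            continue
        key = frozenset(other if ref in side else side)
        node.support = counts.get(key, 0) / B
        node.label = f"{node.support:.4g}"
    return tree


def read_support_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick gene tree whose internal node labels are bootstrap
    supports; values on a [0, 100] scale are rescaled to [0, 1]."""
    tree = parse_newick(newick)
    vals = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None or node.label is None:
            continue
        try:
            vals.append((node, float(node.label)))
        except ValueError:
            continue
    scale = 100.0 if any(v > 1.0 for _, v in vals) else 1.0
    for node, v in vals:
        node.support = v / scale
    return tree


def collapse_low_support(tree: dendropy.Tree, threshold: float = 0.70) -> dendropy.Tree:
    """Contract every internal branch whose support is strictly below
    ``threshold`` (supports exactly at the threshold are kept), producing
    polytomies; tips are never removed.  Returns a new tree."""
    out = parse_newick(write_newick(tree, suppress_internal_node_labels=False))
    # carry supports over by split identity
    taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    to_collapse = []
    for node in out.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        sup = None
        if node.label is not None:
            try:
                sup = float(node.label)
            except ValueError:
                sup = None
        if sup is not None and sup < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


# ---------------------------------------------------------------------------
# Position range on the scenario scale
# ---------------------------------------------------------------------------

def w_position_range(gene_tree: dendropy.Tree, scenarios: ScenarioSet) -> tuple[int, int]:
    """[min, max] scenario index compatible with a (possibly collapsed)
    gene tree.

    Scenario k is compatible iff every non-trivial split of the gene tree,
    restricted to the taxa shared with the scenario topology, is a split
    of scenario k — i.e. the scenario refines the gene tree.  Raises
    :class:`TreeError` naming a conflicting split when no scenario is
    compatible.
    """
    gene_taxa = frozenset(l.taxon.label for l in gene_tree.leaf_node_iter())
    scen_taxa = frozenset(scenarios.tip_labels)
    if not gene_taxa <= scen_taxa:
        raise TreeError(f"gene tree tips not in scenario set: {sorted(gene_taxa - scen_taxa)}")
    shared = gene_taxa
    gene_splits = _splits(gene_tree, shared)
    compatible = []
    scen_split_sets = []
    for k, tree in enumerate(scenarios.dendropy_trees(), start=1):
        ssplits = _splits(tree, shared)
        scen_split_sets.append(ssplits)
        if gene_splits <= ssplits:
            compatible.append(k)
    if not compatible:
        everywhere = set.union(*scen_split_sets) if scen_split_sets else set()
        conflict = next(iter(gene_splits - everywhere), next(iter(gene_splits)))
        raise TreeError(
            f"gene tree incompatible with every scenario; conflicting split: "
            f"{sorted(conflict)}"
        )
    return min(compatible), max(compatible)
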