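"""Synthetic gametolog data with known recombination-cessation times.

The generative model mirrors the assumptions behind the scenario
topologies: the Z genealogy equals the dated species tree (no coalescent
variation or incomplete lineage sorting), and the W lineage of the focal
species splits from the focal path at exactly the cessation time t_RC.
With ``multi_w`` the W lineages of w-bearing species that speciated after
t_RC mirror the species topology; species that split earlier keep their W
sister to their own Z (their own cessation is placed at half the age of
their split from the focal path).  W-side branches evolve faster by a
configurable multiplier, emulating the elevated substitution rate of
degenerating W chromosomes.

The default two-strata design emulates a neo-sex chromosome: 22 "old"
genes whose cessation predates the Sylvioidea-analog clade and 29 "young"
genes whose cessation falls inside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .reference import reference_species_tree
from .seqmodels import Alignment, SubstitutionModel
from .trees import (
    SpeciesTree,
    TreeError,
    parse_newick,
    scenario_to_time_interval,
    time_to_scenario,
    w_label,
)

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "gametolog_tree",
    "gametolog_time_tree",
    "simulate_alignment",
    "simulate_two_strata",
    "default_model",
]

_STOPS = {"TAA", "TAG", "TGA"}


def default_model() -> SubstitutionModel:
    """The generator's default substitution model: HKY85 with a moderate
    transition bias and mildly AT-rich composition."""
    return SubstitutionModel(family="HKY85", kappa=3.0,
                             pi=np.array([0.27, 0.23, 0.23, 0.27]))


@dataclass
class SimConfig:
    """Study conditions for a two-strata gametolog simulation.

    Times are in the species tree's age units (Myr for the bundled
    reference tree).  ``clock_rate`` is expected substitutions per site
    per time unit on non-W branches; W-side branches are multiplied by
    ``w_rate``.  Defaults: 22 old + 29 young genes, cessation times drawn
    uniformly from ``old_time_range`` / ``young_time_range``.
    """

    species_tree: SpeciesTree = field(default_factory=reference_species_tree)
    n_old: int = 22
    n_young: int = 29
    L: int = 1200
    model: SubstitutionModel = field(default_factory=default_model)
    clock_rate: float = 1e-3
    w_rate: float = 1.5
    multi_w: bool = False
    coding: bool = False
    old_time_range: tuple = (90.0, 150.0)
    young_time_range: tuple = (1.0, 21.0)
    seed: int | None = None

    def __post_init__(self):
        if self.coding and self.L % 3:
            raise ValueError("coding output requires L divisible by 3")
        if self.L < 3:
            raise ValueError("L must be >= 3")
        H = self.species_tree.root_age
        for lo, hi in (self.old_time_range, self.young_time_range):
            if not (0 < lo < hi <= H):
                raise ValueError("cessation time range outside (0, root age]")


# ---------------------------------------------------------------------------
# Gene (gametolog) tree construction
# ---------------------------------------------------------------------------

class _N:
    __slots__ = ("age", "children", "label", "w")

    def __init__(self, age, children=None, label=None, w=False):
        self.age = age
        self.children = children or []
        self.label = label
        self.w = w


def _from_species(sp: SpeciesTree, node):
    if node.is_leaf():
        return _N(0.0, label=node.taxon.label)
    return _N(sp.age(node), children=[_from_species(sp, c) for c in node.child_nodes()])


def _tips(n):
    if n.label is not None:
        return [n.label]
    out = []
    for c in n.children:
        out.extend(_tips(c))
    return out


def _restrict(n, keep):
    if n.label is not None:
        return n if n.label in keep else None
    kids = [r for r in (_restrict(c, keep) for c in n.children) if r is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return _N(n.age, children=kids)


def _clone_as_w(n):
    out = _N(n.age, label=w_label(n.label) if n.label is not None else None, w=True)
    out.children = [_clone_as_w(c) for c in n.children]
    return out


def _build_gametolog(sp: SpeciesTree, t_rc: float, multi_w: bool):
    if not 0 < t_rc <= sp.root_age:
        raise TreeError(f"t_rc must lie in (0, root age]; got {t_rc}")
    root = _from_species(sp, sp.tree.seed_node)
    focal = sp.focal_species
    wset = sp.w_bearing_set if multi_w else frozenset([focal])

    # walk down the focal path to the edge straddling t_rc and insert there
    node = root
    while True:
        (child,) = [c for c in node.children if focal in _tips(c)]
        if child.age < t_rc:
            break
        node = child
    below = set(_tips(child)) & set(wset)
    if multi_w and len(below) > 1:
        w_sub = _clone_as_w(_restrict(child, below))
    else:
        w_sub = _N(0.0, label=w_label(focal), w=True)
        below = {focal}
    attach = _N(t_rc, children=[child, w_sub])
    node.children[node.children.index(child)] = attach

    # w-bearing species that split before t_rc: W sister to their own Z,
    # with an independent cessation at half their split age
    def graft_own(n):
        for i, c in enumerate(n.children):
            if c.label is not None and c.label in wset and c.label not in below:
                wleaf = _N(0.0, label=w_label(c.label), w=True)
                n.children[i] = _N(0.5 * n.age, children=[c, wleaf])
            else:
                graft_own(c)

    graft_own(root)
    return root


def _emit_newick(n, parent_age, clock_rate, w_rate):
    rate = clock_rate * (w_rate if n.w else 1.0)
    bl = (parent_age - n.age) * rate
    if n.label is not None:
        return f"{n.label}:{bl:.10g}"
    inner = ",".join(_emit_newick(c, n.age, clock_rate, w_rate) for c in n.children)
    return f"({inner}):{bl:.10g}"


def _to_dendropy(root, clock_rate, w_rate):
    inner = ",".join(_emit_newick(c, root.age, clock_rate, w_rate) for c in root.children)
    return parse_newick(f"({inner});")


def gametolog_tree(species_tree: SpeciesTree, t_rc: float, w_rate: float = 1.5,
                   multi_w: bool = False, clock_rate: float = 1e-3):
    """Dated gametolog gene tree with branch lengths in substitutions/site.

    Returns ``(tree, scenario_index)``; the tree's topology equals the
    enumerated scenario whose time interval contains ``t_rc``.
    """
    root = _build_gametolog(species_tree, t_rc, multi_w)
    tree = _to_dendropy(root, clock_rate, w_rate)
    return tree, time_to_scenario(t_rc, species_tree)


def gametolog_time_tree(species_tree: SpeciesTree, t_rc: float, multi_w: bool = False):
    """Same topology as :func:`gametolog_tree` but with branch lengths in
    time units (ultrametric) — the starting state for node dating."""
    root = _build_gametolog(species_tree, t_rc, multi_w)
    return _to_dendropy(root, 1.0, 1.0)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def simulate_alignment(genetree: dendropy.Tree, model: SubstitutionModel, L: int,
                       seed=None, rng: np.random.Generator | None = None,
                       coding: bool = False) -> Alignment:
    """Evolve sequences along ``genetree`` (branch lengths in subs/site).

    The root state is drawn from the stationary frequencies (per codon
    avoiding stop codons when ``coding``); each branch applies the exact
    transition probabilities of the model, with per-site discrete-gamma
    rate categories (and invariant sites) when the model has them.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    rates, weights = model.category_rates_weights()
    ncat = rates.size
    cat = rng.choice(ncat, p=weights, size=L) if ncat > 1 else np.zeros(L, dtype=int)
    inv = rng.random(L) < model.pinv if model.pinv > 0 else np.zeros(L, dtype=bool)

    root_states = rng.choice(4, p=model.pi, size=L)
    if coding:
        if L % 3:
            raise ValueError("coding simulation requires L divisible by 3")
        codons = root_states.reshape(-1, 3)
        for i in range(codons.shape[0]):
            while "".join("ACGT"[b] for b in codons[i]) in _STOPS:
                codons[i] = rng.choice(4, p=model.pi, size=3)
        root_states = codons.ravel()

    states = {id(genetree.seed_node): root_states}
    seqs = {}
    for node in genetree.preorder_node_iter():
        if node.parent_node is not None:
            bl = float(node.edge.length or 0.0)
            P = model.pmats(np.array([bl]))[0]  # (ncat, 4, 4)
            P = P / P.sum(axis=2, keepdims=True)  # numerical safety
            parent = states[id(node.parent_node)]
            rows = P[cat, parent]  # (L, 4)
            u = rng.random(L)
            child = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
            child = np.where(inv, parent, child)
            states[id(node)] = child
        if node.is_leaf():
            seqs[node.taxon.label] = "".join("ACGT"[b] for b in states[id(node)])
    labels = sorted(seqs)
    return Alignment(labels, [seqs[l] for l in labels])


# ---------------------------------------------------------------------------
# Two-strata dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Per-gene alignments plus the truth table pairing each gene with its
    generating cessation time and scenario index."""

    config: SimConfig
    alignments: dict
    truth: pd.DataFrame
    gene_trees: dict

    def write(self, outdir) -> dict:
        """Write one FASTA per gene, the truth TSV, the dated reference
        tree and a manifest; returns the manifest dict."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for gene, aln in self.alignments.items():
            p = outdir / f"{gene}.fasta"
            aln.to_fasta(p)
            paths[gene] = str(p)
        truth_path = outdir / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        tree_path = outdir / "reference.nwk"
        tree_path.write_text(self.config.species_tree.to_newick() + "\n")
        manifest = {
            "genes": paths,
            "truth": str(truth_path),
            "reference_tree": str(tree_path),
            "seed": self.config.seed,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def simulate_two_strata(config: SimConfig) -> SimulatedDataset:
    """Simulate the old/young two-strata gene set defined by ``config``."""
    sp = config.species_tree
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss)
    strata = [("old", config.old_time_range)] * config.n_old + [
        ("young", config.young_time_range)
    ] * config.n_young
    child_seeds = ss.spawn(len(strata))
    alignments, gene_trees, rows = {}, {}, []
    for i, ((stratum, (lo, hi)), cs) in enumerate(zip(strata, child_seeds)):
        gene = f"{stratum}{i + 1:03d}"
        t_rc = float(master.uniform(lo, hi))
        tree, scen = gametolog_tree(sp, t_rc, w_rate=config.w_rate,
                                    multi_w=config.multi_w,
                                    clock_rate=config.clock_rate)
        aln = simulate_alignment(tree, config.model, config.L,
                                 rng=np.random.default_rng(cs),
                                 coding=config.coding)
        alignments[gene] = aln
        gene_trees[gene] = tree
        rows.append({
            "gene_id": gene,
            "stratum": stratum,
            "t_rc": t_rc,
            "t_rc_norm": t_rc / sp.root_age,
            "scenario": scen,
        })
    truth = pd.DataFrame(rows)
    for _, r in truth.iterrows():  # scenario index consistent with its interval
        lo, hi = scenario_to_time_interval(int(r.scenario), sp)
        assert lo < r.t_rc_norm <= hi + 1e-12
    return SimulatedDataset(config, alignments, truth, gene_trees)
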