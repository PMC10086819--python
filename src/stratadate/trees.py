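"""Rooted dated species trees and recombination-cessation scenario topologies.

A gene on a sex chromosome stops recombining between Z and W at some time
t_RC; after that the two gametologs diverge independently.  On a dated,
rooted reference species topology every possible t_RC falls into one of a
small number of intervals delimited by the speciation nodes on the path
from the focal species to the root.  Each interval corresponds to one
*hypothetical gametolog topology*: the W sequence attaches to the species
tree inside that interval.  This module builds and indexes those
topologies ("scenarios"), ordered from the most recent cessation
(scenario 1: W sister to the focal Z) to the most ancient one allowed
(attachment just below the root).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeError",
    "SpeciesTree",
    "FocalPath",
    "ScenarioSet",
    "parse_newick",
    "write_newick",
    "w_label",
    "enumerate_single_w",
    "enumerate_multi_w",
    "scenario_to_time_interval",
]

#: suffix appended to a species label to name its W gametolog sequence
W_SUFFIX = "_W"


def w_label(species: str) -> str:
    """Return the label used for the W gametolog tip of ``species``."""
    return species + W_SUFFIX


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


# ---------------------------------------------------------------------------
# Newick I/O (thin wrappers over dendropy)
# ---------------------------------------------------------------------------

def parse_newick(text: str, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree.

    Underscores in labels are preserved literally.  Duplicate tip labels
    raise :class:`TreeError`, as do syntax errors (with the parser's
    position information in the message).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip label(s): {dupes}")
    return tree


def write_newick(tree: dendropy.Tree, **kwargs) -> str:
    """Serialize a tree to a one-line Newick string."""
    kwargs.setdefault("suppress_rooting", True)
    kwargs.setdefault("unquoted_underscores", True)
    return tree.as_string(schema="newick", **kwargs).strip()


# ---------------------------------------------------------------------------
# Nested-tuple topology helpers (internal)
# ---------------------------------------------------------------------------
# A topology is either a tip label (str) or a tuple of child topologies.
# This immutable representation makes grafting and restriction trivial and
# safe; dendropy trees are produced only at the emission boundary.

def _node_to_nested(node):
    if node.is_leaf():
        return node.taxon.label
    return tuple(_node_to_nested(c) for c in node.child_nodes())


def _nested_tips(nested):
    if isinstance(nested, str):
        return [nested]
    out = []
    for child in nested:
        out.extend(_nested_tips(child))
    return out


def _nested_restrict(nested, keep):
    """Restrict a nested topology to the tip set ``keep`` (suppressing
    unary nodes); returns None if no tips remain."""
    if isinstance(nested, str):
        return nested if nested in keep else None
    kids = [r for r in (_nested_restrict(c, keep) for c in nested) if r is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return tuple(kids)


def _nested_relabel(nested, fn):
    if isinstance(nested, str):
        return fn(nested)
    return tuple(_nested_relabel(c, fn) for c in nested)


def _nested_newick(nested) -> str:
    def rec(n):
        if isinstance(n, str):
            return n
        return "(" + ",".join(rec(c) for c in n) + ")"

    return rec(nested) + ";"


def nested_clades(nested) -> set[frozenset]:
    """All clades (tip sets of internal nodes, incl. trivial) of a nested
    topology — used for rooted topology comparison."""
    clades = set()

    def rec(n):
        if isinstance(n, str):
            return frozenset([n])
        tips = frozenset()
        for c in n:
            tips |= rec(c)
        clades.add(tips)
        return tips

    total = rec(nested)
    clades.add(total)
    return clades


# ---------------------------------------------------------------------------
# SpeciesTree
# ---------------------------------------------------------------------------

@dataclass
class FocalPath:
    """Internal nodes on the focal-tip-to-root path, tip-to-root order.

    ``ages[i]`` is the age (time before present) of ``nodes[i]``; ages are
    non-decreasing and end at the root age.
    """

    nodes: list
    ages: np.ndarray

    def __len__(self) -> int:
        return len(self.nodes)


class SpeciesTree:
    """A rooted, binary, ultrametric (in time) reference species topology.

    Node ages are read off the branch lengths (which must therefore be in
    time units and ultrametric) or supplied through ``age_map`` mapping a
    clade's frozenset of tip labels to its age.  Tips have age 0 and the
    root age must be positive.

    Parameters
    ----------
    tree:
        A rooted dendropy tree, or a Newick string.
    focal_species:
        Tip label of the species whose W gametolog is being dated.
    w_bearing:
        Labels of species contributing W sequences; defaults to
        ``{focal_species}``.
    age_map:
        Optional ``{frozenset(tip labels): age}``; required when the tree
        carries no (or non-ultrametric) branch lengths.
    """

    def __init__(self, tree, focal_species: str, w_bearing=None, age_map=None, ultrametric_rtol=1e-4):
        if isinstance(tree, str):
            tree = parse_newick(tree)
        self.tree = tree
        self.focal_species = focal_species
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate tip labels")
        self.tips = list(labels)
        if focal_species not in self.tips:
            raise TreeError(f"focal species {focal_species!r} not a tip of the tree")
        self.w_bearing_set = frozenset(w_bearing) if w_bearing else frozenset([focal_species])
        if not self.w_bearing_set <= set(self.tips):
            raise TreeError("w_bearing_set contains labels not in the tree")
        if focal_species not in self.w_bearing_set:
            raise TreeError("focal species must be in w_bearing_set")
        self._validate_binary()
        self._ages = self._compute_ages(age_map, ultrametric_rtol)

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, focal_species: str, **kwargs) -> "SpeciesTree":
        return cls(parse_newick(text), focal_species, **kwargs)

    def _validate_binary(self):
        if len(self.tips) == 1:
            return
        for node in self.tree.preorder_node_iter():
            n = len(node.child_nodes())
            if n not in (0, 2):
                raise TreeError(
                    f"reference tree must be binary; node with {n} children found"
                )

    def _compute_ages(self, age_map, rtol):
        ages = {}
        if len(self.tips) == 1:  # degenerate single-tip tree
            return {n: 0.0 for n in self.tree.preorder_node_iter()}
        if age_map is not None:
            for node in self.tree.postorder_node_iter():
                if node.is_leaf():
                    ages[node] = 0.0
                else:
                    clade = frozenset(l.taxon.label for l in node.leaf_iter())
                    if clade not in age_map:
                        raise TreeError(f"age_map missing clade {sorted(clade)}")
                    ages[node] = float(age_map[clade])
        else:
            # depths from branch lengths; require ultrametricity
            depth = {self.tree.seed_node: 0.0}
            for node in self.tree.preorder_node_iter():
                if node is not self.tree.seed_node:
                    el = node.edge.length
                    if el is None:
                        raise TreeError(
                            "tree has no branch lengths; supply age_map instead"
                        )
                    if el < 0:
                        raise TreeError("negative branch length")
                    depth[node] = depth[node.parent_node] + el
            tip_depths = [depth[l] for l in self.tree.leaf_node_iter()]
            T = float(np.mean(tip_depths))
            if T <= 0:
                raise TreeError("root age must be > 0")
            if (np.max(tip_depths) - np.min(tip_depths)) > rtol * T:
                raise TreeError("tree is not ultrametric in time; supply age_map")
            for node in self.tree.postorder_node_iter():
                ages[node] = 0.0 if node.is_leaf() else T - depth[node]
        # parent strictly older (ties tolerated with warning downstream)
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None and ages[node.parent_node] < ages[node] - 1e-12:
                raise TreeError("node ages must increase from tips to root")
        return ages

    # -- basic accessors -----------------------------------------------------

    @property
    def root_age(self) -> float:
        return self._ages[self.tree.seed_node]

    def age(self, node) -> float:
        return self._ages[node]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def nested(self):
        return _node_to_nested(self.tree.seed_node)

    def to_newick(self) -> str:
        return write_newick(self.tree)

    # -- focal path ----------------------------------------------------------

    def focal_path(self) -> FocalPath:
        """Internal nodes from the focal tip's parent up to the root.

        Their ages delimit the scenario intervals.  Equal consecutive ages
        are permitted but produce zero-width conversion intervals (a
        warning is issued).
        """
        leaf = None
        for l in self.tree.leaf_node_iter():
            if l.taxon.label == self.focal_species:
                leaf = l
                break
        if leaf is None:  # pragma: no cover - guarded in __init__
            raise TreeError("focal species not found")
        nodes = []
        node = leaf.parent_node
        while node is not None:
            nodes.append(node)
            node = node.parent_node
        ages = np.array([self._ages[n] for n in nodes], dtype=float)
        if np.any(np.diff(ages) == 0):
            warnings.warn(
                "tied node ages on the focal path: some scenario intervals have zero width"
            )
        return FocalPath(nodes=nodes, ages=ages)


def focal_path(tree: SpeciesTree) -> FocalPath:
    """Functional alias for :meth:`SpeciesTree.focal_path`."""
    return tree.focal_path()


# ---------------------------------------------------------------------------
# Scenario enumeration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSet:
    """Ordered hypothetical gametolog topologies (the discrete t_RC scale).

    ``topologies[k-1]`` is scenario ``k``; indices run from 1 (most recent
    cessation: W sister to its own Z) to S (most ancient allowed).
    """

    species_tree: SpeciesTree
    topologies: list  # nested-tuple topologies
    kind: str  # "single" | "multi"
    descriptions: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.topologies)

    def __getitem__(self, k: int):
        """Nested topology of scenario ``k`` (1-based)."""
        if not 1 <= k <= len(self):
            raise IndexError(f"scenario index {k} outside 1..{len(self)}")
        return self.topologies[k - 1]

    @property
    def tip_labels(self) -> list[str]:
        return sorted(_nested_tips(self.topologies[0]))

    def newick(self, k: int) -> str:
        return _nested_newick(self[k])

    def dendropy_trees(self, taxon_namespace=None) -> list[dendropy.Tree]:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        return [
            parse_newick(self.newick(k), taxon_namespace=tns)
            for k in range(1, len(self) + 1)
        ]

    def to_newick_file(self, path) -> None:
        """One topology per line, ordered by index."""
        with open(path, "w") as fh:
            for k in range(1, len(self) + 1):
                fh.write(self.newick(k) + "\n")

    def to_table(self) -> pd.DataFrame:
        """Index table: scenario_id, attachment description, (t_lo, t_hi]."""
        rows = []
        for k in range(1, len(self) + 1):
            lo, hi = scenario_to_time_interval(k, self.species_tree)
            desc = self.descriptions[k - 1] if self.descriptions else ""
            rows.append(
                {"scenario_id": k, "attachment_description": desc, "t_lo": lo, "t_hi": hi}
            )
        return pd.DataFrame(rows)


def _check_emitted(nested, required_tips):
    tips = _nested_tips(nested)
    if sorted(tips) != sorted(required_tips):
        raise TreeError(
            "internal error: emitted scenario topology does not contain every "
            "required tip exactly once"
        )


def _graft_on_path(nested_root, path_clades, k, attachment):
    """Return the species topology with ``attachment`` grafted so that it is
    sister to the clade whose tip set is ``path_clades[k-1]`` (for k >= 2),
    or sister to the focal tip itself (k == 1, path_clades[0] is that tip).
    """
    target = path_clades[k - 1]

    def rec(n):
        tips = frozenset(_nested_tips(n))
        if tips == target:
            return (n, attachment)
        if isinstance(n, str):
            return n
        return tuple(rec(c) for c in n)

    return rec(nested_root)


def enumerate_single_w(tree: SpeciesTree, exclude_above_root: bool = True) -> ScenarioSet:
    """Enumerate single-W cessation scenarios on the reference topology.

    Scenario 1 places the focal W sister to the focal Z tip; scenario k
    (2 <= k <= P, with P internal nodes on the focal path) places W on the
    branch between path nodes k-1 and k, i.e. sister to the clade subtended
    by node k-1.  Attachments above the root (cessation predating the root)
    are excluded by default, so S = P.
    """
    if tree.n_tips < 2:
        raise TreeError("scenario enumeration needs at least 2 tips")
    path = tree.focal_path()
    nested = tree.nested()
    wl = w_label(tree.focal_species)
    # clades along the path, preceded by the focal tip itself
    path_clades = [frozenset([tree.focal_species])] + [
        frozenset(l.taxon.label for l in n.leaf_iter()) for n in path.nodes
    ]
    S = len(path) if exclude_above_root else len(path) + 1
    topologies, descriptions = [], []
    for k in range(1, len(path) + 1):
        topo = _graft_on_path(nested, path_clades, k, wl)
        _check_emitted(topo, tree.tips + [wl])
        topologies.append(topo)
        descriptions.append(_describe(tree, path, k))
    if not exclude_above_root:
        topo = (nested, wl)
        _check_emitted(topo, tree.tips + [wl])
        topologies.append(topo)
        descriptions.append("W diverged before the root")
    assert len(topologies) == S
    return ScenarioSet(tree, topologies, kind="single", descriptions=descriptions)


def enumerate_multi_w(tree: SpeciesTree, exclude_above_root: bool = True) -> ScenarioSet:
    """Enumerate multi-W cessation scenarios.

    The index scale is identical to :func:`enumerate_single_w`.  For
    scenario k, every w-bearing species whose lineage split from the focal
    path more recently than attachment point k contributes its W tip to a
    clade mirroring the species topology, attached at position k; every
    w-bearing species that split earlier keeps its W sister to its own Z
    (recombination continued independently in that lineage).  Scenario 1
    places every W sister to its own Z.
    """
    wset = tree.w_bearing_set
    if len(wset) < 2:
        raise TreeError("enumerate_multi_w needs at least 2 w-bearing species")
    # the w-bearing set must sit inside one clade (not span the root)
    root_children = tree.tree.seed_node.child_nodes()
    sides = [
        frozenset(l.taxon.label for l in c.leaf_iter()) & wset for c in root_children
    ]
    if sum(1 for s in sides if s) > 1:
        raise TreeError("w_bearing_set spans the root; unsupported")
    path = tree.focal_path()
    nested = tree.nested()
    path_clades = [frozenset([tree.focal_species])] + [
        frozenset(l.taxon.label for l in n.leaf_iter()) for n in path.nodes
    ]

    def own_sisters(topo, species_set):
        """Replace each listed species tip by (tip, tip_W)."""
        def rec(n):
            if isinstance(n, str):
                return (n, w_label(n)) if n in species_set else n
            return tuple(rec(c) for c in n)

        return rec(topo)

    required = tree.tips + [w_label(s) for s in sorted(wset)]
    topologies, descriptions = [], []
    S = len(path) if exclude_above_root else len(path) + 1
    for k in range(1, S + 1):
        if k == 1:
            topo = own_sisters(nested, wset)
        else:
            below = path_clades[k - 1] & wset if k <= len(path) + 0 else wset
            # mirror clade of the w-bearing species that split after point k
            mirror = _nested_restrict(nested, below)
            mirror = _nested_relabel(mirror, w_label)
            if k <= len(path):
                topo = _graft_on_path(nested, path_clades, k, mirror)
            else:  # above-root attachment
                topo = (nested, mirror)
            topo = own_sisters(topo, wset - below)
        _check_emitted(topo, required)
        topologies.append(topo)
        descriptions.append(_describe(tree, path, k))
    return ScenarioSet(tree, topologies, kind="multi", descriptions=descriptions)


def _describe(tree: SpeciesTree, path: FocalPath, k: int) -> str:
    lo, hi = _interval_ages(path, k)
    if k == 1:
        return (
            f"cessation after the most recent speciation of {tree.focal_species} "
            f"(0 < t_RC <= {hi:g})"
        )
    return f"cessation between path nodes {k-1} and {k} ({lo:g} < t_RC <= {hi:g})"


def _interval_ages(path: FocalPath, k: int):
    lo = 0.0 if k == 1 else float(path.ages[k - 2])
    hi = float(path.ages[k - 1]) if k <= len(path) else np.inf
    return lo, hi


def scenario_to_time_interval(k: int, tree: SpeciesTree):
    """Half-open interval of normalized time (fraction of root age) covered
    by scenario ``k``: (h_{k-1}/h_root, h_k/h_root], with h_0 = 0.

    The intervals over k = 1..S partition (0, 1]; their boundary set has
    exactly S + 1 distinct values when node ages are distinct.
    """
    path = tree.focal_path()
    S = len(path)
    if not 1 <= k <= S:
        raise TreeError(f"scenario index {k} outside 1..{S}")
    H = tree.root_age
    if H <= 0:
        raise TreeError("missing or zero node ages")
    lo, hi = _interval_ages(path, k)
    return (lo / H, hi / H)


def time_to_scenario(t: float, tree: SpeciesTree) -> int:
    """Scenario index whose time interval contains absolute age ``t``."""
    path = tree.focal_path()
    if not 0 < t <= tree.root_age + 1e-12:
        raise TreeError("t outside (0, root age]")
    for k in range(1, len(path) + 1):
        lo, hi = _interval_ages(path, k)
        if lo < t <= hi:
            return k
    return len(path)
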