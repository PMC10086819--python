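"""Bundled 13-species reference topology for the Sylvioidea neo-sex system.

The topology covers six Sylvioidea species (nested pectinately around the
focal great reed warbler), five further Neognath outgroups, one Paleognath
and one reptile.  Node ages are a synthetic fixture: representative
divergence times (in Myr) assembled from published-style dates for these
clades, intended for simulation and testing rather than biological
inference.
"""

from __future__ import annotations

from .trees import SpeciesTree

__all__ = [
    "SYLVIOIDEA",
    "FOCAL_SPECIES",
    "REFERENCE_NEWICK",
    "reference_species_tree",
]

#: the six Sylvioidea species, focal first, in order of increasing split age
SYLVIOIDEA = (
    "A_arundinaceus",
    "A_stentoreus",
    "A_palustris",
    "I_opaca",
    "L_luscinioides",
    "P_biarmicus",
)

FOCAL_SPECIES = "A_arundinaceus"

#: species on the focal-to-root path beyond Sylvioidea, nearest first
OUTGROUP_LADDER = (
    "P_major",
    "T_guttata",
    "L_coronata",
    "M_undulatus",
    "G_gallus",
    "D_novaehollandiae",
    "A_carolinensis",
)

# ages (Myr) of the successive focal-path nodes, tip-to-root
_PATH_AGES = (4.0, 6.0, 7.0, 17.0, 22.0, 30.0, 39.0, 52.0, 65.0, 90.0, 110.0, 312.0)


def _ladder_newick() -> str:
    species = list(SYLVIOIDEA) + list(OUTGROUP_LADDER)
    ages = _PATH_AGES
    # fully pectinate: ((((A,B):h1,C):h2,...)
    node = f"({species[0]}:{ages[0]},{species[1]}:{ages[0]})"
    for i in range(2, len(species)):
        h_prev, h = ages[i - 2], ages[i - 1]
        node = f"({node}:{h - h_prev},{species[i]}:{h})"
    return node + ";"


REFERENCE_NEWICK = _ladder_newick()


def reference_species_tree(multi_w: bool = False) -> SpeciesTree:
    """The dated 13-species reference tree with the great reed warbler as
    focal species.

    With ``multi_w=True`` all six Sylvioidea species are marked as
    contributing W gametologs; otherwise only the focal species is.
    """
    w_bearing = SYLVIOIDEA if multi_w else None
    return SpeciesTree(REFERENCE_NEWICK, FOCAL_SPECIES, w_bearing=w_bearing)
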