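"""Pairwise synonymous divergence between gametologs (NG86 counting).

Synonymous substitutions accumulate roughly clock-like, so the synonymous
rate dS between the Z and W copies of a gene is a classic proxy for the
time since they stopped recombining.  This module implements the
Nei–Gojobori (1986) counting estimator: per-codon synonymous and
nonsynonymous site counts, difference counts averaged over all minimal
substitution pathways between differing codons (pathways through stop
codons excluded), and a Jukes–Cantor multiple-hit correction.

Conventions: the standard genetic code only; codon columns containing a
gap, an ambiguity code or a stop codon are excluded from all counts;
mutations to stop codons count as nonsynonymous in the site tally.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

from .seqmodels import Alignment

__all__ = ["CodonAlignment", "DsResult", "ng86_ds", "extract_focal_pair"]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
AA = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"


class CodingError(ValueError):
    pass


def _is_clean(codon: str) -> bool:
    return all(c in _BASES for c in codon) and codon not in STOP_CODONS


class CodonAlignment:
    """Aligned coding sequences split into countable codon columns.

    Length must be divisible by 3 with the reading frame at position 1.
    Codon columns where any sequence has a gap, an ambiguous base or a
    stop codon are dropped (``n_dropped`` records how many).
    """

    def __init__(self, labels, sequences):
        labels = list(labels)
        sequences = [str(s).upper().replace("U", "T") for s in sequences]
        if len({len(s) for s in sequences}) != 1:
            raise CodingError("sequences have unequal lengths")
        L = len(sequences[0])
        if L % 3:
            raise CodingError(f"length {L} not divisible by 3; frame cannot be established")
        self.labels = labels
        cols = []
        dropped = 0
        for i in range(0, L, 3):
            codons = tuple(s[i:i + 3] for s in sequences)
            if all(_is_clean(c) for c in codons):
                cols.append(codons)
            else:
                dropped += 1
        self.codon_columns = cols
        self.n_dropped = dropped

    @property
    def n_codons(self) -> int:
        return len(self.codon_columns)

    def pair(self, i: int = 0, j: int = 1):
        return [(col[i], col[j]) for col in self.codon_columns]


@dataclass
class DsResult:
    """NG86 estimates for one sequence pair."""

    ds: float
    dn: float
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    saturated: bool

    def as_row(self, gene_id: str = "") -> dict:
        return {"gene_id": gene_id, "dS": self.ds, "dN": self.dn,
                "S_sites": self.s_sites, "N_sites": self.n_sites,
                "saturated": self.saturated}


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon: at each
    position, the fraction of the three possible changes that are
    synonymous (changes to stop codons count as nonsynonymous)."""
    syn = 0.0
    aa = AA[codon]
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and AA[alt] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged over all orderings of the single-base steps; orderings that
    pass through a stop codon are excluded (all orderings are used if
    every one is blocked)."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if AA[cur] == AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # every ordering passes through a stop; fall back to counting
        for order in permutations(diff):
            cur = c1
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                same = nxt not in STOP_CODONS and cur not in STOP_CODONS \
                    and AA.get(cur) == AA.get(nxt)
                sd += 1 if same else 0
                nd += 0 if same else 1
                cur = nxt
            paths.append((sd, nd))
    sds, nds = zip(*paths)
    return float(np.mean(sds)), float(np.mean(nds))


def _jc(p: float) -> float:
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ng86_ds(pair: CodonAlignment) -> DsResult:
    """NG86 dS/dN for the first two sequences of a codon alignment.

    Site counts are averaged over the two sequences; proportions are
    Jukes–Cantor corrected.  A synonymous proportion >= 3/4 sets the
    ``saturated`` flag and leaves dS undefined (NaN); same for dN.
    """
    if len(pair.labels) < 2:
        raise CodingError("need two sequences")
    if pair.n_codons == 0:
        raise CodingError("no countable codons")
    S = N = Sd = Nd = 0.0
    for c1, c2 in pair.pair(0, 1):
        s1, n1 = codon_site_counts(c1)
        s2, n2 = codon_site_counts(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    saturated = ps >= 0.75 or pn >= 0.75
    ds = _jc(ps) if ps < 0.75 else float("nan")
    dn = _jc(pn) if pn < 0.75 else float("nan")
    return DsResult(ds=float(ds), dn=float(dn), s_sites=S, n_sites=N,
                    sd=Sd, nd=Nd, saturated=saturated)


def extract_focal_pair(aln: Alignment, z_label: str, w_label: str) -> CodonAlignment:
    """Two-sequence codon alignment of the focal Z and W gametologs; codon
    columns with a gap/ambiguity in either sequence are excluded."""
    for lab in (z_label, w_label):
        if lab not in aln:
            raise CodingError(f"label {lab!r} not in alignment")
    z = aln.sequences[aln.index(z_label)]
    w = aln.sequences[aln.index(w_label)]
    return CodonAlignment([z_label, w_label], [z, w])
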