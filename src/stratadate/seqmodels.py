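"""Nucleotide substitution models and tree likelihood on fixed topologies.

Implements the reversible GTR family (JC69, K80, HKY85, TN93, GTR) with
discrete-gamma rate variation and a proportion of invariant sites, per-site
log-likelihood computation by the pruning algorithm, and maximum-likelihood
branch-length / model-parameter fitting on a fixed topology.

Conventions
-----------
* States are ordered A, C, G, T.
* The rate matrix is scaled so branch lengths are expected substitutions
  per site at equilibrium (mean rate 1).
* With a proportion of invariant sites ``pinv``, the gamma category rates
  are divided by ``1 - pinv`` so the overall mean rate stays 1.
* Gaps and ambiguity codes are missing data: a tip's partial likelihood is
  1 for every compatible state.
* No numerical rescaling of partials is performed; at desk scale (tens of
  tips, divergences well below saturation) double precision suffices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from Bio import SeqIO
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "Alignment",
    "SubstitutionModel",
    "TreeLikelihood",
    "site_log_likelihoods",
    "optimize_branch_lengths",
    "fit_model",
    "empirical_base_frequencies",
]

BASES = "ACGT"

# IUPAC nucleotide codes as 4-bit masks over (A, C, G, T)
_MASKS = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000, "U": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001, "K": 0b1100,
    "M": 0b0011, "B": 0b1110, "D": 0b1101, "H": 0b1011, "V": 0b0111,
    "N": 0b1111, "-": 0b1111, "?": 0b1111, ".": 0b1111, "X": 0b1111,
}

MIN_BRANCH_LENGTH = 1e-9


class AlignmentError(ValueError):
    pass


class Alignment:
    """A multiple sequence alignment over nucleotides.

    Stores the raw (upper-cased) sequences plus a 4-bit compatibility mask
    per cell.  Case-insensitive; '-', '?', 'N' and the IUPAC ambiguity
    codes are accepted and treated as (partially) missing.
    """

    def __init__(self, labels, sequences):
        labels = list(labels)
        sequences = [str(s).upper() for s in sequences]
        if len(labels) != len(sequences):
            raise AlignmentError("labels and sequences differ in number")
        if len(labels) != len(set(labels)):
            raise AlignmentError("duplicate sequence labels")
        if not sequences or len(sequences[0]) == 0:
            raise AlignmentError("empty alignment")
        L = len(sequences[0])
        if any(len(s) != L for s in sequences):
            raise AlignmentError("sequences have unequal lengths")
        self.labels = labels
        self.sequences = sequences
        masks = np.empty((len(labels), L), dtype=np.uint8)
        for i, seq in enumerate(sequences):
            try:
                masks[i] = [_MASKS[c] for c in seq]
            except KeyError as exc:
                raise AlignmentError(
                    f"unknown character {exc} in sequence {labels[i]!r}"
                ) from exc
        self.masks = masks

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return self.masks.shape[1]

    def __contains__(self, label) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise AlignmentError(f"taxon {label!r} not in alignment") from None

    def subset(self, labels) -> "Alignment":
        return Alignment(list(labels), [self.sequences[self.index(l)] for l in labels])

    # -- FASTA I/O ----------------------------------------------------------

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no FASTA records in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, seq in zip(self.labels, self.sequences):
                fh.write(f">{label}\n{seq}\n")

    def tip_partials(self, label: str) -> np.ndarray:
        """(4, L) array of 0/1 state compatibilities for one taxon."""
        m = self.masks[self.index(label)]
        return np.stack([(m >> b) & 1 for b in range(4)]).astype(float)


def empirical_base_frequencies(aln: Alignment, pseudocount: float = 1.0) -> np.ndarray:
    """Base frequencies from unambiguous characters, with a pseudocount so
    every frequency is strictly positive."""
    counts = np.full(4, pseudocount, dtype=float)
    for b, mask in enumerate((1, 2, 4, 8)):
        counts[b] += np.count_nonzero(aln.masks == mask)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------

_FAMILIES = ("JC69", "K80", "HKY85", "TN93", "GTR")


@dataclass
class SubstitutionModel:
    """A reversible nucleotide substitution model with +G and +I options.

    ``kappa`` is the transition/transversion rate ratio (HKY85, K80);
    ``kappa1``/``kappa2`` are the purine (A-G) and pyrimidine (C-T)
    transition rates of TN93; ``exch`` the six GTR exchangeabilities in
    order AC, AG, AT, CG, CT, GT (GT fixed to 1 when optimized).
    ``alpha=None`` disables gamma rate variation; ``ncat`` is the number of
    discrete gamma categories.
    """

    family: str = "HKY85"
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    kappa: float = 2.0
    kappa1: float = 2.0
    kappa2: float = 2.0
    exch: np.ndarray = field(default_factory=lambda: np.ones(6))
    alpha: float | None = None
    ncat: int = 4
    pinv: float = 0.0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; use one of {_FAMILIES}")
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (4,) or np.any(self.pi <= 0):
            raise ValueError("pi must be a positive 4-vector")
        self.pi = self.pi / self.pi.sum()
        if not 0 <= self.pinv < 1:
            raise ValueError("pinv must lie in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape alpha must be > 0")
        if self.family in ("JC69", "K80"):
            self.pi = np.full(4, 0.25)
        self._eig = None
        self._crw = None

    # -- rate matrix ---------------------------------------------------------

    def exchangeabilities(self) -> np.ndarray:
        """Symmetric exchangeability matrix s with zero diagonal."""
        s = np.zeros((4, 4))
        if self.family == "JC69":
            s[:] = 1.0
        elif self.family in ("K80", "HKY85"):
            s[:] = 1.0
            s[0, 2] = s[2, 0] = self.kappa  # A<->G
            s[1, 3] = s[3, 1] = self.kappa  # C<->T
        elif self.family == "TN93":
            s[:] = 1.0
            s[0, 2] = s[2, 0] = self.kappa1
            s[1, 3] = s[3, 1] = self.kappa2
        else:  # GTR
            ac, ag, at, cg, ct, gt = np.asarray(self.exch, dtype=float)
            s[0, 1] = s[1, 0] = ac
            s[0, 2] = s[2, 0] = ag
            s[0, 3] = s[3, 0] = at
            s[1, 2] = s[2, 1] = cg
            s[1, 3] = s[3, 1] = ct
            s[2, 3] = s[3, 2] = gt
        np.fill_diagonal(s, 0.0)
        return s

    def q_matrix(self) -> np.ndarray:
        """Rate matrix Q with rows summing to 0, pi-stationary, scaled to
        one expected substitution per site per unit branch length."""
        s = self.exchangeabilities()
        q = s * self.pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(self.pi, np.diag(q))
        return q / mu

    def eigensystem(self):
        """Cached symmetric eigendecomposition of Q (reversible models):
        returns (lam, left, right) with P(t) = left @ diag(exp(lam t)) @ right."""
        if self._eig is None:
            q = self.q_matrix()
            sq = np.sqrt(self.pi)
            sym = (q * sq[:, None]) / sq[None, :]
            lam, vec = np.linalg.eigh((sym + sym.T) / 2)
            left = vec / sq[:, None]
            right = vec.T * sq[None, :]
            self._eig = (lam, left, right)
        return self._eig

    def category_rates_weights(self):
        """Discrete-gamma category rates (mean of each quantile bin, Yang
        1994 style) rescaled by 1/(1-pinv), with equal weights."""
        if self._crw is not None:
            return self._crw
        if self.alpha is None or self.ncat == 1:
            rates = np.array([1.0])
        else:
            k, a = self.ncat, self.alpha
            edges = _gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
            upper = np.concatenate([gammainc(a + 1, edges * a), [1.0]])
            lower = np.concatenate([[0.0], gammainc(a + 1, edges * a)])
            rates = k * (upper - lower)
        rates = rates / (1.0 - self.pinv)
        weights = np.full(rates.size, 1.0 / rates.size)
        self._crw = (rates, weights)
        return self._crw

    def pmats(self, branch_lengths: np.ndarray) -> np.ndarray:
        """(n_branches, ncat, 4, 4) transition matrices for the category
        rates of this model."""
        lam, left, right = self.eigensystem()
        rates, _ = self.category_rates_weights()
        b = np.asarray(branch_lengths, dtype=float)
        expo = np.exp(lam[None, None, :] * (b[:, None, None] * rates[None, :, None]))
        p = np.einsum("xk,nck,ky->ncxy", left, expo, right)
        return np.clip(p, 0.0, None)

    def copy(self, **changes) -> "SubstitutionModel":
        return replace(self, **changes)

    # -- structured-text serialization --------------------------------------

    def to_config(self) -> dict:
        """JSON-serializable parameter dictionary."""
        return {
            "family": self.family,
            "pi": [float(x) for x in self.pi],
            "kappa": self.kappa,
            "kappa1": self.kappa1,
            "kappa2": self.kappa2,
            "exch": [float(x) for x in np.asarray(self.exch, dtype=float)],
            "alpha": self.alpha,
            "ncat": self.ncat,
            "pinv": self.pinv,
        }

    @classmethod
    def from_config(cls, config: dict) -> "SubstitutionModel":
        return cls(**config)

    def free_parameters(self) -> list[str]:
        """Names of rate-type parameters optimized by :func:`fit_model`."""
        names = {
            "JC69": [],
            "K80": ["kappa"],
            "HKY85": ["kappa"],
            "TN93": ["kappa1", "kappa2"],
            "GTR": ["exch0", "exch1", "exch2", "exch3", "exch4"],
        }[self.family]
        if self.alpha is not None:
            names = names + ["alpha"]
        return names


# ---------------------------------------------------------------------------
# Tree likelihood
# ---------------------------------------------------------------------------

class TreeLikelihood:
    """Pruning-algorithm likelihood of an alignment on a fixed topology.

    Site patterns are compressed once at construction.  Branch lengths are
    taken from the tree's edges where present, otherwise initialised to
    ``default_blen``.  The engine supports multifurcations.
    """

    def __init__(self, tree: dendropy.Tree, aln: Alignment, model: SubstitutionModel,
                 default_blen: float = 0.05):
        self.model = model
        self.aln = aln
        self._index_tree(tree, default_blen)
        self._compress(aln)
        self._post = None  # (n_nodes, ncat, 4, npat)
        self._pre = None

    # -- setup ---------------------------------------------------------------

    def _index_tree(self, tree, default_blen):
        self.tree = tree
        nodes = list(tree.postorder_node_iter())
        self.nodes = nodes
        self.n_nodes = len(nodes)
        self.node_index = {id(n): i for i, n in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.blens = np.zeros(self.n_nodes)  # edge above each node; root unused
        self.tip_rows: list[tuple[int, str]] = []
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                p = self.node_index[id(n.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                el = n.edge.length
                self.blens[i] = max(float(el) if el is not None else default_blen,
                                    MIN_BRANCH_LENGTH)
            if n.is_leaf():
                label = n.taxon.label if n.taxon is not None else n.label
                self.tip_rows.append((i, label))
        self.root = self.n_nodes - 1
        self.free_edges = np.array([i for i in range(self.n_nodes) if i != self.root])

    def _compress(self, aln):
        labels = [lab for _, lab in self.tip_rows]
        for lab in labels:
            if lab not in aln:
                raise AlignmentError(f"tree taxon {lab!r} absent from alignment")
        sub = np.stack([aln.masks[aln.index(lab)] for lab in labels])
        patterns, inverse, counts = np.unique(
            sub, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (ntips_in_tree, npat)
        self.pattern_of_site = inverse.ravel()
        self.weights = counts.astype(float)
        self.npat = patterns.shape[1]
        # 0/1 tip partials (per tree tip): (4, npat)
        self.tip_partials = {}
        for row, (i, lab) in enumerate(self.tip_rows):
            m = patterns[row]
            self.tip_partials[i] = np.stack(
                [((m >> b) & 1).astype(float) for b in range(4)]
            )
        # invariant-site likelihood per pattern
        prod = np.ones((4, self.npat))
        for i, _ in self.tip_rows:
            prod *= self.tip_partials[i]
        self._inv_lik = self.model.pi @ prod

    # -- core computation ----------------------------------------------------

    def _pmats(self, blens=None):
        b = self.blens if blens is None else blens
        return self.model.pmats(b)

    def _compute_post(self):
        ncat = self.model.category_rates_weights()[0].size
        P = self._pmats()
        post = np.empty((self.n_nodes, ncat, 4, self.npat))
        for i, n in enumerate(self.nodes):
            if not self.children[i]:
                post[i] = self.tip_partials[i][None, :, :]
            else:
                acc = None
                for c in self.children[i]:
                    m = np.matmul(P[c], post[c])
                    acc = m if acc is None else acc * m
                post[i] = acc
        self._post = post
        self._P = P
        return post

    def _site_lik_from_rootvals(self, rootvals):
        """Mix gamma categories and the invariant class; rootvals (ncat, npat)."""
        _, w = self.model.category_rates_weights()
        lik = np.tensordot(w, rootvals, axes=(0, 0))
        pinv = self.model.pinv
        if pinv > 0:
            lik = (1.0 - pinv) * lik + pinv * self._inv_lik
        return lik

    def pattern_log_likelihoods(self) -> np.ndarray:
        post = self._compute_post()
        rootvals = np.einsum("x,cxp->cp", self.model.pi, post[self.root])
        lik = self._site_lik_from_rootvals(rootvals)
        if np.any(lik <= 0) or not np.all(np.isfinite(lik)):
            bad = int(np.flatnonzero((lik <= 0) | ~np.isfinite(lik))[0])
            site = int(np.flatnonzero(self.pattern_of_site == bad)[0])
            raise FloatingPointError(f"non-finite site likelihood at site {site}")
        return np.log(lik)

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-site log-likelihood vector in original site order."""
        return self.pattern_log_likelihoods()[self.pattern_of_site]

    def lnl(self) -> float:
        return float(self.weights @ self.pattern_log_likelihoods())

    # -- pre-order ("outside") partials for fast per-branch optimization ----

    def _compute_pre(self):
        """pre[v][y] = P(all data outside subtree(v) | state y at parent(v)),
        with the root prior folded in."""
        post, P = self._post, self._P
        ncat = post.shape[1]
        pre = np.empty_like(post)
        pre[self.root] = np.nan  # undefined
        order = list(range(self.n_nodes - 1, -1, -1))  # preorder (root first)
        M = {}

        def child_msg(c):
            if c not in M:
                M[c] = np.matmul(P[c], post[c])
            return M[c]

        for i in order:
            kids = self.children[i]
            if not kids:
                continue
            if i == self.root:
                base = np.broadcast_to(
                    self.model.pi[None, :, None], post[i].shape
                ).copy()
            else:
                # B_i[y] = sum_z pre[i][z] P_i(z, y)
                base = np.matmul(P[i].transpose(0, 2, 1), pre[i])
            for v in kids:
                acc = base
                for s in kids:
                    if s != v:
                        acc = acc * child_msg(s)
                pre[v] = acc
        self._pre = pre

    def _branch_lnl(self, v: int, t: float) -> float:
        """Total lnL as a function of the length of the edge above node v,
        holding all cached partials fixed."""
        P = self.model.pmats(np.array([t]))[0]
        tmp = np.matmul(P.transpose(0, 2, 1), self._pre[v])
        rootvals = np.sum(tmp * self._post[v], axis=1)
        lik = self._site_lik_from_rootvals(rootvals)
        with np.errstate(divide="ignore"):
            return float(self.weights @ np.log(lik))

    # -- optimization --------------------------------------------------------

    def optimize_branches(self, tol: float = 1e-8, max_sweeps: int = 20,
                          xatol: float = 1e-4, max_blen: float = 20.0):
        """Round-robin Brent optimization of every branch on the log scale.

        Iterates sweeps until the relative lnL improvement drops below
        ``tol``.  Returns (lnL, converged).  The returned lnL is never
        below the starting lnL (the best-visited branch vector is kept).
        """
        lo, hi = np.log(MIN_BRANCH_LENGTH), np.log(max_blen)
        best_lnl = self.lnl()
        best_b = self.blens.copy()
        converged = False
        for _ in range(max_sweeps):
            prev_b = self.blens.copy()
            self._compute_post()
            self._compute_pre()
            for v in self.free_edges:
                res = minimize_scalar(
                    lambda u: -self._branch_lnl(v, np.exp(u)),
                    bounds=(lo, hi), method="bounded", options={"xatol": xatol},
                )
                self.blens[v] = float(np.exp(res.x))
            cur = self.lnl()
            if cur < best_lnl - 1e-9 * max(1.0, abs(best_lnl)):
                # stale-partial sweep hurt: fall back to exact per-branch pass
                self.blens = best_b.copy()
                cur = self._safe_sweep(lo, hi, xatol)
            moved = float(np.max(np.abs(
                np.log(np.maximum(self.blens[self.free_edges], MIN_BRANCH_LENGTH))
                - np.log(np.maximum(prev_b[self.free_edges], MIN_BRANCH_LENGTH)))))
            improved = cur - best_lnl
            if cur > best_lnl:
                best_b = self.blens.copy()
                best_lnl = cur
            if improved < tol * max(1.0, abs(best_lnl)):
                if moved > 10 * xatol:
                    # lnL flat but branches still crawling (stale partials):
                    # one exact sweep decides between stall and convergence
                    cur = self._safe_sweep(lo, hi, xatol)
                    if cur > best_lnl + tol * max(1.0, abs(best_lnl)):
                        best_b = self.blens.copy()
                        best_lnl = cur
                        continue
                    if cur > best_lnl:
                        best_b = self.blens.copy()
                        best_lnl = cur
                converged = True
                break
        if not converged:
            # sweep budget exhausted while still moving: polish with exact
            # (recompute-per-branch) coordinate ascent, which cannot stall
            self.blens = best_b.copy()
            for _ in range(5):
                cur = self._safe_sweep(lo, hi, xatol)
                improved = cur - best_lnl
                if cur > best_lnl:
                    best_b = self.blens.copy()
                    best_lnl = cur
                if improved < tol * max(1.0, abs(best_lnl)):
                    converged = True
                    break
        self.blens = best_b
        return best_lnl, converged

    def _safe_sweep(self, lo, hi, xatol):
        for v in self.free_edges:
            self._compute_post()
            self._compute_pre()
            res = minimize_scalar(
                lambda u: -self._branch_lnl(v, np.exp(u)),
                bounds=(lo, hi), method="bounded", options={"xatol": xatol},
            )
            self.blens[v] = float(np.exp(res.x))
        return self.lnl()

    def write_lengths_to_tree(self):
        for i, n in enumerate(self.nodes):
            if i != self.root:
                n.edge.length = float(self.blens[i])
        return self.tree


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def site_log_likelihoods(aln: Alignment, tree: dendropy.Tree,
                         model: SubstitutionModel) -> np.ndarray:
    """Per-site log-likelihoods of ``aln`` on ``tree`` (branch lengths from
    the tree's edges) under ``model``.  The sum is the total lnL."""
    return TreeLikelihood(tree, aln, model).site_log_likelihoods()


def optimize_branch_lengths(aln: Alignment, topology: dendropy.Tree,
                            model: SubstitutionModel, optimize_model: bool = False,
                            tol: float = 1e-8, max_sweeps: int = 20,
                            xatol: float = 1e-4):
    """ML branch lengths (and optionally model parameters) on a fixed topology.

    Returns ``(tree, lnl, model)``; the input tree's edge lengths are
    updated in place.  With ``optimize_model=True`` the model's rate
    parameters (and gamma shape / pinv when enabled) are optimized jointly
    with the branches by coordinate ascent.
    """
    engine = TreeLikelihood(topology, aln, model)
    if not optimize_model:
        lnl, _ = engine.optimize_branches(tol=tol, max_sweeps=max_sweeps, xatol=xatol)
        return engine.write_lengths_to_tree(), lnl, engine.model
    lnl = -np.inf
    for _round in range(6):
        cur, _ = engine.optimize_branches(tol=tol, max_sweeps=max_sweeps, xatol=xatol)
        cur, engine = _optimize_model_params(engine)
        if cur - lnl < 1e-6 * max(1.0, abs(cur)):
            lnl = cur
            break
        lnl = cur
    return engine.write_lengths_to_tree(), lnl, engine.model


def _model_with_param(model, name, value):
    if name.startswith("exch"):
        exch = np.array(model.exch, dtype=float).copy()
        exch[int(name[4])] = value
        return model.copy(exch=exch)
    return model.copy(**{name: value})


def _optimize_model_params(engine: TreeLikelihood):
    """Brent over each free rate-type parameter (log scale) and pinv."""
    aln, model = engine.aln, engine.model

    def rebuilt(m):
        e = TreeLikelihood(engine.tree, aln, m)
        e.blens = engine.blens.copy()
        return e

    for name in model.free_parameters():
        def obj(u):
            return -rebuilt(_model_with_param(model, name, np.exp(u))).lnl()

        res = minimize_scalar(obj, bounds=(np.log(0.02), np.log(100.0)),
                              method="bounded", options={"xatol": 1e-3})
        model = _model_with_param(model, name, float(np.exp(res.x)))
    if model.pinv > 0 or getattr(model, "_fit_pinv", False):
        res = minimize_scalar(
            lambda p: -rebuilt(model.copy(pinv=p)).lnl(),
            bounds=(0.0, 0.9), method="bounded", options={"xatol": 1e-3},
        )
        model = model.copy(pinv=float(res.x))
    new = rebuilt(model)
    return new.lnl(), new


def fit_model(aln: Alignment, topology: dendropy.Tree, family: str = "HKY85",
              gamma: bool = False, ncat: int = 4, fit_pinv: bool = False) -> SubstitutionModel:
    """Fit a substitution model on a fixed topology.

    Base frequencies are empirical; exchangeabilities, gamma shape and the
    invariant proportion are optimized jointly with branch lengths.  A
    degenerate alignment (all sequences identical over unambiguous sites)
    returns the default parameters with a warning.
    """
    pi = empirical_base_frequencies(aln)
    model = SubstitutionModel(family=family, pi=pi,
                              alpha=1.0 if gamma else None, ncat=ncat,
                              pinv=0.01 if fit_pinv else 0.0)
    object.__setattr__(model, "_fit_pinv", fit_pinv)
    distinct = {s for s in aln.sequences}
    if len(distinct) == 1:
        warnings.warn("degenerate alignment (single distinct sequence); "
                      "returning default model parameters")
        return model
    _, _, fitted = optimize_branch_lengths(aln, topology, model, optimize_model=True,
                                           tol=1e-7, max_sweeps=8)
    return fitted
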