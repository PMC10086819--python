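"""Simplified Bayesian node dating of the focal Z–W divergence.

A Metropolis-within-Gibbs sampler on a *fixed* gametolog topology (the
reference species topology with the focal W tip at its hypothesised
attachment): node ages move within the parent/child ordering constraints,
calibration priors constrain every species node, and the focal Z–W
divergence node — the quantity of interest — carries no calibration.  The
clock is either strict (one rate) or uncorrelated-lognormal relaxed
(per-branch rate multipliers with mean 1 and a sampled spread).  Output
is a posterior trace of the focal age from which the posterior median and
95% highest-posterior-density (HPD) interval are summarised, optionally
normalized by the root age to the 0–1 t_RC scale.

There is no tree prior beyond the calibrations and the ordering
constraint (uncalibrated node ages are uniform within their bounds);
with the topology fixed this is a proper, if deliberately weak, prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import lognorm, norm

from .seqmodels import Alignment, SubstitutionModel, TreeLikelihood
from .trees import SpeciesTree, TreeError, parse_newick, w_label

__all__ = [
    "CalibrationPrior",
    "DatingConfig",
    "PosteriorTrace",
    "DatingResult",
    "run_dating_mcmc",
    "summarize_trace",
    "hpd_interval",
    "ess",
    "reduce_outgroups",
    "default_calibrations",
]


# ---------------------------------------------------------------------------
# Priors and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationPrior:
    """A proper age prior on the node defined as the MRCA of ``taxa``.

    ``dist`` is one of ``normal`` (mean, sd; truncated to age > 0),
    ``lognormal`` (meanlog, sdlog) or ``uniform`` (lo, hi).
    """

    taxa: frozenset
    dist: str
    params: tuple

    def __post_init__(self):
        if self.dist not in ("normal", "lognormal", "uniform"):
            raise ValueError(f"unknown calibration distribution {self.dist!r}")
        object.__setattr__(self, "taxa", frozenset(self.taxa))

    def logpdf(self, age: float) -> float:
        if age <= 0:
            return -np.inf
        if self.dist == "normal":
            mean, sd = self.params
            return float(norm.logpdf(age, mean, sd))
        if self.dist == "lognormal":
            meanlog, sdlog = self.params
            return float(lognorm.logpdf(age, sdlog, scale=np.exp(meanlog)))
        lo, hi = self.params
        return 0.0 - np.log(hi - lo) if lo <= age <= hi else -np.inf

    def sample(self, rng) -> float:
        if self.dist == "normal":
            mean, sd = self.params
            return abs(float(rng.normal(mean, sd)))
        if self.dist == "lognormal":
            meanlog, sdlog = self.params
            return float(np.exp(rng.normal(meanlog, sdlog)))
        lo, hi = self.params
        return float(rng.uniform(lo, hi))


@dataclass
class DatingConfig:
    """MCMC settings.  Desk-scale defaults (a 2e5-state chain sampled every
    100) rather than production-scale ones; both are reachable here."""

    chain_length: int = 200_000
    sample_interval: int = 100
    pre_burnin: int = 10_000
    clock: str = "strict"  # "strict" | "ucln"
    seed: int | None = None
    rate_bounds: tuple = (1e-8, 10.0)
    sample_substitution: bool = True
    #: optional hard upper bound on the root age (makes the otherwise flat
    #: root prior proper when no calibration sits above the focal node)
    max_root_age: float | None = None

    def __post_init__(self):
        if not self.chain_length >= self.sample_interval >= 1:
            raise ValueError("need chain_length >= sample_interval >= 1")
        if self.pre_burnin < 0:
            raise ValueError("pre_burnin must be >= 0")
        if self.clock not in ("strict", "ucln"):
            raise ValueError("clock must be 'strict' or 'ucln'")


@dataclass
class PosteriorTrace:
    """Sampled chain states (one row per retained sample)."""

    data: pd.DataFrame
    config: DatingConfig

    def __len__(self) -> int:
        return len(self.data)

    @property
    def focal_ages(self) -> np.ndarray:
        return self.data["focal_age"].to_numpy()

    @property
    def root_ages(self) -> np.ndarray:
        return self.data["root_age"].to_numpy()

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class DatingResult:
    median: float
    hpd_lo: float
    hpd_hi: float
    ess: float
    normalized: bool

    @property
    def hpd_width(self) -> float:
        return self.hpd_hi - self.hpd_lo

    def as_row(self, gene_id: str = "") -> dict:
        return {"gene_id": gene_id, "median": self.median, "hpd_lo": self.hpd_lo,
                "hpd_hi": self.hpd_hi, "width": self.hpd_width, "ESS": self.ess}


# ---------------------------------------------------------------------------
# Incremental pruning (partials cached, ancestors-only updates)
# ---------------------------------------------------------------------------

class _Pruning:
    """Pruning likelihood with per-node partial caching so that a proposal
    touching a few branches only recomputes the path to the root."""

    def __init__(self, tree, aln, model):
        self.tl = TreeLikelihood(tree, aln, model)
        self.model = model
        self.blens = self.tl.blens.copy()
        self._full()

    def rebuild_model(self, model):
        self.model = model
        self.tl.model = model
        # invariant-site class depends only on pi, which is fixed
        self._full()

    def _full(self):
        self.tl.blens = self.blens
        self.P = self.tl._pmats(self.blens)
        tl = self.tl
        ncat = self.P.shape[1]
        post = np.empty((tl.n_nodes, ncat, 4, tl.npat))
        for i in range(tl.n_nodes):
            if not tl.children[i]:
                post[i] = tl.tip_partials[i][None]
            else:
                acc = None
                for c in tl.children[i]:
                    m = np.matmul(self.P[c], post[c])
                    acc = m if acc is None else acc * m
                post[i] = acc
        self.post = post
        self.lnl = self._root_lnl(post[tl.root])

    def _root_lnl(self, root_partial):
        tl = self.tl
        rootvals = np.einsum("x,cxp->cp", self.model.pi, root_partial)
        lik = tl._site_lik_from_rootvals(rootvals)
        if np.any(lik <= 0):
            return -np.inf
        return float(tl.weights @ np.log(lik))

    def propose(self, new_blens: dict):
        """lnL if the edges above the given nodes take the given lengths."""
        tl = self.tl
        items = list(new_blens.items())
        Ps = self.model.pmats(np.array([b for _, b in items]))
        P_new = {i: Ps[j] for j, (i, _) in enumerate(items)}
        recomputed = {}
        dirty = set(new_blens)
        for j in range(tl.n_nodes):
            kids = tl.children[j]
            if kids and any((c in dirty) or (c in recomputed) for c in kids):
                acc = None
                for c in kids:
                    P = P_new.get(c, self.P[c])
                    m = np.matmul(P, recomputed.get(c, self.post[c]))
                    acc = m if acc is None else acc * m
                recomputed[j] = acc
        lnl = self._root_lnl(recomputed.get(tl.root, self.post[tl.root]))
        return lnl, (new_blens, P_new, recomputed)

    def accept(self, lnl, update):
        new_blens, P_new, recomputed = update
        for i, b in new_blens.items():
            self.blens[i] = b
            self.P[i] = P_new[i]
        for j, r in recomputed.items():
            self.post[j] = r
        self.lnl = lnl

    def set_all(self, blens):
        self.blens = np.asarray(blens, dtype=float).copy()
        self._full()


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

class _DatingSampler:
    def __init__(self, aln, topology, calibrations, config, model, likelihood_on=True):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.tree = parse_newick(topology) if isinstance(topology, str) else topology
        self.model = model
        self.likelihood_on = likelihood_on
        self._index()
        self._resolve_calibrations(calibrations)
        self._init_state(aln)

    # -- setup --------------------------------------------------------------

    def _index(self):
        nodes = list(self.tree.postorder_node_iter())
        self.nodes = nodes
        self.n = len(nodes)
        self.idx = {id(n): i for i, n in enumerate(nodes)}
        self.parent = np.full(self.n, -1, dtype=int)
        self.children = [[] for _ in nodes]
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self.idx[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
        self.root = self.n - 1
        self._nonroot_idx = np.array([i for i in range(self.n) if i != self.root])
        self.is_tip = np.array([not self.children[i] for i in range(self.n)])
        self.internal = [i for i in range(self.n) if not self.is_tip[i]]
        self.leafsets = [frozenset(l.taxon.label for l in nd.leaf_iter()) for nd in nodes]
        # initial ages from the (time-)tree's branch lengths
        depth = np.zeros(self.n)
        for i in range(self.n - 1, -1, -1):
            if self.parent[i] >= 0:
                el = self.nodes[i].edge.length or 0.0
                depth[i] = depth[self.parent[i]] + el
        T = depth[self.is_tip].max()
        self.ages = np.where(self.is_tip, 0.0, T - depth)
        self.ages[self.is_tip] = 0.0

    def _mrca(self, taxa: frozenset) -> int:
        best, bestsize = None, None
        for i in self.internal:
            if taxa <= self.leafsets[i]:
                if bestsize is None or len(self.leafsets[i]) < bestsize:
                    best, bestsize = i, len(self.leafsets[i])
        if best is None:
            raise TreeError(f"no node contains taxa {sorted(taxa)}")
        return best

    def _resolve_calibrations(self, calibrations):
        # the focal node = MRCA of a Z tip and its W partner
        labels = {l.taxon.label for l in self.tree.leaf_node_iter()}
        w_tips = [l for l in labels if l.endswith("_W")]
        self.focal_node = None
        if w_tips:
            wt = sorted(w_tips)[0]
            z = wt[:-2]
            if z in labels:
                self.focal_node = self._mrca(frozenset([z, wt]))
        self.calib = {}  # node index -> list of priors
        for cal in calibrations:
            node = self._mrca(cal.taxa)
            if node == self.focal_node:
                raise TreeError(
                    "calibration prior placed on the focal Z-W divergence node"
                )
            self.calib.setdefault(node, []).append(cal)
        # vectorized calibration arrays for the hot prior evaluation
        norm, logn, unif = [], [], []
        for node, cals in self.calib.items():
            for cal in cals:
                a, b = cal.params
                {"normal": norm, "lognormal": logn, "uniform": unif}[cal.dist] \
                    .append((node, a, b))
        self._cal_norm = tuple(np.array(v) for v in zip(*norm)) if norm else None
        self._cal_logn = tuple(np.array(v) for v in zip(*logn)) if logn else None
        self._cal_unif = tuple(np.array(v) for v in zip(*unif)) if unif else None
        if self._cal_norm is not None:
            self._cal_norm = (self._cal_norm[0].astype(int),) + self._cal_norm[1:]
        if self._cal_logn is not None:
            self._cal_logn = (self._cal_logn[0].astype(int),) + self._cal_logn[1:]
        if self._cal_unif is not None:
            self._cal_unif = (self._cal_unif[0].astype(int),) + self._cal_unif[1:]

    def _init_state(self, aln):
        c = self.config
        self.log_rate = np.log(1e-3)
        self.sigma = 0.1
        self.mults = np.ones(self.n)  # per-branch rate multipliers (ucln)
        # ensure a positive-prior starting state
        for attempt in range(101):
            if np.isfinite(self._log_prior()):
                break
            if attempt == 100:
                raise TreeError("could not find a starting state with positive prior")
            self._redraw_ages()
        self.engine = None
        if self.likelihood_on:
            self.engine = _Pruning(self.tree, aln, self.model)
            self.engine.set_all(self._all_blens())
        self.tune = {"root": 0.1, "rate": 0.3, "mult": 0.3, "sigma": 0.3, "subst": 0.2}
        self._acc = {k: [0, 0] for k in list(self.tune) + ["age"]}

    def _redraw_ages(self):
        # draw calibrated ages from their priors, then enforce ordering by
        # pushing parents above children
        for i, cals in self.calib.items():
            self.ages[i] = cals[0].sample(self.rng)
        for i in range(self.n):  # postorder: children first
            if not self.is_tip[i]:
                mx = max(self.ages[c] for c in self.children[i])
                if self.ages[i] <= mx:
                    self.ages[i] = mx * 1.05 + 1e-9
        if self.focal_node is not None:
            i = self.focal_node
            lo = max(self.ages[c] for c in self.children[i])
            hi = self.ages[self.parent[i]] if self.parent[i] >= 0 else lo * 2 + 1.0
            self.ages[i] = 0.5 * (lo + hi) if hi > lo else lo + 1e-9

    # -- state pieces -------------------------------------------------------

    def _all_blens(self):
        rate = np.exp(self.log_rate)
        b = np.empty(self.n)
        for i in range(self.n):
            p = self.parent[i]
            if p >= 0:
                b[i] = max((self.ages[p] - self.ages[i]) * rate * self.mults[i], 1e-12)
        b[self.root] = 0.0
        return b

    def _log_prior(self):
        ages = self.ages
        nr = self._nonroot_idx
        if np.any(ages[self.parent[nr]] < ages[nr]):
            return -np.inf
        mra = self.config.max_root_age
        if mra is not None and ages[self.root] > mra:
            return -np.inf
        lp = 0.0
        if self._cal_norm is not None:
            idx, mu, sd = self._cal_norm
            a = ages[idx]
            if np.any(a <= 0):
                return -np.inf
            lp += float(np.sum(-0.5 * ((a - mu) / sd) ** 2 - np.log(sd)
                               - 0.5 * np.log(2 * np.pi)))
        if self._cal_logn is not None:
            idx, mu, sd = self._cal_logn
            a = ages[idx]
            if np.any(a <= 0):
                return -np.inf
            la = np.log(a)
            lp += float(np.sum(-0.5 * ((la - mu) / sd) ** 2 - la - np.log(sd)
                               - 0.5 * np.log(2 * np.pi)))
        if self._cal_unif is not None:
            idx, lo_b, hi_b = self._cal_unif
            a = ages[idx]
            if np.any((a < lo_b) | (a > hi_b)):
                return -np.inf
            lp += float(np.sum(-np.log(hi_b - lo_b)))
        lo, hi = self.config.rate_bounds
        rate = np.exp(self.log_rate)
        if not lo <= rate <= hi:
            return -np.inf
        lp += -self.log_rate  # 1/rate density on [lo, hi]
        if self.config.clock == "ucln":
            if self.sigma <= 0:
                return -np.inf
            lp += -2.0 * self.sigma  # Exponential(2) on the clock spread
            mu = -0.5 * self.sigma ** 2
            m = self.mults[np.arange(self.n) != self.root]
            lp += float(np.sum(
                -np.log(m) - np.log(self.sigma) - 0.5 * np.log(2 * np.pi)
                - (np.log(m) - mu) ** 2 / (2 * self.sigma ** 2)
            ))
        return lp

    # -- proposal machinery ---------------------------------------------------

    def _edges_of_node(self, i):
        out = [c for c in self.children[i]]
        if self.parent[i] >= 0:
            out.append(i)
        return out

    def _blen(self, i, ages=None, rate=None):
        ages = self.ages if ages is None else ages
        rate = np.exp(self.log_rate) if rate is None else rate
        p = self.parent[i]
        return max((ages[p] - ages[i]) * rate * self.mults[i], 1e-12)

    def _try(self, kind, d_logprior_new, blens_update, log_hastings=0.0,
             full_state=None):
        """Generic Metropolis step.  ``d_logprior_new`` is the full new log
        prior; ``blens_update`` maps node->new length (None = no change)."""
        if not np.isfinite(d_logprior_new):
            ok = False
            new_lnl = None
            update = None
        elif self.engine is None or blens_update is None:
            new_lnl, update = (self.engine.lnl if self.engine else 0.0), None
            blens_update = None
            ok = True
        elif blens_update == "all":
            old_blens = self.engine.blens.copy()
            old_lnl = self.engine.lnl
            self.engine.set_all(full_state)
            new_lnl, update = self.engine.lnl, "all"
            ok = True
        else:
            new_lnl, update = self.engine.propose(blens_update)
            ok = True
        if ok:
            cur_post = self.lp + self.ll
            new_post = d_logprior_new + (new_lnl if self.engine else 0.0)
            if np.log(self.rng.random()) < new_post - cur_post + log_hastings:
                # accept
                if self.engine is not None and update is not None and update != "all":
                    self.engine.accept(new_lnl, update)
                self.lp = d_logprior_new
                self.ll = new_lnl if self.engine else 0.0
                self._acc[kind][0] += 1
                self._acc[kind][1] += 1
                return True
        # reject: restore engine if we clobbered it
        if blens_update == "all" and ok:
            self.engine.set_all(old_blens)
            self.engine.lnl = old_lnl
        self._acc[kind][1] += 1
        return False

    # -- the chain ----------------------------------------------------------

    def run(self):
        c = self.config
        self.lp = self._log_prior()
        self.ll = self.engine.lnl if self.engine else 0.0
        non_root_internal = [i for i in self.internal if i != self.root]
        subst_params = self.model.free_parameters() if c.sample_substitution else []
        moves = ["age"] * 12 + ["root"] * 2 + ["rate"] * 3
        if c.clock == "ucln":
            moves += ["mult"] * 4 + ["sigma"] * 1
        if subst_params and self.engine is not None:
            moves += ["subst"]
        moves = np.array(moves)
        records = []
        rng = self.rng
        total = c.chain_length
        draw = rng.integers(0, len(moves), size=total)
        for step in range(1, total + 1):
            kind = moves[draw[step - 1]]
            if kind == "age" and non_root_internal:
                i = non_root_internal[int(rng.integers(len(non_root_internal)))]
                lo = max(self.ages[cc] for cc in self.children[i])
                hi = self.ages[self.parent[i]]
                if hi > lo:
                    old = self.ages[i]
                    self.ages[i] = rng.uniform(lo, hi)
                    lp_new = self._log_prior()
                    upd = {e: self._blen(e) for e in self._edges_of_node(i)}
                    if not self._try("age", lp_new, upd):
                        self.ages[i] = old
            elif kind == "root":
                i = self.root
                old = self.ages[i]
                lam = self.tune["root"]
                factor = np.exp(lam * (rng.random() - 0.5))
                self.ages[i] = old * factor
                lp_new = self._log_prior()
                upd = {e: self._blen(e) for e in self.children[i]}
                if not self._try("root", lp_new, upd, log_hastings=np.log(factor)):
                    self.ages[i] = old
            elif kind == "rate":
                old = self.log_rate
                lam = self.tune["rate"]
                self.log_rate = old + lam * (rng.random() - 0.5)
                lp_new = self._log_prior()
                if not self._try("rate", lp_new, "all", full_state=self._all_blens()):
                    self.log_rate = old
            elif kind == "mult":
                i = int(rng.integers(self.n))
                if i == self.root:
                    continue
                old = self.mults[i]
                lam = self.tune["mult"]
                factor = np.exp(lam * (rng.random() - 0.5))
                self.mults[i] = old * factor
                lp_new = self._log_prior()
                upd = {i: self._blen(i)}
                if not self._try("mult", lp_new, upd, log_hastings=np.log(factor)):
                    self.mults[i] = old
            elif kind == "sigma":
                old = self.sigma
                lam = self.tune["sigma"]
                self.sigma = old * np.exp(lam * (rng.random() - 0.5))
                lp_new = self._log_prior()
                if not self._try("sigma", lp_new, None,
                                 log_hastings=np.log(self.sigma / old)):
                    self.sigma = old
            elif kind == "subst":
                name = subst_params[int(rng.integers(len(subst_params)))]
                self._subst_move(name)
            # adaptive tuning during pre-burnin only
            if step <= c.pre_burnin and step % 200 == 0:
                self._adapt()
            if step > c.pre_burnin and (step - c.pre_burnin) % c.sample_interval == 0:
                records.append(self._record(step))
        return PosteriorTrace(pd.DataFrame(records), c)

    def _subst_move(self, name):
        from .seqmodels import _model_with_param
        old_model = self.model
        cur = getattr(old_model, name) if not name.startswith("exch") \
            else old_model.exch[int(name[4])]
        lam = self.tune["subst"]
        factor = np.exp(lam * (self.rng.random() - 0.5))
        new_val = cur * factor
        if not 0.02 <= new_val <= 100:
            self._acc["subst"][1] += 1
            return
        new_model = _model_with_param(old_model, name, new_val)
        old_lnl = self.engine.lnl
        self.engine.rebuild_model(new_model)
        new_lnl = self.engine.lnl
        # log-uniform prior on rate-type parameters: density 1/x
        if np.log(self.rng.random()) < (new_lnl - old_lnl) \
                + np.log(cur / new_val) + np.log(factor):
            self.model = new_model
            self.ll = new_lnl
            self._acc["subst"][0] += 1
        else:
            self.engine.rebuild_model(old_model)
        self._acc["subst"][1] += 1

    def _adapt(self):
        for k, (acc, tot) in self._acc.items():
            if k in self.tune and tot >= 20:
                frac = acc / tot
                if frac < 0.2:
                    self.tune[k] *= 0.8
                elif frac > 0.5:
                    self.tune[k] *= 1.25
                self._acc[k] = [0, 0]

    def _record(self, step):
        rec = {
            "state": step,
            "posterior": self.lp + self.ll,
            "likelihood": self.ll,
            "prior": self.lp,
            "root_age": self.ages[self.root],
            "rate": float(np.exp(self.log_rate)),
        }
        if self.focal_node is not None:
            rec["focal_age"] = self.ages[self.focal_node]
        if self.config.clock == "ucln":
            rec["sigma"] = self.sigma
        return rec


def run_dating_mcmc(aln: Alignment | None, topology, calibrations,
                    config: DatingConfig, model: SubstitutionModel | None = None,
                    likelihood_on: bool = True) -> PosteriorTrace:
    """Run the node-dating chain on a fixed gametolog topology.

    ``topology`` is a dated tree (Newick string or dendropy tree with
    branch lengths in time units) providing the starting node ages; its
    topology never changes during the run.  ``model`` defaults to the
    TN93+G4+I site model with empirical base frequencies.  With
    ``likelihood_on=False`` the chain samples from the prior alone (the
    standard sampler validation).  Deterministic given ``config.seed``.
    """
    if model is None:
        if aln is None:
            model = SubstitutionModel(family="TN93", alpha=0.5, ncat=4, pinv=0.1)
        else:
            from .seqmodels import empirical_base_frequencies
            model = SubstitutionModel(family="TN93", pi=empirical_base_frequencies(aln),
                                      kappa1=4.0, kappa2=4.0, alpha=0.5, ncat=4,
                                      pinv=0.1)
    if likelihood_on and aln is None:
        raise ValueError("likelihood_on requires an alignment")
    sampler = _DatingSampler(aln, topology, list(calibrations), config, model,
                             likelihood_on=likelihood_on)
    return sampler.run()


# ---------------------------------------------------------------------------
# Trace summaries
# ---------------------------------------------------------------------------

def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous window containing ``ceil(mass * n)`` order
    statistics — the highest-posterior-density interval of an empirical
    sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    if n == 1:
        return float(x[0]), float(x[0])
    m = int(np.ceil(mass * n))
    m = min(max(m, 1), n)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def ess(samples) -> float:
    """Effective sample size n / (1 + 2 * sum rho_k), summing empirical
    autocorrelations until the first non-positive one."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    v = np.var(x)
    if v == 0:
        warnings.warn("constant series; ESS defined as n")
        return float(n)
    xc = x - x.mean()
    acf_sum = 0.0
    for k in range(1, n):
        rho = float(np.dot(xc[:-k], xc[k:]) / (n * v))
        if rho <= 0:
            break
        acf_sum += rho
    return float(n / (1 + 2 * acf_sum))


def summarize_trace(trace: PosteriorTrace, mass: float = 0.95,
                    burnin_frac: float = 0.10, normalized: bool = True) -> DatingResult:
    """Posterior median, HPD and ESS of the focal Z–W divergence age.

    ``burnin_frac`` discards an initial fraction of retained samples
    before summarising.  With ``normalized=True`` each sample is divided
    by that state's root age, mapping onto the 0–1 t_RC scale.
    """
    df = trace.data
    start = int(np.floor(burnin_frac * len(df)))
    ages = df["focal_age"].to_numpy()[start:]
    if normalized:
        ages = ages / df["root_age"].to_numpy()[start:]
    lo, hi = hpd_interval(ages, mass)
    return DatingResult(median=float(np.median(ages)), hpd_lo=lo, hpd_hi=hi,
                        ess=ess(ages), normalized=normalized)


# ---------------------------------------------------------------------------
# Outgroup reduction (precision-vs-taxa experiment)
# ---------------------------------------------------------------------------

def load_calibrations(path):
    """Read calibration priors from a JSON config: a list of objects with
    keys ``taxa`` (clade tip labels), ``dist`` and ``params``."""
    import json

    with open(path) as fh:
        entries = json.load(fh)
    return [CalibrationPrior(frozenset(e["taxa"]), e["dist"], tuple(e["params"]))
            for e in entries]


def save_calibrations(calibrations, path) -> None:
    import json

    entries = [{"taxa": sorted(c.taxa), "dist": c.dist,
                "params": list(c.params)} for c in calibrations]
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2)


def default_calibrations(sp: SpeciesTree, sd_frac: float = 0.05):
    """Normal calibration priors centred on every internal-node age of a
    dated species tree (sd = ``sd_frac`` x age) — fixture-style priors for
    simulation studies."""
    out = []
    for node in sp.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        taxa = frozenset(l.taxon.label for l in node.leaf_iter())
        age = sp.age(node)
        out.append(CalibrationPrior(taxa, "normal", (age, max(sd_frac * age, 1e-6))))
    return out


def reduce_outgroups(sp: SpeciesTree, aln: Alignment | None, keep: int,
                     calibrations=None):
    """Prune the species tree (and alignment / calibrations) down to the
    focal species plus its ``keep`` closest outgroups along the focal path.

    A calibration survives iff its node survives the pruning (at least two
    of the node's child subtrees retain kept tips); its taxa are restricted
    to the kept set.  Returns ``(species_tree, alignment, calibrations)``.
    """
    others = [t for t in sp.tips if t != sp.focal_species]
    if keep > len(others):
        raise TreeError(f"keep={keep} exceeds the {len(others)} available outgroups")
    # closest-first: order by divergence age from the focal species
    def div_age(t):
        return sp.age(sp.tree.mrca(taxon_labels=[sp.focal_species, t]))

    kept = sorted(others, key=div_age)[:keep]
    kept_set = frozenset(kept) | {sp.focal_species}

    # rebuild pruned dated newick from node ages
    from .simulate import _from_species, _restrict, _emit_newick
    root = _restrict(_from_species(sp, sp.tree.seed_node), kept_set)
    if root.label is not None:
        raise TreeError("pruning left fewer than 2 tips")
    inner = ",".join(_emit_newick(c, root.age, 1.0, 1.0) for c in root.children)
    pruned = SpeciesTree(f"({inner});", sp.focal_species,
                         w_bearing=(sp.w_bearing_set & kept_set) or None)

    new_aln = None
    if aln is not None:
        keep_labels = [l for l in aln.labels
                       if l in kept_set or (l.endswith("_W") and l[:-2] in kept_set)
                       or l == w_label(sp.focal_species)]
        new_aln = aln.subset(keep_labels)

    new_cals = None
    if calibrations is not None:
        surviving = {}
        for node in sp.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            child_hits = sum(
                1 for c in node.child_nodes()
                if any(l.taxon.label in kept_set for l in c.leaf_iter())
            )
            if child_hits >= 2:
                taxa = frozenset(l.taxon.label for l in node.leaf_iter())
                surviving[taxa] = taxa & kept_set
        new_cals = []
        for cal in calibrations:
            if cal.taxa in surviving:
                new_cals.append(CalibrationPrior(surviving[cal.taxa], cal.dist,
                                                 cal.params))
    return pruned, new_aln, new_cals
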