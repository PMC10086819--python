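"""Expected likelihood weights (ELW) over a recombination-cessation scenario set.

Given per-site log-likelihoods of a gene alignment under each hypothetical
gametolog topology (each at its own ML branch lengths), the RELL bootstrap
resamples site columns with replacement, turns each replicate's total
log-likelihoods into normalized weights (softmax), and averages the
weights over replicates.  The resulting ELW vector sums to 1 over the
scenario set; its argmax is the most likely cessation index and the
smallest high-weight set accumulating 95% of the mass gives the
uncertainty range on the discrete t_RC scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .seqmodels import Alignment, SubstitutionModel, TreeLikelihood, fit_model
from .trees import ScenarioSet

__all__ = [
    "ELWResult",
    "rell_elw",
    "elw_range",
    "scenario_site_lnl_matrix",
    "elw_pipeline",
]

#: replicates drawn per chunk; chunking keeps memory flat while leaving the
#: random stream a pure function of (seed, chunk index)
_CHUNK = 4096


@dataclass
class ELWResult:
    """ELW vector over scenarios 1..S plus derived summaries."""

    weights: np.ndarray
    n_boot: int
    seed: int | None
    mass: float = 0.95

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n_scenarios(self) -> int:
        return self.weights.size

    @property
    def best_index(self) -> int:
        """1-based index of the highest-ELW scenario."""
        return int(np.argmax(self.weights)) + 1

    @property
    def range_95(self) -> tuple[int, int]:
        return elw_range(self, self.mass)

    def as_row(self, gene_id: str = "") -> dict:
        lo, hi = self.range_95
        row = {"gene_id": gene_id}
        row.update({f"elw_{k+1}": w for k, w in enumerate(self.weights)})
        row.update({"best_index": self.best_index, "range_lo": lo, "range_hi": hi})
        return row


def rell_elw(site_lnl_matrix: np.ndarray, n_boot: int, seed: int | None = None,
             mass: float = 0.95) -> ELWResult:
    """RELL-bootstrap expected likelihood weights.

    ``site_lnl_matrix`` is S x L: per-site log-likelihoods of each of S >= 2
    scenario topologies at their own ML branch lengths.  Each bootstrap
    replicate resamples the L site columns with replacement (equivalently,
    draws multinomial site counts), computes replicate total lnL per
    scenario, and softmax-normalizes; ELW is the mean weight vector over
    replicates.  Deterministic given ``seed``.
    """
    m = np.asarray(site_lnl_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need an S x L matrix with S >= 2 scenarios")
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite site log-likelihoods")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    S, L = m.shape
    p = np.full(L, 1.0 / L)
    total = np.zeros(S)
    seeds = np.random.SeedSequence(seed).spawn(-(-n_boot // _CHUNK))
    done = 0
    for cs in seeds:
        b = min(_CHUNK, n_boot - done)
        counts = np.random.default_rng(cs).multinomial(L, p, size=b)
        lnls = counts @ m.T  # (b, S)
        w = np.exp(lnls - logsumexp(lnls, axis=1, keepdims=True))
        total += w.sum(axis=0)
        done += b
    return ELWResult(weights=total / n_boot, n_boot=n_boot, seed=seed, mass=mass)


def elw_range(result: ELWResult, mass: float = 0.95) -> tuple[int, int]:
    """Contiguous index hull of the greedy high-ELW set.

    Scenarios are added in descending weight (ties broken toward the lower
    index) until the cumulative weight reaches ``mass``; the reported range
    is [min index, max index] of the selected set.
    """
    if not 0 < mass <= 1:
        raise ValueError("mass must lie in (0, 1]")
    w = result.weights
    order = np.lexsort((np.arange(w.size), -w))
    csum = np.cumsum(w[order])
    n_sel = int(np.searchsorted(csum, mass - 1e-12)) + 1
    n_sel = min(n_sel, w.size)
    chosen = order[:n_sel]
    return int(chosen.min()) + 1, int(chosen.max()) + 1


def scenario_site_lnl_matrix(aln: Alignment, scenarios: ScenarioSet,
                             model: SubstitutionModel,
                             tol: float = 1e-6, max_sweeps: int = 8) -> np.ndarray:
    """S x L per-site log-likelihood matrix: branch lengths are optimized
    per scenario topology while the substitution model is shared."""
    rows = []
    for tree in scenarios.dendropy_trees():
        engine = TreeLikelihood(tree, aln, model)
        engine.optimize_branches(tol=tol, max_sweeps=max_sweeps)
        rows.append(engine.site_log_likelihoods())
    return np.vstack(rows)


def elw_pipeline(aln: Alignment, scenarios: ScenarioSet,
                 model: SubstitutionModel | str = "HKY85",
                 n_boot: int = 100_000, seed: int | None = None,
                 mass: float = 0.95, fit_gamma: bool = False) -> ELWResult:
    """End-to-end ELW for one gene alignment.

    When ``model`` is a family name, the model is fitted once on the
    scenario-1 topology (empirical base frequencies, ML rate parameters)
    and then shared across scenarios; per-scenario branch lengths are
    always re-optimized.  Returns an :class:`ELWResult` of length S.
    """
    needed = set(scenarios.tip_labels)
    missing = needed - set(aln.labels)
    if missing:
        raise ValueError(f"alignment lacks scenario tips: {sorted(missing)}")
    aln = aln.subset(sorted(needed)) if set(aln.labels) - needed else aln
    if isinstance(model, str):
        first = scenarios.dendropy_trees()[0]
        model = fit_model(aln, first, family=model, gamma=fit_gamma)
    m = scenario_site_lnl_matrix(aln, scenarios, model)
    return rell_elw(m, n_boot=n_boot, seed=seed, mass=mass)


def elw_table(results: dict[str, ELWResult]) -> pd.DataFrame:
    """Wide per-gene ELW table (gene_id, S weights, best index, 95% range)."""
    return pd.DataFrame([r.as_row(g) for g, r in results.items()])


def elw_long_table(results: dict[str, ELWResult]) -> pd.DataFrame:
    """Heatmap-ready long format: one row per gene x scenario."""
    rows = []
    for gene, r in results.items():
        for k, w in enumerate(r.weights, start=1):
            rows.append({"gene_id": gene, "scenario": k, "elw": w})
    return pd.DataFrame(rows)
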