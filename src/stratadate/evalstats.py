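"""Evaluation statistics for comparing t_RC estimators.

Two-cluster analyses of per-gene t_RC estimates (Lloyd K-means on feature
vectors, PAM k-medoids on a distance matrix), the exact one-dimensional
second-order Wasserstein distance between posterior samples, Spearman
rank correlation, and the Kruskal–Wallis / Wilcoxon signed-rank battery
with Bonferroni correction.

K-means needs coordinates, so scalar or vector estimates (dS values,
ML_CT ranges as (lo, hi) pairs, full ELW weight vectors) are clustered
with Lloyd's algorithm under the Euclidean metric, while posterior
distributions — for which Euclidean distance is not meaningful — are
compared by W2 distance and clustered with k-medoids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _st
from sklearn.cluster import KMeans

__all__ = [
    "ClusterAssignment",
    "kmeans_lloyd",
    "kmedoids",
    "wasserstein2_1d",
    "wasserstein2_matrix",
    "spearman_rho",
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "bonferroni",
    "nonparam_battery",
    "compare_hpd_widths",
    "plot_elw_heatmap",
]


@dataclass
class ClusterAssignment:
    """Cluster labels (0-based) with sizes and objective value."""

    labels: np.ndarray
    k: int
    cost: float
    medoids: np.ndarray | None = None

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def kmeans_lloyd(points, k: int = 2, seed=None, n_init: int = 50) -> ClusterAssignment:
    """Best of ``n_init`` seeded Lloyd runs by within-cluster sum of
    squares; deterministic given ``seed``."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    if np.allclose(X, X[0]):
        warnings.warn("all points identical; degenerate single-cluster partition")
        return ClusterAssignment(labels=np.zeros(n, dtype=int), k=k, cost=0.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    return ClusterAssignment(labels=labels.astype(int), k=k, cost=float(km.inertia_))


def kmedoids(d: np.ndarray, k: int = 2, seed=None) -> ClusterAssignment:
    """PAM (partitioning around medoids): greedy BUILD then SWAP until no
    single medoid exchange lowers the total distance-to-medoid cost.
    Input is a square symmetric non-negative matrix with zero diagonal.
    Deterministic (the seed only breaks exact ties, which are resolved by
    index order anyway)."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9) or np.any(d < -1e-12) \
            or np.any(np.abs(np.diag(d)) > 1e-9):
        raise ValueError("need a symmetric non-negative matrix with zero diagonal")
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")

    def cost_of(meds):
        return float(d[:, meds].min(axis=1).sum())

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        best_c, best_j = np.inf, None
        for j in range(n):
            if j in medoids:
                continue
            c = cost_of(medoids + [j])
            if c < best_c:
                best_c, best_j = c, j
        medoids.append(best_j)
    cost = cost_of(medoids)
    # SWAP
    improved = True
    while improved:
        improved = False
        for mi, m in enumerate(list(medoids)):
            for j in range(n):
                if j in medoids:
                    continue
                cand = list(medoids)
                cand[mi] = j
                c = cost_of(cand)
                if c < cost - 1e-12:
                    medoids, cost = cand, c
                    improved = True
    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1)
    return ClusterAssignment(labels=labels.astype(int), k=k, cost=cost,
                             medoids=np.array(medoids))


# ---------------------------------------------------------------------------
# Wasserstein distance (1-D, second order)
# ---------------------------------------------------------------------------

def wasserstein2_1d(a, b) -> float:
    """Exact W2 between the empirical distributions of two 1-D samples.

    W2^2 = integral over u in (0,1) of (Qa(u) - Qb(u))^2 du, computed on
    the union of the two quantile-function breakpoint grids; for samples
    of equal size this reduces to the root-mean-square difference of the
    sorted values.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("empty sample")
    grid = np.union1d(np.arange(1, n + 1) / n, np.arange(1, m + 1) / m)
    grid = np.concatenate([[0.0], grid])
    mids = (grid[:-1] + grid[1:]) / 2
    widths = np.diff(grid)
    ia = np.minimum(np.ceil(mids * n).astype(int) - 1, n - 1)
    ib = np.minimum(np.ceil(mids * m).astype(int) - 1, m - 1)
    return float(np.sqrt(np.sum((a[ia] - b[ib]) ** 2 * widths)))


def wasserstein2_matrix(samples: list) -> np.ndarray:
    """Pairwise W2 matrix between a list of 1-D samples."""
    n = len(samples)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = wasserstein2_1d(samples[i], samples[j])
    return d


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def spearman_rho(x, y):
    """Spearman rank correlation (mid-ranks for ties) with the t-based
    p-value; returns (nan, nan) with a warning for a constant vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Spearman rho undefined")
        return float("nan"), float("nan")
    res = _st.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups):
    """Kruskal–Wallis H (tie-corrected) across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    flat = [np.asarray(g, dtype=float) for g in groups]
    if np.ptp(np.concatenate(flat)) == 0:  # identical data: H = 0
        return 0.0, 1.0
    res = _st.kruskal(*flat)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(x, y, exact_max_n: int = 25):
    """Paired Wilcoxon signed-rank test; exact null distribution for
    n <= ``exact_max_n`` (when free of ties/zeros), normal approximation
    above.  All-zero differences leave the test undefined (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    if np.all(diff == 0):
        warnings.warn("all paired differences are zero: Wilcoxon undefined")
        return float("nan"), float("nan")
    nz = diff[diff != 0]
    use_exact = nz.size <= exact_max_n and np.unique(np.abs(nz)).size == nz.size
    method = "exact" if use_exact else "approx"
    res = _st.wilcoxon(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(pvals):
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.asarray(pvals, dtype=float)
    return np.minimum(1.0, p * p.size)


def nonparam_battery(samples: dict, paired: bool = True) -> pd.DataFrame:
    """Kruskal–Wallis across all groups plus all pairwise Wilcoxon
    signed-rank tests (paired), Bonferroni-corrected over the pairwise
    family.  ``samples`` maps group label -> 1-D sample.  Returns a long
    table (test, groups, statistic, p, p_adjusted)."""
    labels = list(samples)
    rows = []
    H, p = kruskal_wallis([samples[l] for l in labels])
    rows.append({"test": "kruskal-wallis", "groups": "|".join(map(str, labels)),
                 "statistic": H, "p": p, "p_adjusted": p})
    pair_rows = []
    for a, b in combinations(labels, 2):
        W, pw = wilcoxon_signed_rank(samples[a], samples[b])
        pair_rows.append({"test": "wilcoxon-signed-rank", "groups": f"{a}|{b}",
                          "statistic": W, "p": pw})
    if pair_rows:
        adj = bonferroni([r["p"] for r in pair_rows])
        for r, pa in zip(pair_rows, adj):
            r["p_adjusted"] = float(pa) if np.isfinite(r["p"]) else float("nan")
    rows.extend(pair_rows)
    return pd.DataFrame(rows)


def compare_hpd_widths(widths: pd.DataFrame):
    """Summarise 95%-HPD widths across outgroup levels.

    ``widths`` needs columns ``level``, ``gene_id``, ``width`` with the
    same gene set at every level.  Returns ``(long, medians, tests)``:
    the level x gene long table, per-level median widths, and the paired
    test battery with Bonferroni correction.
    """
    required = {"level", "gene_id", "width"}
    if not required <= set(widths.columns):
        raise ValueError(f"need columns {sorted(required)}")
    levels = list(dict.fromkeys(widths["level"]))
    gene_sets = {lv: frozenset(widths.loc[widths.level == lv, "gene_id"])
                 for lv in levels}
    if len(set(gene_sets.values())) != 1:
        raise ValueError("gene sets differ between levels")
    genes = sorted(gene_sets[levels[0]])
    long = (widths.set_index(["level", "gene_id"])
            .loc[[(lv, g) for lv in levels for g in genes]]
            .reset_index())
    medians = long.groupby("level", sort=False)["width"].median().reset_index()
    by_level = {
        lv: long[long.level == lv].set_index("gene_id").loc[genes, "width"].to_numpy()
        for lv in levels
    }
    tests = nonparam_battery(by_level, paired=True)
    return long, medians, tests


# ---------------------------------------------------------------------------
# Minimal plotting helper (the correctness surface is the tables)
# ---------------------------------------------------------------------------

def plot_elw_heatmap(long_table: pd.DataFrame, path=None):
    """Gene x scenario ELW heatmap from the long-format table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = long_table.pivot(index="gene_id", columns="scenario", values="elw")
    fig, ax = plt.subplots(figsize=(6, max(2, 0.2 * len(pivot))))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xlabel("scenario (recent → ancient)")
    ax.set_ylabel("gene")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns)
    fig.colorbar(im, ax=ax, label="ELW")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
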