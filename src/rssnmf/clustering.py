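"""Cluster assignment, baselines, ARI evaluation and consensus stability.

Cells are clustered either by k-means on the columns of the coefficient
matrix H or by assigning each cell to the metagene with its largest
coefficient.  Stability over repeated randomly initialized runs is
summarized by the consensus matrix: the per-run binary connectivity matrix
(C_ij = 1 iff cells i and j share a cluster) averaged over runs, so an
entry of 1 means the pair co-clustered in every run.

Accuracy against known labels is the adjusted Rand index (ARI), the
chance-corrected pair-counting agreement between two partitions, ranging
from -1 to 1 with 1 for identical partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import comb
from sklearn.cluster import KMeans

from .data_io import ExpressionMatrix, LabelVector
from .graph import PriorGraph
from .solvers import FactorizationResult, fit

__all__ = [
    "ConsensusResult",
    "cluster_from_H",
    "baseline_cluster",
    "connectivity_matrix",
    "consensus_matrix",
    "adjusted_rand_index",
    "run_experiment",
]


@dataclass
class ConsensusResult:
    """Connectivity matrices and their average over repeated runs."""

    connectivity: list[np.ndarray]
    consensus: np.ndarray
    per_run_labels: list[LabelVector]
    runs: int
    per_run_ari: Optional[np.ndarray] = None
    results: Optional[list[FactorizationResult]] = None

    @property
    def mean_ari(self) -> Optional[float]:
        return None if self.per_run_ari is None else float(np.mean(self.per_run_ari))

    @property
    def sd_ari(self) -> Optional[float]:
        return None if self.per_run_ari is None else float(np.std(self.per_run_ari))


def cluster_from_H(
    h: np.ndarray, k: int, method: str = "kmeans", seed: int = 0
) -> LabelVector:
    """Assign cells to k clusters from the coefficient matrix H (k' x n).

    ``kmeans`` clusters the raw columns of H (10 seeded restarts);
    ``argmax`` assigns cell j to the metagene with the largest coefficient
    in column j, ties broken toward the lowest index.  Cluster labels are
    integers 1..k.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2:
        raise ValueError("H must be 2-d")
    n = h.shape[1]
    if method == "argmax":
        labels = np.argmax(h, axis=0) + 1
    elif method == "kmeans":
        if k > n:
            raise ValueError(f"k={k} exceeds number of cells n={n}")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(h.T) + 1
    else:
        raise ValueError(f"unknown assignment method {method!r}")
    return LabelVector([int(l) for l in labels])


def baseline_cluster(
    x: ExpressionMatrix | np.ndarray, k: int, method: str = "kmeans", seed: int = 0
) -> LabelVector:
    """Cluster cells directly on expression: k-means or Ward hierarchical.

    Both use Euclidean distance on the cell columns; hierarchical clustering
    uses Ward linkage cut at k clusters.
    """
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    n = values.shape[1]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must lie in [1, {n}]")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(values.T) + 1
    elif method == "hierarchical":
        Z = linkage(values.T, method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust")
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return LabelVector([int(l) for l in labels])


def connectivity_matrix(labels: LabelVector | Sequence) -> np.ndarray:
    """Binary co-clustering indicator: C_ij = 1 iff i and j share a cluster."""
    arr = labels.as_array() if isinstance(labels, LabelVector) else np.asarray(labels)
    if arr.size == 0:
        raise ValueError("empty labeling")
    return (arr[:, None] == arr[None, :]).astype(float)


def consensus_matrix(connectivities: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise mean of per-run connectivity matrices."""
    if len(connectivities) == 0:
        raise ValueError("need at least one connectivity matrix")
    mats = [np.asarray(c, dtype=float) for c in connectivities]
    shape = mats[0].shape
    if any(c.shape != shape for c in mats):
        raise ValueError("connectivity matrices have mismatched shapes")
    return np.mean(mats, axis=0)


def adjusted_rand_index(a: LabelVector | Sequence, b: LabelVector | Sequence) -> float:
    """Adjusted Rand index between two partitions of the same items.

    Computed from the pair-counting contingency table as
    (Index - ExpectedIndex) / (MaxIndex - ExpectedIndex), where Index is the
    number of co-clustered pairs shared by both partitions and the
    expectation is under the hypergeometric model of random partitions with
    fixed cluster sizes.  Returns 1 for identical partitions (up to label
    renaming) and 0 in expectation for independent ones.
    """
    ax = a.as_array() if isinstance(a, LabelVector) else np.asarray(a)
    bx = b.as_array() if isinstance(b, LabelVector) else np.asarray(b)
    if ax.shape != bx.shape:
        raise ValueError(f"label vectors differ in length: {ax.size} vs {bx.size}")
    n = ax.size
    if n < 2:
        raise ValueError("need at least two items")
    _, ai = np.unique(ax, return_inverse=True)
    _, bi = np.unique(bx, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    sum_comb = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        # both partitions are the same trivial partition (all-in-one or
        # all-singletons); they agree perfectly
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def run_experiment(
    x: ExpressionMatrix | np.ndarray,
    k: int,
    variant: str = "rssnmf",
    g: Optional[PriorGraph] = None,
    alpha: float = 0.0,
    beta: float = 0.0,
    runs: int = 30,
    base_seed: int = 0,
    assignment: str = "kmeans",
    truth: Optional[LabelVector] = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    keep_results: bool = False,
) -> ConsensusResult:
    """Repeat the factorization `runs` times and summarize stability.

    Run r uses seed ``base_seed + r`` for both the factor initialization and
    the k-means assignment, so the whole experiment is reproducible from
    ``base_seed``.  When ``truth`` is given, the per-run ARI against it is
    recorded.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    connectivity = []
    per_run_labels = []
    aris = [] if truth is not None else None
    results = [] if keep_results else None
    for r in range(runs):
        seed = base_seed + r
        res = fit(x, k, variant=variant, g=g, alpha=alpha, beta=beta,
                  max_iter=max_iter, tol=tol, seed=seed)
        labels = cluster_from_H(res.H, k, method=assignment, seed=seed)
        per_run_labels.append(labels)
        connectivity.append(connectivity_matrix(labels))
        if truth is not None:
            aris.append(adjusted_rand_index(labels, truth))
        if keep_results:
            results.append(res)
    return ConsensusResult(
        connectivity=connectivity,
        consensus=consensus_matrix(connectivity),
        per_run_labels=per_run_labels,
        runs=runs,
        per_run_ari=None if aris is None else np.asarray(aris),
        results=results,
    )
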