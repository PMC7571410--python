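"""Cell-cell similarity graph built from marker-gene expression.

The semi-supervised prior enters the factorization through a graph on the
cells.  Only the expression rows of known marker genes are used: for cells
``x_i``, ``x_j`` restricted to those rows, the heat-kernel weight is

    Q_ij = exp(-||x_i - x_j||^2 / sigma)

with bandwidth ``sigma`` (default 1).  The degree matrix is
``D_ii = sum_j Q_ij`` and the graph Laplacian ``L = D - Q`` is symmetric
positive semidefinite with zero row sums.  The local-invariance penalty on
a coefficient matrix ``H`` is ``Tr(H L H^T)``, which equals half the
Q-weighted sum of squared distances between coefficient columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import ExpressionMatrix, MarkerSet

__all__ = [
    "PriorGraph",
    "select_marker_rows",
    "heat_kernel_weights",
    "graph_laplacian",
    "graph_penalty",
    "build_prior_graph",
]

_SYM_TOL = 1e-10


@dataclass
class PriorGraph:
    """Heat-kernel weight matrix Q with its degree matrix and Laplacian."""

    Q: np.ndarray
    sigma: float
    marker_genes_used: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.degrees = self.Q.sum(axis=1)
        self.L = np.diag(self.degrees) - self.Q

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def n_cells(self) -> int:
        return self.Q.shape[0]


def select_marker_rows(x: ExpressionMatrix, markers: MarkerSet) -> ExpressionMatrix:
    """Row-submatrix of x over the union of all marker genes.

    Rows are ordered by first appearance in the marker set; marker ids not
    present in the matrix are reported with a warning.  Raises if the
    overlap is empty.
    """
    present = set(x.gene_ids)
    wanted = markers.all_genes()
    found = [g for g in wanted if g in present]
    missing = [g for g in wanted if g not in present]
    if missing:
        warnings.warn(f"marker genes absent from matrix: {missing}")
    if not found:
        raise ValueError(f"no marker genes overlap the matrix: {missing}")
    return x.subset_genes(found)


def heat_kernel_weights(x_sub: ExpressionMatrix | np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Heat-kernel similarity between cell columns of a marker submatrix.

    ``Q_ij = exp(-||x_i - x_j||^2 / sigma)`` over the marker rows; symmetric
    with unit diagonal.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    values = x_sub.values if isinstance(x_sub, ExpressionMatrix) else np.asarray(x_sub, float)
    if values.ndim != 2 or values.shape[0] < 1:
        raise ValueError("marker submatrix must have at least one row")
    d2 = squareform(pdist(values.T, metric="sqeuclidean"))
    Q = np.exp(-d2 / sigma)
    # pdist leaves the diagonal exactly zero, so Q_ii == 1; symmetrize away
    # any rounding in the off-diagonal exponentials
    return (Q + Q.T) / 2.0


def graph_laplacian(q: np.ndarray, sigma: float = 1.0,
                    marker_genes_used: list[str] | None = None) -> PriorGraph:
    """Build degree matrix and Laplacian from a symmetric weight matrix."""
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("Q must be square")
    if np.any(q < 0):
        raise ValueError("Q must be nonnegative")
    if np.max(np.abs(q - q.T)) > _SYM_TOL:
        raise ValueError("Q must be symmetric")
    g = PriorGraph(q, sigma, marker_genes_used or [])
    # L is PSD by construction for nonnegative symmetric Q; cheap sanity check
    eig_min = np.linalg.eigvalsh(g.L)[0]
    if eig_min < -1e-8:
        raise ValueError(f"Laplacian not positive semidefinite (lambda_min={eig_min})")
    return g


def graph_penalty(h: np.ndarray, g: PriorGraph) -> float:
    """Local-invariance penalty Tr(H L H^T) of a coefficient matrix.

    Equals ``(1/2) * sum_ij ||h_i - h_j||^2 Q_ij``; nonnegative because L
    is positive semidefinite.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[1] != g.n_cells:
        raise ValueError(
            f"H has {h.shape} but graph has {g.n_cells} cells"
        )
    return float(np.trace(h @ g.L @ h.T))


def build_prior_graph(
    x: ExpressionMatrix,
    markers: MarkerSet,
    sigma: float = 1.0,
    *,
    log1p: bool = False,
    knn: int | None = None,
) -> PriorGraph:
    """Marker-row selection, heat-kernel weighting and Laplacian in one step.

    ``log1p`` applies log(1+x) to the marker rows before computing distances
    (off by default; distances are taken on the matrix as given).  ``knn``
    optionally sparsifies Q by keeping each cell's top-k weights and
    re-symmetrizing with the elementwise maximum.
    """
    sub = select_marker_rows(x, markers)
    values = np.log1p(sub.values) if log1p else sub.values
    Q = heat_kernel_weights(values, sigma)
    if knn is not None:
        if knn < 1:
            raise ValueError("knn must be >= 1")
        n = Q.shape[0]
        keep = np.zeros_like(Q, dtype=bool)
        for i in range(n):
            order = np.argsort(Q[i])[::-1]
            order = order[order != i][:knn]
            keep[i, order] = True
            keep[i, i] = True
        Qs = np.where(keep, Q, 0.0)
        Q = np.maximum(Qs, Qs.T)
    return graph_laplacian(Q, sigma, sub.gene_ids)
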