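"""Multiplicative-update solvers for NMF, rNMF, ssNMF and rssNMF.

The full robust semi-supervised objective is

    min_{W,H,S}  ||X - W H - S||_F^2  +  alpha ||S||_1  +  beta Tr(H L H^T)
    s.t.  W >= 0, H >= 0

where ``X`` is the (m genes x n cells) expression matrix, ``W`` (m x k) the
basis of metagenes, ``H`` (k x n) the per-cell loadings, ``S`` (m x n) a
sparse error matrix absorbing outliers, and ``L`` the graph Laplacian of a
marker-gene cell similarity graph.  The four variants are ablations of this
objective:

======== ============= ==============
variant  sparse S (α)  graph term (β)
======== ============= ==============
nmf      no            no
rnmf     yes           no
ssnmf    no            yes
rssnmf   yes           yes
======== ============= ==============

Optimization is block coordinate descent.  W and H use the KKT-derived
multiplicative rules

    W_ij <- W_ij (X H^T)_ij / (W H H^T + S H^T)_ij
    H_ij <- H_ij (W^T X + beta H Q)_ij / (W^T W H + W^T S + beta H D)_ij

and S has the closed-form proximal solution S <- T_{alpha/2}(X - W H) with
T the elementwise soft-thresholding operator.  Each block step does not
increase the objective, so the recorded objective trace is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_io import ExpressionMatrix
from .graph import PriorGraph, graph_penalty

__all__ = [
    "FactorizationResult",
    "VARIANTS",
    "init_factors",
    "soft_threshold",
    "update_W",
    "update_H",
    "update_S",
    "objective",
    "fit",
]

VARIANTS = ("nmf", "rnmf", "ssnmf", "rssnmf")

#: additive floor applied to every multiplicative-update denominator,
#: guarding against 0/0 when a factor entry collapses to zero
EPS = 1e-10


@dataclass
class FactorizationResult:
    """Outcome of one factorization run.

    ``S`` is the zero matrix for the variants without the sparse error term.
    ``objective_trace[0]`` is the objective at initialization and one value
    is appended per iteration.
    """

    W: np.ndarray
    H: np.ndarray
    S: np.ndarray
    objective_trace: list[float]
    params: dict
    n_iter: int
    converged: bool
    gene_ids: Optional[list[str]] = None
    cell_ids: Optional[list[str]] = None

    @property
    def s_sparsity(self) -> float:
        """Fraction of exactly-zero entries in S."""
        return float(np.mean(self.S == 0.0))


def init_factors(m: int, n: int, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random nonnegative initialization of W (m x k) and H (k x n).

    Entries are absolute values of standard-normal draws, which keeps the
    scale of a standard-normal initialization while satisfying the
    nonnegativity constraints.  Deterministic given the seed.
    """
    if not (1 <= k <= min(m, n)):
        raise ValueError(f"rank k={k} must satisfy 1 <= k <= min(m={m}, n={n})")
    rng = np.random.default_rng(seed)
    W = np.abs(rng.standard_normal((m, k)))
    H = np.abs(rng.standard_normal((k, n)))
    return W, H


def soft_threshold(z, upsilon: float):
    """Elementwise soft-thresholding T_v(z): shrink toward 0, zero the dead zone.

    T_v(z) = z - v if z > v;  z + v if z < -v;  0 otherwise.  This is the
    closed-form minimizer of (1/2)(x - v)^2 + v|v|-type L1 proximal
    subproblems.
    """
    if upsilon <= 0:
        raise ValueError("upsilon must be positive")
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - upsilon, 0.0)


def update_W(X: np.ndarray, W: np.ndarray, H: np.ndarray, S: np.ndarray) -> np.ndarray:
    """One multiplicative update of the basis matrix W."""
    numer = X @ H.T
    denom = W @ (H @ H.T) + S @ H.T + EPS
    return W * (numer / denom)


def update_H(
    X: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    S: np.ndarray,
    g: Optional[PriorGraph] = None,
    beta: float = 0.0,
) -> np.ndarray:
    """One multiplicative update of the coefficient matrix H.

    With ``beta == 0`` (and S zero) this is exactly the classical
    Lee-Seung rule H_ij <- H_ij (W^T X)_ij / (W^T W H)_ij.
    """
    if beta > 0 and g is None:
        raise ValueError("beta > 0 requires a prior graph")
    numer = W.T @ X
    denom = (W.T @ W) @ H + W.T @ S
    if beta > 0:
        numer = numer + beta * (H @ g.Q)
        denom = denom + beta * (H * g.degrees[np.newaxis, :])  # H @ D
    return H * (numer / (denom + EPS))


def update_S(X: np.ndarray, W: np.ndarray, H: np.ndarray, alpha: float) -> np.ndarray:
    """Closed-form S step: soft-threshold the residual at alpha/2.

    Minimizes ||X - WH - S||_F^2 + alpha ||S||_1 over S.  Entries of the
    residual with magnitude at most alpha/2 give S exactly zero, so a large
    enough alpha pins S to the zero matrix and the model degenerates to
    plain NMF.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    R = X - W @ H
    if alpha == 0:
        import warnings

        warnings.warn("alpha=0: S absorbs the entire residual; WH is unidentifiable")
        return R
    return soft_threshold(R, alpha / 2.0)


def objective(
    X: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    S: Optional[np.ndarray] = None,
    g: Optional[PriorGraph] = None,
    alpha: float = 0.0,
    beta: float = 0.0,
) -> float:
    """Value of ||X - WH - S||_F^2 + alpha ||S||_1 + beta Tr(H L H^T)."""
    R = X - W @ H
    if S is not None:
        R = R - S
    val = float(np.sum(R * R))
    if S is not None and alpha > 0:
        val += alpha * float(np.sum(np.abs(S)))
    if beta > 0:
        if g is None:
            raise ValueError("beta > 0 requires a prior graph")
        val += beta * graph_penalty(H, g)
    return val


def _validate_variant(variant: str, alpha: float, beta: float, g) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if variant == "nmf":
        if alpha != 0 or beta != 0:
            raise ValueError("variant 'nmf' takes neither alpha nor beta")
    elif variant == "rnmf":
        if alpha <= 0:
            raise ValueError("variant 'rnmf' requires alpha > 0")
        if beta != 0:
            raise ValueError("variant 'rnmf' has no graph term; use rssnmf")
    elif variant == "ssnmf":
        if alpha != 0:
            raise ValueError("variant 'ssnmf' has no sparse error term (alpha)")
        if beta <= 0:
            raise ValueError("variant 'ssnmf' requires beta > 0")
    elif variant == "rssnmf":
        if alpha <= 0:
            raise ValueError("variant 'rssnmf' requires alpha > 0")
        if beta < 0:
            raise ValueError("beta must be nonnegative")
    if beta > 0 and g is None:
        raise ValueError("beta > 0 requires a prior graph")


def fit(
    X: ExpressionMatrix | np.ndarray,
    k: int,
    variant: str = "rssnmf",
    g: Optional[PriorGraph] = None,
    alpha: float = 0.0,
    beta: float = 0.0,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> FactorizationResult:
    """Factorize X with the chosen variant by block coordinate descent.

    Each iteration updates W, then H, then S (the S step is skipped for the
    variants without the error matrix).  Iteration stops when the relative
    objective change drops below ``tol`` or after ``max_iter`` iterations.
    The objective trace is non-increasing up to floating-point slack.
    """
    gene_ids = cell_ids = None
    if isinstance(X, ExpressionMatrix):
        gene_ids, cell_ids = X.gene_ids, X.cell_ids
        X = X.values
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be nonnegative")
    _validate_variant(variant, alpha, beta, g)
    m, n = X.shape
    W, H = init_factors(m, n, k, seed)
    S = np.zeros((m, n))
    with_S = variant in ("rnmf", "rssnmf")
    use_beta = beta if variant in ("ssnmf", "rssnmf") else 0.0

    obj = objective(X, W, H, S, g, alpha if with_S else 0.0, use_beta)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = update_W(X, W, H, S)
        H = update_H(X, W, H, S, g, use_beta)
        if with_S:
            S = update_S(X, W, H, alpha)
        new_obj = objective(X, W, H, S, g, alpha if with_S else 0.0, use_beta)
        if not np.isfinite(new_obj):
            raise FloatingPointError(
                "objective became non-finite; check the denominator floor"
            )
        trace.append(new_obj)
        if abs(obj - new_obj) / max(obj, 1e-12) < tol:
            converged = True
            obj = new_obj
            break
        obj = new_obj

    params = dict(
        k=k, variant=variant, alpha=alpha, beta=beta,
        sigma=(g.sigma if g is not None else None),
        max_iter=max_iter, tol=tol, seed=seed,
    )
    return FactorizationResult(
        W=W, H=H, S=S, objective_trace=trace, params=params,
        n_iter=it, converged=converged, gene_ids=gene_ids, cell_ids=cell_ids,
    )
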