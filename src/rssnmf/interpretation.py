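"""Gene scoring and cluster assignment from the basis matrix W.

Each row of W gives a gene's contribution to the k metagenes.  Normalizing
the row to a probability profile p(i, .), the gene score

    score(i) = 1 + (1 / log2 k) * sum_j p(i, j) log2 p(i, j)

is one minus the normalized entropy of the profile: 1 for a gene loading
on a single metagene (perfectly cluster-specific), 0 for a uniform gene.
Genes are assigned to the metagene with the largest contribution.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, MarkerSet

__all__ = ["gene_scores", "assign_genes", "select_markers_by_variance"]


def gene_scores(
    w: np.ndarray, gene_ids: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Score every gene for cluster specificity from its W row.

    Returns a DataFrame with columns ``gene_id``, ``score``, ``cluster``
    (1-based argmax metagene, or "unassigned" for an all-zero row) and the
    contribution profile ``p_1 .. p_k``.  Uses the 0*log2(0) = 0 convention;
    scores lie in [0, 1] and are invariant to positive rescaling of a row.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2:
        raise ValueError("W must be 2-d")
    m, k = w.shape
    if k < 2:
        raise ValueError("gene score requires k >= 2 (log2(k) must be positive)")
    if np.any(w < 0):
        raise ValueError("W must be nonnegative")
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(m)]
    row_sums = w.sum(axis=1)
    nonzero = row_sums > 0
    p = np.zeros_like(w)
    p[nonzero] = w[nonzero] / row_sums[nonzero, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    scores = np.where(nonzero, 1.0 + plogp.sum(axis=1) / np.log2(k), 0.0)
    scores = np.clip(scores, 0.0, 1.0)  # guard rounding at the boundaries
    clusters: list = [
        int(np.argmax(w[i]) + 1) if nonzero[i] else "unassigned" for i in range(m)
    ]
    table = pd.DataFrame({"gene_id": list(gene_ids), "score": scores, "cluster": clusters})
    for j in range(k):
        table[f"p_{j + 1}"] = p[:, j]
    return table


def assign_genes(table: pd.DataFrame, w: np.ndarray, min_score: float = 0.0) -> pd.DataFrame:
    """Assign each gene to its argmax metagene, gated by a minimum score.

    Genes scoring below ``min_score`` (and all-zero rows) are marked
    "unassigned".  The default threshold 0 assigns every gene with a
    nonzero row, mirroring a full row-annotation of W.
    """
    w = np.asarray(w, dtype=float)
    if len(table) != w.shape[0]:
        raise ValueError("table and W are not aligned")
    if not (0.0 <= min_score <= 1.0):
        raise ValueError("min_score must lie in [0, 1]")
    out = table.copy()
    nonzero = w.sum(axis=1) > 0
    assigned: list = []
    for i in range(w.shape[0]):
        if not nonzero[i] or out.iloc[i]["score"] < min_score:
            assigned.append("unassigned")
        else:
            assigned.append(int(np.argmax(w[i]) + 1))
    out["cluster"] = assigned
    return out


def select_markers_by_variance(
    x: ExpressionMatrix,
    candidates: MarkerSet | Mapping[str, Sequence[str]],
    n_per_group: int,
) -> MarkerSet:
    """Keep each group's top-variance candidate genes as its markers.

    Within each group's candidate list (e.g. differentially expressed genes
    from an external DE analysis), genes are ranked by the variance of
    their expression row across all cells and the top ``n_per_group`` kept;
    ties break by gene id ascending.  Groups with fewer candidates than
    requested return all of them with a warning.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    groups = candidates.groups if isinstance(candidates, MarkerSet) else dict(candidates)
    index = {gid: i for i, gid in enumerate(x.gene_ids)}
    selected: dict[str, list[str]] = {}
    for group, genes in groups.items():
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"group {group!r}: candidate genes absent from matrix: {missing}")
        if len(genes) < n_per_group:
            warnings.warn(
                f"group {group!r} has only {len(genes)} candidates "
                f"(requested {n_per_group}); keeping all"
            )
        variances = {g: float(np.var(x.values[index[g], :])) for g in genes}
        ranked = sorted(genes, key=lambda g: (-variances[g], g))
        selected[group] = ranked[:n_per_group]
    return MarkerSet(selected)
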