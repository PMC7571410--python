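# rssnmf — robust semi-supervised NMF for scRNA-seq clustering

Clustering single-cell RNA-seq data is hard when the expression matrix
contains gross outliers and when cell types are transcriptionally similar.
`rssnmf` addresses both at once: it factorizes a nonnegative gene × cell
matrix X as

    X ≈ W H + S,    minimize ‖X − WH − S‖_F² + α‖S‖₁ + β·Tr(H L Hᵀ)
                    subject to W ≥ 0, H ≥ 0

where the sparse error matrix **S** absorbs outlying entries (L1 weight α)
and the graph Laplacian **L**, built from heat-kernel similarities
`Q_ij = exp(−‖x_i−x_j‖²/σ)` over the rows of *known marker genes*, injects
partial prior knowledge: cells that look alike on the markers of a known
cell group are pulled toward similar loadings. Cells are clustered from
the columns of H (k-means or argmax); genes are scored for cluster
specificity from the rows of W. The ablations `nmf` (neither term),
`rnmf` (S only) and `ssnmf` (graph only) are included, along with k-means
and Ward baselines, adjusted-Rand-index evaluation, and consensus-matrix
stability analysis over repeated seeded runs.

It is aimed at computational biologists who have a normalized expression
matrix, know marker genes for at least one of the cell populations in
their sample (the common case: sorted or well-characterized contaminating
populations), and want that knowledge to sharpen an otherwise unsupervised
clustering.

## Worked example

```python
import numpy as np
from rssnmf import (make_block_dataset, holdout_markers, build_prior_graph,
                    run_experiment)

# 5 cell groups x 10 cells, 20 marker genes each; 10% outlier entries of 5x signal
ds = make_block_dataset(k_groups=5, genes_per_group=20, background_genes=0,
                        cells_per_group=10, signal_mean=10, outlier_fraction=0.10,
                        outlier_magnitude=50, seed=1)

# assume only group1 is known a priori, through its 20 marker genes
graph = build_prior_graph(ds.expression, holdout_markers(ds, ["group1"], 20))

for variant, alpha, beta, g in [("nmf", 0, 0, None), ("rnmf", 2, 0, None),
                                ("rssnmf", 2, 2, graph)]:
    cr = run_experiment(ds.expression, k=5, variant=variant, g=g, alpha=alpha,
                        beta=beta, runs=30, base_seed=0, truth=ds.true_labels)
    print(f"{variant:7s} mean ARI {cr.mean_ari:.3f} (sd {cr.sd_ari:.3f})")
```

prints

```
nmf     mean ARI 0.065 (sd 0.050)
rnmf    mean ARI 0.734 (sd 0.205)
rssnmf  mean ARI 0.732 (sd 0.194)
```

Plain NMF is destroyed by the outliers (ARI ≈ 0.07: its metagenes chase
the corrupted entries), while the robust variants shunt them into S and
recover the block structure (ARI ≈ 0.73). On this heavily corrupted
matrix the marker prior adds little beyond robustness — few cell pairs
survive with clean marker rows. On the clean version of the data, NMF,
ssNMF and both baselines recover the true labels exactly and perfectly
stably (ARI 1 in every run, binary consensus); the robust variants reach
ARI 1 in most runs but can absorb marker blocks into S on idealized
zero-background data (see the limitations section of `docs/methods.md`).

The same pipeline is available from the shell:

```
rssnmf simulate --k 5 --genes-per-group 20 --cells-per-group 10 --outlier-fraction 0.1 --out sim/
rssnmf experiment --input sim/expression.tsv --variant rssnmf --k 5 \
    --markers sim/markers.tsv --runs 30 --labels sim/labels.tsv --out res/
rssnmf genescore --w res/W.tsv --out gene_scores.tsv   # after `rssnmf fit`
```

## Layout

- `src/rssnmf/data_io.py` — TSV/CSV/MatrixMarket readers and writers for
  expression matrices, marker sets, labels and factorization results
- `src/rssnmf/synthetic.py` — block-structured generator with known truth
- `src/rssnmf/graph.py` — marker-row selection, heat-kernel weights,
  Laplacian, graph penalty
- `src/rssnmf/solvers.py` — the four factorization variants
- `src/rssnmf/clustering.py` — assignment, baselines, ARI, consensus
- `src/rssnmf/interpretation.py` — gene scores and marker selection
- `src/rssnmf/cli.py` — `rssnmf` command with subcommands
- `docs/methods.md` — model, conventions, numerical choices, limitations
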