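"""Per-cluster expression statistics.

Provides the 10%-prevalence "expressed genes" filter, one-vs-rest Wilcoxon
rank-sum differential expression (the source of node scores downstream),
Benjamini–Hochberg correction, and centroid-distance summaries in an
arbitrary embedding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .datatypes import ClusterAssignment, ExpressionMatrix, ValidationError

__all__ = [
    "expressed_genes",
    "wilcoxon_de",
    "benjamini_hochberg",
    "centroid_distances",
]


def expressed_genes(expr: ExpressionMatrix, clusters: ClusterAssignment,
                    cluster: str, min_frac: float = 0.10) -> set[str]:
    """Genes detected (value > 0) in at least ``min_frac`` of the cluster's cells.

    The boundary is inclusive: a gene detected in exactly ``min_frac`` of the
    cells passes.
    """
    if not (0.0 <= min_frac <= 1.0):
        raise ValidationError("min_frac must be in [0, 1]")
    mask = clusters.mask_for(cluster, expr.cell_ids)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError(f"cluster {cluster!r} has no cells in the matrix")
    frac = (expr.values[:, mask] > 0).sum(axis=1) / n
    return {g for g, f in zip(expr.gene_ids, frac) if f >= min_frac}


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_EXACT_MAX_N = 25


def wilcoxon_de(expr: ExpressionMatrix, clusters: ClusterAssignment,
                cluster: str, genes: list[str] | None = None) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test of one cluster vs all other cells.

    Exact p-values when both groups have <= 25 cells and the gene's values are
    tie-free; normal approximation (tie-corrected, continuity-corrected)
    otherwise. Adjusted p-values are BH across all genes tested for this
    cluster. Returns a table with columns cluster, gene_id, p, p_adj, mean_in,
    mean_out.
    """
    mask = clusters.mask_for(cluster, expr.cell_ids)
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    if n_in < 2 or n_out < 2:
        raise ValidationError(
            f"cluster {cluster!r}: need >= 2 cells on both sides "
            f"(got {n_in} vs {n_out})"
        )
    if genes is None:
        gene_rows = np.arange(expr.n_genes)
    else:
        gidx = expr.gene_index()
        gene_rows = np.array([gidx[g] for g in genes], dtype=int)
    x = expr.values[np.ix_(gene_rows, mask)]
    y = expr.values[np.ix_(gene_rows, ~mask)]

    pvals = np.ones(len(gene_rows))
    # constant genes carry no rank information: p = 1 by convention
    allvals = np.concatenate([x, y], axis=1)
    constant = np.all(allvals == allvals[:, :1], axis=1)
    varying = ~constant
    if varying.any():
        if n_in <= _EXACT_MAX_N and n_out <= _EXACT_MAX_N:
            for i in np.nonzero(varying)[0]:
                row = allvals[i]
                method = "exact" if len(np.unique(row)) == len(row) else "asymptotic"
                pvals[i] = mannwhitneyu(x[i], y[i], alternative="two-sided",
                                        method=method).pvalue
        else:
            res = mannwhitneyu(x[varying], y[varying], alternative="two-sided",
                               method="asymptotic", axis=1)
            pvals[varying] = np.minimum(np.nan_to_num(res.pvalue, nan=1.0), 1.0)
    return pd.DataFrame({
        "cluster": cluster,
        "gene_id": [expr.gene_ids[i] for i in gene_rows],
        "p": pvals,
        "p_adj": benjamini_hochberg(pvals),
        "mean_in": x.mean(axis=1),
        "mean_out": y.mean(axis=1),
    })


def centroid_distances(embedding: pd.DataFrame, clusters: ClusterAssignment,
                       ref_cluster: str) -> pd.DataFrame:
    """Mean and population SD of Euclidean distances from the reference
    cluster's centroid to each cell of every other cluster.

    ``embedding`` is cells × dimensions with cell IDs as index.
    """
    ref_cells = clusters.cells_of(ref_cluster)
    missing = [c for c in clusters.labels.index if c not in embedding.index]
    if missing:
        raise ValidationError(f"cells missing from embedding: {missing[:5]}")
    coords = embedding.to_numpy(dtype=float)
    if coords.ndim != 2:
        raise ValidationError("embedding must be 2-dimensional")
    centroid = embedding.loc[ref_cells].to_numpy(dtype=float).mean(axis=0)
    rows = []
    for target in clusters.clusters:
        if target == ref_cluster:
            continue
        pts = embedding.loc[clusters.cells_of(target)].to_numpy(dtype=float)
        d = np.linalg.norm(pts - centroid, axis=1)
        rows.append({"target_cluster": target,
                     "mean_distance": float(d.mean()),
                     "sd": float(d.std(ddof=0))})
    return pd.DataFrame(rows, columns=["target_cluster", "mean_distance", "sd"])
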