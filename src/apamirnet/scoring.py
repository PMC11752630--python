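"""Expression-based significance scoring of feed-forward loops.

Each SFFL receives:

* node scores — Φ⁻¹(1 − p_adj) of the one-vs-rest differential-expression
  adjusted p-value (larger = more cluster-specific), for every node with a
  DE row;
* edge scores — |atanh(r)|·sqrt(n − 3), the Fisher-transformed Pearson
  correlation of the two endpoints' log-normalized expression over the
  cluster's n cells (a signed variant is available);
* an overall score S = arithmetic mean of all available node and edge
  scores. A miRNA without an expression row contributes neither its node
  score nor its incident edge scores.

Significance per SFFL comes from B random (miRNA, TF, gene) triples drawn
from the cluster's candidate pools and scored under the observed SFFL's
edge-presence pattern, so observed and null scores average the same entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_stats import benjamini_hochberg
from .datatypes import (
    ClusterAssignment,
    ExpressionMatrix,
    PipelineConfig,
    ValidationError,
)
from .ffl import MFFL, SFFL

__all__ = [
    "node_score",
    "edge_score",
    "ClusterContext",
    "build_cluster_context",
    "sffl_score",
    "sffl_permutation_test",
    "annotate_apa_loss",
]

_P_CLIP = 1e-12
_R_CLIP = 1.0 - 1e-7


def node_score(p_adj) -> np.ndarray | float:
    """Inverse-normal transform Φ⁻¹(1 − p_adj); strictly decreasing in p_adj.

    p is clipped to [1e-12, 1 − 1e-12] so the score stays finite at the ends.
    """
    from scipy.stats import norm

    p = np.asarray(p_adj, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("adjusted p-values must be in [0, 1]")
    out = norm.ppf(1.0 - np.clip(p, _P_CLIP, 1.0 - _P_CLIP))
    return float(out) if np.isscalar(p_adj) else out


def edge_score(x, y, signed: bool = False) -> float:
    """Fisher-z score of the Pearson correlation of two expression vectors.

    z = atanh(r)·sqrt(n − 3) with r clipped to ±(1 − 1e-7); the absolute
    value is returned unless ``signed``. A zero-variance vector yields 0 with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 4:
        raise ValidationError("edge score needs n >= 4 cells")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in expression vectors")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance vector in edge score; returning 0",
                      stacklevel=2)
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -_R_CLIP, _R_CLIP))
    z = np.arctanh(r) * np.sqrt(n - 3)
    return float(z if signed else abs(z))


@dataclass
class ClusterContext:
    """Precomputed per-cluster scoring state.

    ``Z`` holds the cluster cells' log-normalized expression rows, centered
    and scaled to unit norm, so a row dot product is a Pearson r;
    zero-variance rows are all-zero (edge score 0). ``node_scores`` maps every
    DE-tested node to its inverse-normal score.
    """

    cluster: str
    n_cells: int
    Z: np.ndarray
    row_index: dict[str, int]
    node_scores: dict[str, float]

    def expr_row(self, node: str) -> int:
        """Row index of a node, or -1 when it has no expression row."""
        return self.row_index.get(node, -1)


def build_cluster_context(expr: ExpressionMatrix, clusters: ClusterAssignment,
                          cluster: str, de: pd.DataFrame) -> ClusterContext:
    """Assemble the scoring context for one cluster.

    ``de`` is a DEResult-shaped table (gene_id, p_adj) for this cluster; any
    such table may stand in for the built-in Wilcoxon DE.
    """
    mask = clusters.mask_for(cluster, expr.cell_ids)
    n = int(mask.sum())
    if n < 4:
        raise ValidationError(f"cluster {cluster!r} needs >= 4 cells for edge scores")
    ln = expr.log_normalized()
    X = ln.values[:, mask]
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    Z = np.zeros_like(Xc)
    nz = norms > 0
    Z[nz] = Xc[nz] / norms[nz, None]
    de_c = de[de["cluster"] == cluster] if "cluster" in de.columns else de
    scores = dict(zip(de_c["gene_id"], node_score(de_c["p_adj"].to_numpy())))
    return ClusterContext(
        cluster=cluster, n_cells=n, Z=Z,
        row_index={g: i for i, g in enumerate(expr.gene_ids)},
        node_scores=scores,
    )


def _pattern(sffl: SFFL) -> int:
    """Number of miRNA–TF cross-edges contributing to the score (1 or 2)."""
    return 2 if sffl.cls == "feedback" else 1


def _score_triples(ctx: ClusterContext, m_idx: np.ndarray, t_idx: np.ndarray,
                   g_idx: np.ndarray, m_node_scores: np.ndarray,
                   t_node_scores: np.ndarray, g_node_scores: np.ndarray,
                   n_cross: int, signed: bool) -> np.ndarray:
    """Mean of available node and edge scores for a batch of triples.

    ``m_idx`` entries of -1 mean the miRNA has no expression row: its node
    score (NaN in ``m_node_scores``) and incident edges are dropped.
    """
    sqrt_nm3 = np.sqrt(ctx.n_cells - 3)
    m_safe = np.where(m_idx >= 0, m_idx, 0)
    r_mg = np.einsum("ij,ij->i", ctx.Z[m_safe], ctx.Z[g_idx])
    r_mt = np.einsum("ij,ij->i", ctx.Z[m_safe], ctx.Z[t_idx])
    r_tg = np.einsum("ij,ij->i", ctx.Z[t_idx], ctx.Z[g_idx])

    def fisher(r):
        z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP)) * sqrt_nm3
        return z if signed else np.abs(z)

    has_m = m_idx >= 0
    has_m_node = has_m & np.isfinite(m_node_scores)
    total = np.where(has_m_node, m_node_scores, 0.0) + t_node_scores + g_node_scores
    count = has_m_node.astype(float) + 2.0
    total = total + fisher(r_tg)
    count += 1.0
    total = total + np.where(has_m, fisher(r_mg) + n_cross * fisher(r_mt), 0.0)
    count += np.where(has_m, 1.0 + n_cross, 0.0)
    return total / count


def _lookup_scores(ctx: ClusterContext, nodes: list[str]) -> np.ndarray:
    return np.array([ctx.node_scores.get(n, np.nan) for n in nodes])


def sffl_score(sffl: SFFL, ctx: ClusterContext, signed: bool = False) -> float:
    """Overall score of one SFFL; NaN when unscorable.

    Requires at least the TF and gene node scores plus the TF→gene edge (3
    entries); a miRNA without expression contributes nothing.
    """
    ti, gi = ctx.expr_row(sffl.tf), ctx.expr_row(sffl.gene)
    ts, gs = ctx.node_scores.get(sffl.tf), ctx.node_scores.get(sffl.gene)
    if ti < 0 or gi < 0 or ts is None or gs is None:
        return float("nan")  # unscorable: TF/gene must have expression and DE
    mi = ctx.expr_row(sffl.mirna)
    s = _score_triples(
        ctx,
        np.array([mi]), np.array([ti]), np.array([gi]),
        _lookup_scores(ctx, [sffl.mirna]), np.array([ts]), np.array([gs]),
        n_cross=_pattern(sffl), signed=signed,
    )
    return float(s[0])


def sffl_permutation_test(candidate_sffls: list[SFFL], ctx: ClusterContext,
                          pools: dict[str, list[str]],
                          config: PipelineConfig,
                          rng: np.random.Generator) -> list[SFFL]:
    """Random-triple permutation significance for a cluster's candidate SFFLs.

    ``pools`` maps "miRNA"/"TF"/"gene" to the cluster's candidate node lists
    (miRNAs without expression rows included). Each SFFL is compared against
    B uniform random triples scored under its own edge-presence pattern;
    default p = (1 + #{S_rand >= S_obs}) / (B + 1), or the literal
    #{S_rand >= S_obs} / B count with smoothing off. BH runs across all
    scorable candidates of the cluster.
    """
    B = config.n_permutations
    if B < 1:
        raise ValidationError("n_permutations must be >= 1")
    for k in ("miRNA", "TF", "gene"):
        if not pools.get(k):
            raise ValidationError(f"empty candidate pool for {k}")

    pool_idx = {}
    pool_ns = {}
    for k in ("miRNA", "TF", "gene"):
        nodes = pools[k]
        pool_idx[k] = np.array([ctx.expr_row(n) for n in nodes], dtype=int)
        pool_ns[k] = _lookup_scores(ctx, nodes)
    # TFs and genes in the pools must be scorable
    for k in ("TF", "gene"):
        bad = (pool_idx[k] < 0) | ~np.isfinite(pool_ns[k])
        if bad.any():
            offenders = [pools[k][i] for i in np.nonzero(bad)[0][:5]]
            raise ValidationError(
                f"{k} pool members without expression or DE rows: {offenders}")

    out: list[SFFL] = []
    scored = []
    for s in candidate_sffls:
        obs = sffl_score(s, ctx, signed=config.signed_edges)
        new = SFFL(mirna=s.mirna, tf=s.tf, gene=s.gene, cls=s.cls,
                   cluster=ctx.cluster, score=obs)
        if np.isfinite(obs):
            mi = rng.integers(0, len(pools["miRNA"]), size=B)
            ti = rng.integers(0, len(pools["TF"]), size=B)
            gi = rng.integers(0, len(pools["gene"]), size=B)
            s_rand = _score_triples(
                ctx,
                pool_idx["miRNA"][mi], pool_idx["TF"][ti], pool_idx["gene"][gi],
                pool_ns["miRNA"][mi], pool_ns["TF"][ti], pool_ns["gene"][gi],
                n_cross=_pattern(s), signed=config.signed_edges,
            )
            if config.smooth_permutation_p:
                new.p = float((1.0 + np.sum(s_rand >= obs)) / (B + 1.0))
            else:
                new.p = float(np.sum(s_rand >= obs) / B)
            scored.append(new)
        out.append(new)
    if scored:
        adj = benjamini_hochberg([s.p for s in scored])
        for s, a in zip(scored, adj):
            s.p_adj = float(a)
    return out


def annotate_apa_loss(sffls: list[SFFL], mffls: list[MFFL],
                      avoidance: pd.DataFrame, alpha: float = 0.05,
                      ) -> tuple[list[SFFL], list[dict]]:
    """Flag SFFLs/MFFLs whose miRNA family is significantly avoided by APA.

    An SFFL's flag is true iff its (cluster, miRNA family) pair has
    BH-adjusted avoidance p < alpha. MFFL dictionaries gain
    ``center_apa_loss`` (center miRNA family significant, miRNA-centered
    modules only) and ``member_apa_loss`` (any member miRNA significant).
    """
    sig: set[tuple[str, str]] = set()
    fam_col = "family_id" if "family_id" in avoidance.columns else "family"
    if len(avoidance):
        hit = avoidance[avoidance["p_adj"] < alpha]
        sig = set(zip(hit["cluster"], hit[fam_col]))
    av_clusters = set(avoidance["cluster"]) if len(avoidance) else set()
    for s in sffls:
        if s.cluster is None:
            raise ValidationError("SFFL has no cluster; filter before annotating")
        if av_clusters and s.cluster not in av_clusters:
            raise ValidationError(
                f"no avoidance results for cluster {s.cluster!r}")
        s.apa_loss_flag = (s.cluster, s.mirna) in sig
    if not av_clusters and sffls:
        warnings.warn("no avoidance results; all APA-loss flags set to False",
                      stacklevel=2)
    mffl_dicts = []
    for m in mffls:
        d = m.to_dict()
        d["center_apa_loss"] = (m.center_type == "miRNA"
                                and (m.cluster, m.center) in sig)
        d["member_apa_loss"] = any((m.cluster, s.mirna) in sig for s in m.members)
        mffl_dicts.append(d)
    return sffls, mffl_dicts
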