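"""APA-driven loss of microRNA-family binding sites, per cell cluster.

Alternative polyadenylation (APA) lets a gene emit 3'UTR isoforms of
different lengths. A microRNA-binding site located downstream of an isoform's
cleavage position is absent from that isoform ("lost"); a site wholly
upstream is "retained". For each (cluster, microRNA family) pair we total the
expression mass carried by lost versus retained site copies across the
cluster's cells and summarize it as the lost fraction L/(L+R) — a monotone
reparameterization of the lost:retained ratio that avoids division by zero.

Significance is assessed by shuffling cell-to-cluster labels (preserving
cluster sizes), recomputing the statistic for the focal cluster's permuted
cell set, and counting permuted statistics at least as large as the observed
one. BH correction is applied per cluster across families.

Only genes with >= 2 APA sites enter the statistic: loss *due to APA*
requires an alternative isoform to exist.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_stats import benjamini_hochberg
from .datatypes import ApaMatrix, ClusterAssignment, PipelineConfig, ValidationError

__all__ = [
    "site_fate",
    "family_lost_retained",
    "avoidance_statistic",
    "avoidance_permutation_test",
    "gene_loss_overlap",
    "substream",
]

BINARY_USE_FRAC = 0.05  # an isoform is "used" if nonzero in >= 5% of the cells


def substream(seed: int, *tokens) -> np.random.Generator:
    """Deterministic RNG substream keyed by (seed, tokens).

    Hashing the tokens makes each (stage, cluster) stream independent of the
    order in which stages and clusters are processed.
    """
    keys = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(t).encode()) & 0x7FFFFFFF for t in tokens
    ]
    return np.random.default_rng(np.random.SeedSequence(keys))


def site_fate(site: tuple[int, int], cleavage_pos: int) -> str:
    """Fate of one binding site on one isoform: ``retained`` iff the site lies
    wholly upstream of the cleavage position (``end <= cleavage_pos``), else
    ``lost`` — a truncated site cannot function."""
    start, end = site
    if not (0 <= start < end):
        raise ValidationError(f"invalid site ({start}, {end})")
    if cleavage_pos < 0:
        raise ValidationError("cleavage_pos must be >= 0")
    return "retained" if end <= cleavage_pos else "lost"


def avoidance_statistic(L: float, R: float) -> float:
    """Lost fraction L/(L+R); order-equivalent to the lost:retained ratio."""
    if L < 0 or R < 0:
        raise ValidationError("L and R must be non-negative")
    if L + R == 0:
        raise ValidationError("statistic undefined when L + R = 0")
    return L / (L + R)


@dataclass
class _FateWeights:
    """Per-(family, isoform) counts of lost and retained site copies.

    For family f and isoform row i of the APA matrix, ``lost[f, i]`` is the
    number of f-sites in the isoform's gene whose end exceeds the isoform's
    cleavage position. Multiplying by per-isoform expression sums gives the
    lost/retained mass totals without touching cells again — the cell set
    enters only through the isoform sums, which is what makes the label
    permutation cheap.
    """

    families: list[str]
    lost: np.ndarray       # (n_families, n_isoforms)
    retained: np.ndarray   # (n_families, n_isoforms)
    isoform_gene: np.ndarray  # gene id per isoform row (object array)


def _fate_weights(apa: ApaMatrix, sites: pd.DataFrame,
                  eligible_genes: set[str]) -> _FateWeights:
    meta = apa.site_meta
    families = sorted(sites["family_id"].unique())
    fidx = {f: k for k, f in enumerate(families)}
    n_iso = len(meta)
    lost = np.zeros((len(families), n_iso))
    ret = np.zeros((len(families), n_iso))
    sites_by_gene = {g: grp for g, grp in sites.groupby("gene_id")}
    cleavage = meta["cleavage_pos"].to_numpy()
    genes = meta["gene_id"].to_numpy()
    for i in range(n_iso):
        g = genes[i]
        if g not in eligible_genes:
            continue
        grp = sites_by_gene.get(g)
        if grp is None:
            continue
        is_lost = grp["end"].to_numpy() > cleavage[i]
        for fam, flag in zip(grp["family_id"], is_lost):
            if flag:
                lost[fidx[fam], i] += 1
            else:
                ret[fidx[fam], i] += 1
    return _FateWeights(families=families, lost=lost, retained=ret,
                        isoform_gene=genes)


def _eligible_genes(apa: ApaMatrix, eligible_genes: set[str] | None) -> set[str]:
    multi = apa.genes_with_multiple_sites()
    return multi if eligible_genes is None else multi & set(eligible_genes)


def _isoform_usage(apa: ApaMatrix, cell_mask: np.ndarray, mode: str) -> np.ndarray:
    """Per-isoform weight over a cell set: expression sum (weighted mode) or a
    0/1 "used" indicator (nonzero in >= 5% of the cells, binary mode)."""
    sub = apa.values[:, cell_mask]
    if mode == "weighted":
        return sub.sum(axis=1)
    if mode == "binary":
        n = int(cell_mask.sum())
        return ((sub > 0).sum(axis=1) >= BINARY_USE_FRAC * n).astype(float)
    raise ValidationError(f"unknown count mode {mode!r}")


def family_lost_retained(apa: ApaMatrix, sites: pd.DataFrame, cells,
                         eligible_genes: set[str] | None = None,
                         mode: str = "weighted") -> pd.DataFrame:
    """Per-family lost (L) and retained (R) site mass over a cell set.

    ``cells`` is a collection of cell IDs or a boolean mask over
    ``apa.cell_ids``. Returns columns family_id, lost, retained,
    contributing_genes (genes with positive lost mass).
    """
    if isinstance(cells, np.ndarray) and cells.dtype == bool:
        mask = cells
    else:
        cellset = set(cells)
        mask = np.array([c in cellset for c in apa.cell_ids], dtype=bool)
    if not mask.any():
        raise ValidationError("empty cell set")
    eligible = _eligible_genes(apa, eligible_genes)
    fw = _fate_weights(apa, sites, eligible)
    s = _isoform_usage(apa, mask, mode)
    L = fw.lost @ s
    R = fw.retained @ s
    contrib = []
    for k in range(len(fw.families)):
        per_iso = fw.lost[k] * s
        contrib.append(sorted(set(fw.isoform_gene[per_iso > 0])))
    return pd.DataFrame({
        "family_id": fw.families,
        "lost": L,
        "retained": R,
        "contributing_genes": contrib,
    })


def avoidance_permutation_test(apa: ApaMatrix, sites: pd.DataFrame,
                               clusters: ClusterAssignment, cluster: str,
                               config: PipelineConfig,
                               rng: np.random.Generator | None = None,
                               eligible_genes: set[str] | None = None,
                               ) -> pd.DataFrame:
    """Label-shuffle permutation test of binding-site loss for one cluster.

    For each of B permutations, cell labels are shuffled across all clusters
    preserving cluster sizes, and the lost fraction is recomputed on the focal
    cluster's permuted cell set. The default p-value is the add-one-smoothed
    tail frequency (1 + #{perm >= obs}) / (B + 1); with
    ``config.smooth_permutation_p`` off, the literal #{perm > obs} / B count
    is used instead. BH correction runs across the cluster's testable
    families. Families with L + R = 0 are untestable and reported with
    missing statistic and p.
    """
    if len(clusters.clusters) < 2:
        raise ValidationError("need >= 2 clusters for a label permutation test")
    B = config.n_permutations
    if B < 1:
        raise ValidationError("n_permutations must be >= 1")
    mask = clusters.mask_for(cluster, apa.cell_ids)
    n_c = int(mask.sum())
    if n_c < 2:
        raise ValidationError(f"cluster {cluster!r} has fewer than 2 cells")
    if rng is None:
        rng = substream(config.seed, "avoidance", cluster)

    eligible = _eligible_genes(apa, eligible_genes)
    fw = _fate_weights(apa, sites, eligible)
    n_cells = len(apa.cell_ids)
    mode = config.count_mode

    s_obs = _isoform_usage(apa, mask, mode)
    L = fw.lost @ s_obs
    R = fw.retained @ s_obs
    with np.errstate(invalid="ignore"):
        stat_obs = np.where(L + R > 0, L / np.maximum(L + R, 1e-300), np.nan)
    testable = (L + R) > 0

    # permuted focal cell sets are uniform subsets of size n_c
    member = np.zeros((n_cells, B))
    for b in range(B):
        member[rng.permutation(n_cells)[:n_c], b] = 1.0
    if mode == "weighted":
        s_perm = apa.values @ member                      # isoforms × B
    else:
        counts = (apa.values > 0).astype(float) @ member
        s_perm = (counts >= BINARY_USE_FRAC * n_c).astype(float)
    Lp = fw.lost @ s_perm
    Rp = fw.retained @ s_perm
    with np.errstate(invalid="ignore", divide="ignore"):
        stat_perm = Lp / (Lp + Rp)
    stat_perm[~np.isfinite(stat_perm)] = -np.inf  # undefined permutations never count

    p = np.full(len(fw.families), np.nan)
    for k in np.nonzero(testable)[0]:
        if config.smooth_permutation_p:
            p[k] = (1.0 + np.sum(stat_perm[k] >= stat_obs[k])) / (B + 1.0)
        else:
            p[k] = np.sum(stat_perm[k] > stat_obs[k]) / B
    p_adj = np.full(len(fw.families), np.nan)
    if testable.any():
        p_adj[testable] = benjamini_hochberg(p[testable])

    contrib = []
    for k in range(len(fw.families)):
        per_iso = fw.lost[k] * s_obs
        contrib.append(sorted(set(fw.isoform_gene[per_iso > 0])))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(R > 0, L / np.maximum(R, 1e-300), np.inf)
    return pd.DataFrame({
        "cluster": cluster,
        "family_id": fw.families,
        "lost": L,
        "retained": R,
        "statistic": stat_obs,
        "ratio": np.where(testable, ratio, np.nan),
        "p": p,
        "p_adj": p_adj,
        "contributing_genes": contrib,
    })


def gene_loss_overlap(gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Venn-region counts of per-cluster gene sets.

    ``gene_sets`` maps cluster → genes contributing to significant families.
    Returns one row per non-empty cluster combination with the number of
    genes belonging to exactly that combination.
    """
    clusters = sorted(gene_sets)
    membership: dict[str, frozenset[str]] = {}
    for c in clusters:
        for g in gene_sets[c]:
            membership[g] = membership.get(g, frozenset()) | {c}
    from itertools import combinations

    rows = []
    for r in range(1, len(clusters) + 1):
        for combo in combinations(clusters, r):
            region = frozenset(combo)
            count = sum(1 for m in membership.values() if m == region)
            rows.append({"clusters": "&".join(combo), "exclusive_count": count})
    return pd.DataFrame(rows, columns=["clusters", "exclusive_count"])
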