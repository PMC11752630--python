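"""Synthetic single-cell APA + regulatory-network data with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, end to end:

* cluster-structured negative-binomial gene expression (Dirichlet-split
  across a gene's polyA-site isoforms, so gene expression is exactly the
  isoform sum);
* a configurable fraction of genes with 2–4 APA sites (default 16.6%,
  the remainder single-site);
* microRNA-family binding sites placed uniformly along each 3'UTR;
* planted "avoidance" effects — in a chosen cluster, a usage shift δ moves
  isoform mass of dedicated carrier genes to the most proximal cleavage
  site, deleting the planted family's distal sites from the expressed
  isoforms;
* a random four-kind regulatory graph with planted coherent feed-forward
  loops whose three nodes share a latent factor (target pairwise
  correlation ρ) and a cluster-specific mean shift.

Planted avoidance effects live on *private* carrier genes that receive no
background binding sites, so every non-planted family stays truly null —
without this, a usage shift in a shared gene would silently create real
avoidance for other families and ground truth would be ill-defined.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as amio
from .datatypes import (
    ApaMatrix,
    ClusterAssignment,
    ExpressionMatrix,
    ValidationError,
    validate_binding_sites,
    validate_interactions,
)

__all__ = [
    "SyntheticConfig",
    "PlantedAvoidance",
    "PlantedFFL",
    "SyntheticDataset",
    "generate_regulatory_graph",
    "generate_apa_annotation",
    "generate_cells",
    "generate_dataset",
]

SITE_LEN = 7  # seed-match footprint of a microRNA-binding site, bases


@dataclass
class PlantedAvoidance:
    cluster: str
    family: str
    delta: float  # usage mass moved to the most proximal site, in (0, 1]


@dataclass
class PlantedFFL:
    cluster: str
    mirna: str
    tf: str
    gene: str
    rho: float        # target pairwise correlation of the three nodes
    de_effect: float  # fold change of the three nodes' means in the cluster
    cls: str = "mirna_centric"


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults describe a two-cluster desk-scale study."""

    n_clusters: int = 2
    cells_per_cluster: int = 200
    n_genes: int = 300
    n_tfs: int = 20
    n_mirna_families: int = 60
    frac_multi_apa: float = 0.166
    utr_length_range: tuple[int, int] = (500, 2000)
    sites_per_multi_gene: tuple[int, int] = (2, 4)
    mean_binding_sites_per_family: float = 0.05  # Poisson rate per (family, gene)
    nb_mean: float = 2.0
    nb_dispersion: float = 0.5  # NB size r; var = mu + mu^2 / r
    n_marker_genes_per_cluster: int = 10
    marker_log2fc: float = 1.0
    planted_avoidance: list[PlantedAvoidance] = field(default_factory=list)
    planted_ffls: list[PlantedFFL] = field(default_factory=list)
    n_private_genes_per_planted: int = 3
    sites_per_private_gene: int = 2
    edge_prob: dict = field(default_factory=lambda: {
        "mirna_gene": 0.05, "mirna_tf": 0.05, "tf_gene": 0.05, "tf_mirna": 0.05,
    })
    mirna_expression: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        errs = []
        if not (0.0 <= self.frac_multi_apa <= 1.0):
            errs.append("frac_multi_apa must be in [0, 1]")
        for pa in self.planted_avoidance:
            if not (0.0 < pa.delta <= 1.0):
                errs.append(f"delta must be in (0, 1]: {pa}")
        for pf in self.planted_ffls:
            if not (0.0 < pf.rho <= 1.0):
                errs.append(f"rho must be in (0, 1]: {pf}")
        for name in ("n_clusters", "cells_per_cluster", "n_genes", "n_tfs",
                     "n_mirna_families"):
            if getattr(self, name) < 1:
                errs.append(f"{name} must be >= 1")
        lo, hi = self.utr_length_range
        smax = self.sites_per_multi_gene[1]
        if lo < max(SITE_LEN + 1, smax + 1):
            errs.append("utr_length_range too short to place sites and "
                        "distinct cleavage positions")
        if errs:
            raise ValidationError("; ".join(errs))

    # -- deterministic ID spaces -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(self.n_tfs)]

    @property
    def family_ids(self) -> list[str]:
        return [f"MIRF{i:03d}" for i in range(self.n_mirna_families)]

    @property
    def cluster_labels(self) -> list[str]:
        return [f"C{i}" for i in range(self.n_clusters)]


@dataclass
class GroundTruth:
    planted_avoidance: list[PlantedAvoidance]
    planted_ffls: list[PlantedFFL]
    private_genes: dict[str, list[str]]  # "cluster|family" -> carrier genes
    usage: dict[str, dict[str, list[float]]]  # cluster -> gene -> usage vector

    def to_json(self) -> str:
        return json.dumps({
            "planted_avoidance": [asdict(p) for p in self.planted_avoidance],
            "planted_ffls": [asdict(p) for p in self.planted_ffls],
            "private_genes": self.private_genes,
            "usage": self.usage,
        }, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    apa: ApaMatrix
    clusters: ClusterAssignment
    binding_sites: pd.DataFrame
    interactions: pd.DataFrame
    ground_truth: GroundTruth

    def write(self, out_dir: Path | str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        amio.write_expression_mtx(self.expression, out / "expression")
        amio.write_apa_matrix(self.apa, out / "apa")
        amio.write_clusters_tsv(self.clusters, out / "clusters.tsv")
        amio.write_binding_sites_tsv(self.binding_sites, out / "binding_sites.tsv")
        amio.write_interactions_tsv(self.interactions, out / "interactions.tsv")
        (out / "ground_truth.json").write_text(self.ground_truth.to_json())


# ---------------------------------------------------------------------------
# stage 1: regulatory graph


def generate_regulatory_graph(config: SyntheticConfig, rng: np.random.Generator,
                              ) -> tuple[pd.DataFrame, list[PlantedFFL]]:
    """Random four-kind interaction table with planted FFL edges forced in."""
    rows = []

    def block(sources, stype, targets, ttype, prob):
        if prob <= 0:
            return
        hits = rng.random((len(sources), len(targets))) < prob
        for i, j in zip(*np.nonzero(hits)):
            if sources[i] != targets[j]:
                rows.append((sources[i], stype, targets[j], ttype))

    ep = config.edge_prob
    fams, tfs, genes = config.family_ids, config.tf_ids, config.gene_ids
    block(fams, "miRNA", genes, "gene", ep.get("mirna_gene", 0.0))
    block(fams, "miRNA", tfs, "TF", ep.get("mirna_tf", 0.0))
    block(tfs, "TF", genes, "gene", ep.get("tf_gene", 0.0))
    block(tfs, "TF", fams, "miRNA", ep.get("tf_mirna", 0.0))
    for pf in config.planted_ffls:
        rows.append((pf.mirna, "miRNA", pf.gene, "gene"))
        rows.append((pf.tf, "TF", pf.gene, "gene"))
        if pf.cls in ("mirna_centric", "feedback"):
            rows.append((pf.mirna, "miRNA", pf.tf, "TF"))
        if pf.cls in ("tf_centric", "feedback"):
            rows.append((pf.tf, "TF", pf.mirna, "miRNA"))
    table = pd.DataFrame(rows, columns=["source_id", "source_type",
                                        "target_id", "target_type"])
    return validate_interactions(table), list(config.planted_ffls)


# ---------------------------------------------------------------------------
# stage 2: APA annotation + binding sites


@dataclass
class ApaAnnotation:
    site_meta: pd.DataFrame        # gene_id, site_id, cleavage_pos (sorted)
    binding_sites: pd.DataFrame
    utr_length: dict[str, int]
    private_genes: dict[str, list[str]]  # "cluster|family" -> genes


def generate_apa_annotation(config: SyntheticConfig, rng: np.random.Generator,
                            ) -> ApaAnnotation:
    """Cleavage-site metadata and binding-site table.

    ``round(frac_multi_apa * n_genes)`` genes get 2–4 increasing cleavage
    positions (the most distal at the UTR end, i.e. a full-length isoform);
    the rest get one. Binding sites are placed uniformly with Poisson counts
    per (family, gene); none straddles the UTR end. Planted-avoidance carrier
    genes are drawn from the multi-site genes, receive only the planted
    family's sites, and those sites lie distal to the most proximal cleavage
    position so the usage shift deletes them.
    """
    genes = config.gene_ids
    utr_len = {g: int(rng.integers(*config.utr_length_range)) for g in genes}
    n_multi = int(round(config.frac_multi_apa * config.n_genes))
    multi = [str(g) for g in rng.choice(genes, size=n_multi, replace=False)] \
        if n_multi else []
    multi_set = set(multi)

    # assign private carrier genes to planted avoidance pairs
    private: dict[str, list[str]] = {}
    pool = list(multi)
    for pa in config.planted_avoidance:
        k = min(config.n_private_genes_per_planted, len(pool))
        if k == 0:
            raise ValidationError(
                "not enough multi-APA genes to assign private carriers")
        chosen = [pool.pop(0) for _ in range(k)]
        private[f"{pa.cluster}|{pa.family}"] = chosen
    all_private = {g for gs in private.values() for g in gs}

    lo_sites, hi_sites = config.sites_per_multi_gene
    meta_rows = []
    cleavages: dict[str, list[int]] = {}
    for g in genes:
        L = utr_len[g]
        if g in multi_set:
            k = int(rng.integers(lo_sites, hi_sites + 1))
            inner = sorted(rng.choice(np.arange(1, L), size=k - 1, replace=False))
            pos = [int(p) for p in inner] + [L]
        else:
            pos = [L]
        cleavages[g] = pos
        for j, p in enumerate(pos):
            meta_rows.append({"gene_id": g, "site_id": f"{g}:PA{j}",
                              "cleavage_pos": p})
    site_meta = pd.DataFrame(meta_rows)

    bs_rows = []
    lam = config.mean_binding_sites_per_family
    if lam > 0:
        for f in config.family_ids:
            counts = rng.poisson(lam, size=len(genes))
            for g, c in zip(genes, counts):
                if c == 0 or g in all_private:
                    continue
                hi = utr_len[g] - SITE_LEN
                if hi < 0:
                    raise ValidationError(f"UTR of {g} too short for a site")
                for start in rng.integers(0, hi + 1, size=c):
                    bs_rows.append((f, g, int(start), int(start) + SITE_LEN))
    for pa in config.planted_avoidance:
        for g in private[f"{pa.cluster}|{pa.family}"]:
            proximal = cleavages[g][0]
            hi = utr_len[g] - SITE_LEN
            lo = min(proximal, hi)
            for start in rng.integers(lo, hi + 1,
                                      size=config.sites_per_private_gene):
                bs_rows.append((pa.family, g, int(start), int(start) + SITE_LEN))
    bs = pd.DataFrame(bs_rows, columns=["family_id", "gene_id", "start", "end"])
    bs = bs.drop_duplicates().reset_index(drop=True)
    if len(bs):
        bs = validate_binding_sites(bs)
    return ApaAnnotation(site_meta=site_meta, binding_sites=bs,
                         utr_length=utr_len, private_genes=private)


# ---------------------------------------------------------------------------
# stage 3: cells


def generate_cells(config: SyntheticConfig, interactions: pd.DataFrame,
                   annotation: ApaAnnotation, rng: np.random.Generator,
                   ) -> tuple[ExpressionMatrix, ApaMatrix, ClusterAssignment,
                              GroundTruth]:
    """Draw the expression and APA matrices plus cluster labels.

    Gene totals are negative binomial with cluster-specific means; each
    multi-site gene's total is split across isoforms by a Dirichlet-drawn
    usage vector, shifted toward the most proximal site for planted
    avoidance pairs. Planted FFL triples share a per-cell latent factor on
    the log-mean scale (target correlation ρ) and a fold change
    ``de_effect`` for the cluster-vs-rest contrast. Gene expression equals
    the isoform sum by construction.
    """
    labels = config.cluster_labels
    n_cells = config.n_clusters * config.cells_per_cluster
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    cluster_of = np.repeat(np.arange(config.n_clusters), config.cells_per_cluster)
    clusters = ClusterAssignment(pd.Series(
        [labels[c] for c in cluster_of], index=cell_ids))

    genes = config.gene_ids
    rows = list(genes) + list(config.tf_ids)
    fam_rows = list(config.family_ids) if config.mirna_expression else []
    rows = rows + fam_rows
    row_idx = {r: i for i, r in enumerate(rows)}
    n_rows = len(rows)

    base_logmu = rng.normal(math.log(config.nb_mean), 0.5, size=n_rows)
    logmu = np.tile(base_logmu[:, None], (1, config.n_clusters))
    # cluster marker structure
    lfc = config.marker_log2fc * math.log(2.0)
    for c in range(config.n_clusters):
        k = min(config.n_marker_genes_per_cluster, n_rows)
        if k > 0 and lfc != 0.0:
            marker_rows = rng.choice(n_rows, size=k, replace=False)
            logmu[marker_rows, c] += lfc
    for pf in config.planted_ffls:
        c = labels.index(pf.cluster)
        for node in (pf.mirna, pf.tf, pf.gene):
            if node in row_idx:
                logmu[row_idx[node], c] += math.log(pf.de_effect)

    # per-cell log-mean with planted latent factors
    log_mu_cells = logmu[:, cluster_of]
    s0 = 0.7  # nominal log-scale noise sd used to size the shared factor
    for pf in config.planted_ffls:
        c = labels.index(pf.cluster)
        lam = math.sqrt(pf.rho / (1.0 - pf.rho + 1e-12)) * s0
        in_cluster = cluster_of == c
        u = rng.normal(0.0, 1.0, size=int(in_cluster.sum()))
        for node in (pf.mirna, pf.tf, pf.gene):
            if node in row_idx:
                log_mu_cells[row_idx[node], in_cluster] += lam * u - lam * lam / 2.0

    mu = np.exp(log_mu_cells)
    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    # isoform usage
    meta = annotation.site_meta
    usage_truth: dict[str, dict[str, list[float]]] = {lab: {} for lab in labels}
    shift = {}  # gene -> (cluster index, delta)
    for pa in config.planted_avoidance:
        for g in annotation.private_genes[f"{pa.cluster}|{pa.family}"]:
            shift[g] = (labels.index(pa.cluster), pa.delta)

    apa_values = np.zeros((len(meta), n_cells))
    iso_rows_of: dict[str, np.ndarray] = {
        g: grp.index.to_numpy() for g, grp in meta.groupby("gene_id")
    }
    for g in genes:
        iso = iso_rows_of[g]
        gi = row_idx[g]
        if len(iso) == 1:
            apa_values[iso[0]] = counts[gi]
            for lab in labels:
                usage_truth[lab][g] = [1.0]
            continue
        base_usage = rng.dirichlet(np.full(len(iso), 2.0))
        for c, lab in enumerate(labels):
            u = base_usage.copy()
            if g in shift and shift[g][0] == c:
                delta = shift[g][1]
                onehot = np.zeros_like(u)
                onehot[0] = 1.0  # meta rows are ordered proximal -> distal
                u = (1.0 - delta) * u + delta * onehot
            usage_truth[lab][g] = [float(x) for x in u]
            cells_c = np.nonzero(cluster_of == c)[0]
            tot = counts[gi, cells_c]
            draws = rng.multinomial(tot, u)
            apa_values[np.ix_(iso, cells_c)] = draws.T

    # gene rows equal the isoform sum (exact conservation)
    values = counts.astype(float)
    for g in genes:
        values[row_idx[g]] = apa_values[iso_rows_of[g]].sum(axis=0)

    expr = ExpressionMatrix(values=values, gene_ids=rows, cell_ids=cell_ids)
    apa = ApaMatrix(values=apa_values, site_meta=meta, cell_ids=cell_ids)
    gt = GroundTruth(
        planted_avoidance=list(config.planted_avoidance),
        planted_ffls=list(config.planted_ffls),
        private_genes=annotation.private_genes,
        usage=usage_truth,
    )
    _check_ground_truth(config, interactions, annotation, apa, gt)
    return expr, apa, clusters, gt


def _check_ground_truth(config, interactions, annotation, apa, gt) -> None:
    edges = set(zip(interactions["source_id"], interactions["target_id"]))
    for pf in gt.planted_ffls:
        need = [(pf.mirna, pf.gene), (pf.tf, pf.gene)]
        if pf.cls in ("mirna_centric", "feedback"):
            need.append((pf.mirna, pf.tf))
        if pf.cls in ("tf_centric", "feedback"):
            need.append((pf.tf, pf.mirna))
        for e in need:
            if e not in edges:
                raise ValidationError(f"planted FFL edge missing: {e}")
    bs = annotation.binding_sites
    multi = apa.genes_with_multiple_sites()
    proximal = annotation.site_meta.groupby("gene_id")["cleavage_pos"].min()
    for pa in gt.planted_avoidance:
        fam_sites = bs[bs["family_id"] == pa.family]
        ok = any(
            row.gene_id in multi and row.end > proximal[row.gene_id]
            for row in fam_sites.itertuples()
        )
        if not ok:
            raise ValidationError(
                f"planted family {pa.family} has no distal site in a "
                f"multi-APA gene")


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run the three generation stages under one seeded RNG."""
    rng = np.random.default_rng(config.seed)
    interactions, _ = generate_regulatory_graph(config, rng)
    annotation = generate_apa_annotation(config, rng)
    expr, apa, clusters, gt = generate_cells(config, interactions, annotation, rng)
    return SyntheticDataset(
        expression=expr, apa=apa, clusters=clusters,
        binding_sites=annotation.binding_sites, interactions=interactions,
        ground_truth=gt,
    )
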