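"""Calibration and recovery studies on synthetic data.

These routines define the standard self-evaluation scenarios of the package:
null calibration of the two permutation tests (is the raw p-value uniform
when nothing is planted?), and power/recovery under planted effects. They
are used by the test suite and by the reproduction script.

Scenario sizes are desk-scale study conditions: two clusters of 200 cells,
1000 permutations per test. Calibration scenarios use an exchangeable null
(no cluster-specific expression means), the null hypothesis the
label-shuffling procedure actually addresses; see the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ks_1samp, uniform

from .avoidance import avoidance_permutation_test, substream
from .cluster_stats import expressed_genes, wilcoxon_de
from .datatypes import PipelineConfig
from .ffl import (
    apply_expression_filter,
    build_background_graph,
    enumerate_sffls,
    nodes_of_type,
)
from .scoring import build_cluster_context, sffl_permutation_test
from .synthetic import PlantedAvoidance, PlantedFFL, SyntheticConfig, generate_dataset

ALPHA = 0.05


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# avoidance


def avoidance_null_calibration(seed: int, n_permutations: int = 1000) -> dict:
    """Raw avoidance p-values under a fully exchangeable null.

    Two clusters × 200 cells, ~1000 testable (family, cluster) pairs,
    nothing planted and no cluster-specific expression. Reports the fraction
    of raw p < 0.05 and the Kolmogorov–Smirnov distance to Uniform(0,1).
    """
    cfg = SyntheticConfig(seed=seed, n_genes=1200, n_mirna_families=500,
                          n_marker_genes_per_cluster=0)
    ds = generate_dataset(cfg)
    pc = PipelineConfig(n_permutations=n_permutations, seed=seed)
    ps: list[float] = []
    for cl in ds.clusters.clusters:
        res = avoidance_permutation_test(ds.apa, ds.binding_sites,
                                         ds.clusters, cl, pc)
        ps.extend(res["p"].dropna().tolist())
    p = np.asarray(ps)
    return {
        "n_pairs": int(p.size),
        "frac_below_alpha": float((p < ALPHA).mean()),
        "ks_distance": float(ks_1samp(p, uniform.cdf).statistic),
    }


def _power_planting() -> list[PlantedAvoidance]:
    return ([PlantedAvoidance("C0", f"MIRF{i:03d}", 0.8) for i in range(5)]
            + [PlantedAvoidance("C1", f"MIRF{i:03d}", 0.8)
               for i in range(5, 10)])


def avoidance_power(seed: int, n_replicates: int = 20,
                    n_permutations: int = 1000) -> dict:
    """Recovery of 10 planted (cluster, family, δ=0.8) pairs over replicates.

    Reports the fraction of planted pairs recovered at BH-adjusted p < 0.05,
    and for each non-planted (cluster, family) pair the worst significance
    rate across replicates (should not exceed alpha plus 3 binomial sd).
    """
    planted = _power_planting()
    planted_keys = {(p.cluster, p.family) for p in planted}
    recovered = 0
    total = 0
    null_hits: dict[tuple[str, str], int] = {}
    for rep_seed in _child_seeds(seed, n_replicates):
        cfg = SyntheticConfig(seed=rep_seed, planted_avoidance=planted,
                              n_marker_genes_per_cluster=0)
        ds = generate_dataset(cfg)
        pc = PipelineConfig(n_permutations=n_permutations, seed=rep_seed)
        for cl in ds.clusters.clusters:
            res = avoidance_permutation_test(ds.apa, ds.binding_sites,
                                             ds.clusters, cl, pc)
            tested = res[res["p_adj"].notna()]
            sig = set(tested.loc[tested["p_adj"] < ALPHA, "family_id"])
            for fam in tested["family_id"]:
                key = (cl, fam)
                if key in planted_keys:
                    total += 1
                    recovered += fam in sig
                elif fam in sig:
                    null_hits[key] = null_hits.get(key, 0) + 1
    # rate per replicate: a family untestable in a replicate was not
    # significant in that replicate
    worst_null_rate = max(null_hits.values(), default=0) / n_replicates
    return {
        "n_planted_tested": total,
        "recovery_rate": recovered / total if total else 0.0,
        "worst_null_family_rate": float(worst_null_rate),
        "null_rate_bound": ALPHA + 3 * np.sqrt(ALPHA * (1 - ALPHA)
                                               / n_replicates),
    }


# ---------------------------------------------------------------------------
# SFFL scoring


def _score_cluster(ds, cl: str, pc: PipelineConfig):
    expr = ds.expression
    keep = expressed_genes(expr, ds.clusters, cl, pc.min_expr_frac)
    de = wilcoxon_de(expr, ds.clusters, cl)
    graph = build_background_graph([ds.interactions])
    sffls = enumerate_sffls(graph)
    gene_rows = set(expr.gene_ids)
    mirnas_with_rows = {n for n in nodes_of_type(graph, "miRNA")
                        if n in gene_rows}
    cands = apply_expression_filter(sffls, keep, cl, mirnas_with_rows)
    if not cands:
        return []
    ctx = build_cluster_context(expr, ds.clusters, cl, de)
    pools = {
        "miRNA": sorted({n for n in nodes_of_type(graph, "miRNA")
                         if n not in gene_rows or n in keep}),
        "TF": sorted({n for n in nodes_of_type(graph, "TF") if n in keep}),
        "gene": sorted({n for n in nodes_of_type(graph, "gene") if n in keep}),
    }
    return sffl_permutation_test(cands, ctx, pools, pc,
                                 rng=substream(pc.seed, "sffl", cl))


_DENSE_EDGES = {"mirna_gene": 0.15, "mirna_tf": 0.05,
                "tf_gene": 0.15, "tf_mirna": 0.05}


def sffl_null_calibration(seed: int, n_permutations: int = 1000) -> dict:
    """Raw SFFL permutation p-values with no planted coherence.

    A dense random graph gives several hundred candidate SFFLs per cluster;
    with no planted latent factor the observed triples are exchangeable with
    the random-pool triples and the raw p should be uniform.
    """
    cfg = SyntheticConfig(seed=seed, edge_prob=dict(_DENSE_EDGES),
                          n_marker_genes_per_cluster=0)
    ds = generate_dataset(cfg)
    pc = PipelineConfig(n_permutations=n_permutations, seed=seed)
    ps: list[float] = []
    for cl in ds.clusters.clusters:
        ps.extend(s.p for s in _score_cluster(ds, cl, pc) if s.p is not None)
    p = np.asarray(ps)
    return {
        "n_sffls": int(p.size),
        "frac_below_alpha": float((p < ALPHA).mean()),
        "ks_distance": float(ks_1samp(p, uniform.cdf).statistic),
    }


def _recovery_planting() -> list[PlantedFFL]:
    return [PlantedFFL("C0", f"MIRF{i:03d}", f"TF{i:03d}", f"G{i:04d}",
                       rho=0.9, de_effect=4.0) for i in range(5)]


def sffl_recovery(seed: int, n_replicates: int = 20,
                  n_permutations: int = 1000) -> dict:
    """Recovery of planted coherent FFLs (ρ = 0.9, 4-fold DE) over replicates.

    Reports the fraction of (replicate, planted triple) pairs significant at
    BH-adjusted p < 0.05 and the pooled significant fraction among
    non-planted candidates.
    """
    planted = _recovery_planting()
    planted_keys = {(p.mirna, p.tf, p.gene) for p in planted}
    recovered = total = 0
    null_sig = null_total = 0
    for rep_seed in _child_seeds(seed, n_replicates):
        cfg = SyntheticConfig(seed=rep_seed, planted_ffls=planted)
        ds = generate_dataset(cfg)
        pc = PipelineConfig(n_permutations=n_permutations, seed=rep_seed)
        scored = _score_cluster(ds, "C0", pc)
        for s in scored:
            sig = s.p_adj is not None and s.p_adj < ALPHA
            if (s.mirna, s.tf, s.gene) in planted_keys:
                total += 1
                recovered += sig
            else:
                null_total += 1
                null_sig += sig
    return {
        "n_planted_tested": total,
        "recovery_rate": recovered / total if total else 0.0,
        "null_sig_frac": null_sig / null_total if null_total else 0.0,
        "n_null": null_total,
    }
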