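"""End-to-end orchestration: simulate/load → filter → DE → avoidance →
FFL build → FFL score → annotate → write, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as amio
from .avoidance import avoidance_permutation_test, gene_loss_overlap, substream
from .cluster_stats import expressed_genes, wilcoxon_de
from .datatypes import PipelineConfig
from .ffl import (
    apply_expression_filter,
    build_background_graph,
    enumerate_sffls,
    merge_mffls,
    nodes_of_type,
    sffls_to_frame,
)
from .scoring import annotate_apa_loss, build_cluster_context, sffl_permutation_test
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("apamirnet")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig,
                 sim_config: SyntheticConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run every stage in dependency order and write results + manifest.

    With ``sim_config`` given, inputs are simulated; otherwise they are
    loaded from ``config.paths``. Returns the manifest dictionary.
    """
    out = Path(out_dir or config.out_dir or "apamirnet_out")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "seed": config.seed, "stages": {}}

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {
                "wall_time_s": round(time.perf_counter() - t0, 3), **counts}
            log.info("stage=%s %s", name, counts)
        return done

    # -- inputs -------------------------------------------------------------
    fin = stage("inputs")
    if sim_config is not None:
        ds = generate_dataset(sim_config)
        ds.write(out / "inputs")
        bundle = {
            "expression": ds.expression, "apa": ds.apa,
            "clusters": ds.clusters, "binding_sites": ds.binding_sites,
            "interactions": ds.interactions, "embedding": None,
        }
    else:
        bundle = amio.load_dataset(config.paths, config)
    expr = bundle["expression"]
    apa = bundle["apa"]
    clusters = bundle["clusters"]
    clusters.validate_against(expr.cell_ids)
    fin(n_genes=expr.n_genes, n_cells=expr.n_cells,
        n_clusters=len(clusters.clusters))

    # -- per-cluster filter + DE -------------------------------------------
    fin = stage("filter_de")
    expressed = {}
    de_tables = []
    for cl in clusters.clusters:
        expressed[cl] = expressed_genes(expr, clusters, cl, config.min_expr_frac)
        de_tables.append(wilcoxon_de(expr, clusters, cl))
    de = pd.concat(de_tables, ignore_index=True)
    de.to_csv(out / "de.tsv", sep="\t", index=False)
    fin(genes_pass_filter={cl: len(s) for cl, s in expressed.items()})

    # -- avoidance ----------------------------------------------------------
    fin = stage("avoidance")
    avoid_tables = []
    if apa is not None and bundle["binding_sites"] is not None:
        for cl in clusters.clusters:
            eligible = apa.genes_with_multiple_sites() & expressed[cl]
            res = avoidance_permutation_test(
                apa, bundle["binding_sites"], clusters, cl, config,
                rng=substream(config.seed, "avoidance", cl),
                eligible_genes=eligible)
            avoid_tables.append(res)
    avoidance = (pd.concat(avoid_tables, ignore_index=True)
                 if avoid_tables else pd.DataFrame(
                     columns=["cluster", "family_id", "lost", "retained",
                              "statistic", "p", "p_adj", "contributing_genes"]))
    amio.write_avoidance_results(
        avoidance.drop(columns=["ratio"], errors="ignore")
                 .drop(columns=["contributing_genes"], errors="ignore"),
        out / "avoidance.tsv")
    sig_av = avoidance[avoidance["p_adj"] < config.alpha] if len(avoidance) else avoidance
    gene_sets = {
        cl: set(g for gl in sig_av[sig_av["cluster"] == cl]["contributing_genes"]
                for g in gl)
        for cl in clusters.clusters
    } if len(sig_av) else {}
    if gene_sets:
        gene_loss_overlap(gene_sets).to_csv(out / "gene_loss_overlap.tsv",
                                            sep="\t", index=False)
    fin(families_tested=int(avoidance["p"].notna().sum()) if len(avoidance) else 0,
        families_significant=int(len(sig_av)))

    # -- FFL build + score --------------------------------------------------
    fin = stage("ffl")
    all_sffl_rows = []
    all_mffls: list[dict] = []
    n_enum = 0
    if bundle["interactions"] is not None:
        graph = build_background_graph([bundle["interactions"]])
        sffls = enumerate_sffls(graph)
        n_enum = len(sffls)
        gene_rows = set(expr.gene_ids)
        mirnas_with_rows = {n for n in nodes_of_type(graph, "miRNA")
                            if n in gene_rows}
        for cl in clusters.clusters:
            cands = apply_expression_filter(
                sffls, expressed[cl], cl, mirnas_with_rows)
            if not cands:
                continue
            ctx = build_cluster_context(expr, clusters, cl, de)
            pools = {
                "miRNA": sorted({n for n in nodes_of_type(graph, "miRNA")
                                 if n not in gene_rows or n in expressed[cl]}),
                "TF": sorted({n for n in nodes_of_type(graph, "TF")
                              if n in expressed[cl]}),
                "gene": sorted({n for n in nodes_of_type(graph, "gene")
                                if n in expressed[cl]}),
            }
            scored = sffl_permutation_test(
                cands, ctx, pools, config,
                rng=substream(config.seed, "sffl", cl))
            sig = [s for s in scored
                   if s.p_adj is not None and s.p_adj < config.alpha]
            mffls = merge_mffls(sig, cl)
            av_cl = avoidance[avoidance["cluster"] == cl] if len(avoidance) else avoidance
            scored, mffl_dicts = annotate_apa_loss(scored, mffls, av_cl,
                                                   config.alpha)
            all_sffl_rows.append(sffls_to_frame(scored))
            all_mffls.extend(mffl_dicts)
    sffl_frame = (pd.concat(all_sffl_rows, ignore_index=True)
                  if all_sffl_rows else sffls_to_frame([]))
    amio.write_network_results(sffl_frame, all_mffls, out)
    fin(sffls_enumerated=n_enum, sffls_candidate=int(len(sffl_frame)),
        sffls_significant=int((sffl_frame["p_adj"] < config.alpha).sum())
        if len(sffl_frame) else 0,
        mffls=len(all_mffls))

    # -- manifest -----------------------------------------------------------
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*"))
        if p.is_file() and p.suffix in (".tsv", ".json")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
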