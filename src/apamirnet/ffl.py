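"""Regulatory-graph assembly and feed-forward-loop enumeration.

A simple feed-forward loop (SFFL) is a (microRNA, TF, gene) triple in which
both regulators target the gene and at least one regulates the other:

* miRNA-centric — miRNA→TF present, TF→miRNA absent;
* TF-centric   — TF→miRNA present, miRNA→TF absent;
* feedback     — both cross-edges present.

Module feed-forward loops (MFFLs) merge all significant SFFLs sharing a
center node: miRNA-centric SFFLs group by their miRNA, TF-centric ones by
their TF, and feedback SFFLs contribute to both groupings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .datatypes import ValidationError, validate_interactions

__all__ = [
    "SFFL",
    "MFFL",
    "build_background_graph",
    "enumerate_sffls",
    "apply_expression_filter",
    "merge_mffls",
]

_KIND_OF = {
    ("miRNA", "gene"): "mirna_gene",
    ("miRNA", "TF"): "mirna_tf",
    ("TF", "gene"): "tf_gene",
    ("TF", "miRNA"): "tf_mirna",
}


@dataclass
class SFFL:
    mirna: str
    tf: str
    gene: str
    cls: str  # mirna_centric | tf_centric | feedback
    cluster: str | None = None
    score: float | None = None
    p: float | None = None
    p_adj: float | None = None
    apa_loss_flag: bool | None = None

    @property
    def has_mirna_to_tf(self) -> bool:
        return self.cls in ("mirna_centric", "feedback")

    @property
    def has_tf_to_mirna(self) -> bool:
        return self.cls in ("tf_centric", "feedback")

    def key(self) -> tuple[str, str, str]:
        return (self.mirna, self.tf, self.gene)


@dataclass
class MFFL:
    cluster: str | None
    center: str
    center_type: str  # "miRNA" or "TF"
    members: list[SFFL] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for s in self.members:
            out |= {s.mirna, s.tf, s.gene}
        return out

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster,
            "center": self.center,
            "center_type": self.center_type,
            "members": [list(s.key()) for s in self.members],
            "nodes": sorted(self.nodes),
        }


def build_background_graph(tables: list[pd.DataFrame]) -> nx.DiGraph:
    """Union of validated interaction tables as a typed directed graph.

    Node types (miRNA / TF / gene) are inferred from edge kinds; a node with
    conflicting types across rows is an error naming the offenders.
    """
    merged = pd.concat([validate_interactions(t) for t in tables],
                       ignore_index=True).drop_duplicates().reset_index(drop=True)
    types: dict[str, set[str]] = {}
    for _, row in merged.iterrows():
        types.setdefault(row.source_id, set()).add(row.source_type)
        types.setdefault(row.target_id, set()).add(row.target_type)
    conflicts = sorted(n for n, ts in types.items() if len(ts) > 1)
    if conflicts:
        detail = {n: sorted(types[n]) for n in conflicts[:5]}
        raise ValidationError(f"nodes with conflicting types: {detail}")
    g = nx.DiGraph()
    for n, ts in types.items():
        g.add_node(n, ntype=next(iter(ts)))
    for _, row in merged.iterrows():
        g.add_edge(row.source_id, row.target_id,
                   kind=_KIND_OF[(row.source_type, row.target_type)])
    return g


def nodes_of_type(graph: nx.DiGraph, ntype: str) -> list[str]:
    return sorted(n for n, d in graph.nodes(data=True) if d["ntype"] == ntype)


def enumerate_sffls(graph: nx.DiGraph) -> list[SFFL]:
    """All (miRNA, TF, gene) triples with m→g, t→g and >= 1 cross-edge.

    Output is deterministic: sorted by (mirna, tf, gene).
    """
    mirnas = nodes_of_type(graph, "miRNA")
    tfs = nodes_of_type(graph, "TF")
    succ = {n: set(graph.successors(n)) for n in graph.nodes}
    gene_targets = {
        n: {t for t in succ[n] if graph.nodes[t]["ntype"] == "gene"}
        for n in mirnas + tfs
    }
    out: list[SFFL] = []
    for m in mirnas:
        for t in tfs:
            m_to_t = t in succ[m]
            t_to_m = m in succ[t]
            if not (m_to_t or t_to_m):
                continue
            if m_to_t and t_to_m:
                cls = "feedback"
            elif m_to_t:
                cls = "mirna_centric"
            else:
                cls = "tf_centric"
            for g in sorted(gene_targets[m] & gene_targets[t]):
                out.append(SFFL(mirna=m, tf=t, gene=g, cls=cls))
    out.sort(key=lambda s: s.key())
    return out


def apply_expression_filter(sffls: list[SFFL], expressed: set[str],
                            cluster: str,
                            mirnas_with_expression: set[str] | None = None,
                            ) -> list[SFFL]:
    """Keep SFFLs whose TF and gene pass the cluster's prevalence filter.

    The miRNA must pass only when it has an expression row
    (``mirnas_with_expression``); miRNAs absent from the expression matrix —
    the usual situation for small RNAs in scRNA-seq — are exempt and stay in
    the analysis with their node dropped at scoring time.
    """
    kept = []
    for s in sffls:
        if s.tf not in expressed or s.gene not in expressed:
            continue
        if (mirnas_with_expression is not None
                and s.mirna in mirnas_with_expression
                and s.mirna not in expressed):
            continue
        kept.append(SFFL(mirna=s.mirna, tf=s.tf, gene=s.gene, cls=s.cls,
                         cluster=cluster))
    return kept


def merge_mffls(significant_sffls: list[SFFL], cluster: str | None = None) -> list[MFFL]:
    """Merge significant SFFLs sharing a center node into MFFLs.

    miRNA-centric SFFLs group by miRNA, TF-centric by TF; feedback SFFLs join
    both groupings. Singleton groups still form an MFFL. Output sorted by
    (center_type, center).
    """
    groups: dict[tuple[str, str], list[SFFL]] = {}
    for s in significant_sffls:
        if s.has_mirna_to_tf:
            groups.setdefault(("miRNA", s.mirna), []).append(s)
        if s.has_tf_to_mirna:
            groups.setdefault(("TF", s.tf), []).append(s)
    out = [MFFL(cluster=cluster, center=center, center_type=ctype,
                members=sorted(members, key=lambda s: s.key()))
           for (ctype, center), members in groups.items()]
    out.sort(key=lambda m: (m.center_type, m.center))
    return out


def sffls_to_frame(sffls: list[SFFL]) -> pd.DataFrame:
    """Tabular view matching the scored-SFFL TSV schema."""
    return pd.DataFrame({
        "cluster": [s.cluster for s in sffls],
        "family": [s.mirna for s in sffls],
        "tf": [s.tf for s in sffls],
        "gene": [s.gene for s in sffls],
        "class": [s.cls for s in sffls],
        "score": [s.score for s in sffls],
        "p": [s.p for s in sffls],
        "p_adj": [s.p_adj for s in sffls],
        "mirna_sites_lost_flag": [s.apa_loss_flag for s in sffls],
    })
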