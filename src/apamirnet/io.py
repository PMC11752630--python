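"""Readers and writers for the on-disk formats.

Matrices travel as MatrixMarket coordinate files with one-column gene/cell ID
lists, or as dense TSV with a header row of cell IDs for toy inputs. Tables
(clusters, binding sites, interactions, results) are plain TSV; configuration
is YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .datatypes import (
    ApaMatrix,
    ClusterAssignment,
    ExpressionMatrix,
    PipelineConfig,
    ValidationError,
    validate_binding_sites,
    validate_interactions,
)

# ---------------------------------------------------------------------------
# matrices


def write_expression_mtx(expr: ExpressionMatrix, prefix: Path | str) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.genes.tsv`` / ``<prefix>.cells.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.coo_matrix(expr.values))
    Path(str(prefix) + ".genes.tsv").write_text("\n".join(expr.gene_ids) + "\n")
    Path(str(prefix) + ".cells.tsv").write_text("\n".join(expr.cell_ids) + "\n")


def read_expression_mtx(prefix: Path | str, normalized: bool = False) -> ExpressionMatrix:
    prefix = Path(prefix)
    mtx = Path(str(prefix) + ".mtx")
    if not mtx.exists():
        raise FileNotFoundError(mtx)
    m = scipy.io.mmread(str(mtx))
    values = np.asarray(m.todense()) if scipy.sparse.issparse(m) else np.asarray(m)
    genes = Path(str(prefix) + ".genes.tsv").read_text().split()
    cells = Path(str(prefix) + ".cells.tsv").read_text().split()
    return ExpressionMatrix(values=values, gene_ids=genes, cell_ids=cells,
                            normalized=normalized)


def write_expression_tsv(expr: ExpressionMatrix, path: Path | str) -> None:
    """Dense TSV: first column gene IDs, header row cell IDs."""
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: Path | str, normalized: bool = False) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        normalized=normalized,
    )


def write_apa_matrix(apa: ApaMatrix, prefix: Path | str) -> None:
    """Write ``<prefix>.mtx`` + ``<prefix>.sites.tsv`` + ``<prefix>.cells.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.coo_matrix(apa.values))
    apa.site_meta.to_csv(str(prefix) + ".sites.tsv", sep="\t", index=False)
    Path(str(prefix) + ".cells.tsv").write_text("\n".join(apa.cell_ids) + "\n")


def read_apa_matrix(prefix: Path | str) -> ApaMatrix:
    prefix = Path(prefix)
    m = scipy.io.mmread(str(prefix) + ".mtx")
    values = np.asarray(m.todense()) if scipy.sparse.issparse(m) else np.asarray(m)
    meta = pd.read_csv(str(prefix) + ".sites.tsv", sep="\t",
                       dtype={"gene_id": str, "site_id": str})
    cells = Path(str(prefix) + ".cells.tsv").read_text().split()
    return ApaMatrix(values=values, site_meta=meta, cell_ids=cells)


# ---------------------------------------------------------------------------
# tables


def read_clusters_tsv(path: Path | str) -> ClusterAssignment:
    df = _read_table(path, ["cell_id", "cluster"])
    return ClusterAssignment(pd.Series(df["cluster"].values, index=df["cell_id"].values))


def write_clusters_tsv(clusters: ClusterAssignment, path: Path | str) -> None:
    df = pd.DataFrame({"cell_id": clusters.labels.index, "cluster": clusters.labels.values})
    df.to_csv(path, sep="\t", index=False)


def read_binding_sites_tsv(path: Path | str) -> pd.DataFrame:
    df = _read_table(path, ["family_id", "gene_id", "start", "end"])
    return validate_binding_sites(df)


def write_binding_sites_tsv(sites: pd.DataFrame, path: Path | str) -> None:
    validate_binding_sites(sites).to_csv(path, sep="\t", index=False)


def read_interactions_tsv(path: Path | str) -> pd.DataFrame:
    df = _read_table(path, ["source_id", "source_type", "target_id", "target_type"])
    return validate_interactions(df)


def write_interactions_tsv(interactions: pd.DataFrame, path: Path | str) -> None:
    validate_interactions(interactions).to_csv(path, sep="\t", index=False)


def read_embedding_tsv(path: Path | str) -> pd.DataFrame:
    """Cells × dimensions embedding; first column is the cell ID."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_embedding_tsv(embedding: pd.DataFrame, path: Path | str) -> None:
    embedding.to_csv(path, sep="\t", index_label="cell_id")


def _read_table(path: Path | str, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise ValidationError(f"malformed table {path}: {exc}") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# dataset bundle


def load_dataset(paths: dict, config: Optional[PipelineConfig] = None) -> dict:
    """Load and cross-validate a full input bundle.

    ``paths`` keys: ``expression`` (MTX prefix or dense .tsv), ``apa`` (MTX
    prefix), ``clusters``, ``binding_sites``, ``interactions`` (one path or a
    list), and optionally ``embedding``. Returns a dict with keys
    ``expression``, ``apa``, ``clusters``, ``binding_sites``, ``interactions``,
    ``embedding``.
    """
    expr_path = str(paths["expression"])
    if expr_path.endswith(".tsv"):
        expr = read_expression_tsv(expr_path)
    else:
        expr = read_expression_mtx(expr_path)
    apa = read_apa_matrix(paths["apa"]) if "apa" in paths else None
    clusters = read_clusters_tsv(paths["clusters"])
    sites = read_binding_sites_tsv(paths["binding_sites"]) if "binding_sites" in paths else None
    inter_paths = paths.get("interactions")
    if inter_paths is None:
        interactions = None
    else:
        if isinstance(inter_paths, (str, Path)):
            inter_paths = [inter_paths]
        interactions = pd.concat(
            [read_interactions_tsv(p) for p in inter_paths], ignore_index=True
        ).drop_duplicates().reset_index(drop=True)
    embedding = read_embedding_tsv(paths["embedding"]) if "embedding" in paths else None

    # cross-reference validation
    unknown = [c for c in clusters.labels.index if c not in set(expr.cell_ids)]
    if unknown:
        raise ValidationError(
            f"cluster assignment references unknown cells: {unknown[:5]}"
        )
    if apa is not None and apa.cell_ids != expr.cell_ids:
        raise ValidationError(
            "cell IDs of the APA matrix differ from the expression matrix "
            "(content and order must match)"
        )
    if embedding is not None:
        missing = [c for c in expr.cell_ids if c not in embedding.index]
        if missing:
            raise ValidationError(f"embedding missing cells: {missing[:5]}")
    return {
        "expression": expr,
        "apa": apa,
        "clusters": clusters,
        "binding_sites": sites,
        "interactions": interactions,
        "embedding": embedding,
    }


# ---------------------------------------------------------------------------
# results


AVOIDANCE_COLUMNS = ["cluster", "family", "lost", "retained", "statistic", "p", "p_adj"]


def write_avoidance_results(results: pd.DataFrame, out_path: Path | str) -> None:
    """Write per-(cluster, family) avoidance results, sorted by (cluster, family)."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if len(results) == 0:
        df = pd.DataFrame(columns=AVOIDANCE_COLUMNS)
    else:
        df = results.rename(columns={"family_id": "family"})
        df = df[AVOIDANCE_COLUMNS].sort_values(["cluster", "family"]).reset_index(drop=True)
    df.to_csv(out_path, sep="\t", index=False)


def read_avoidance_results(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cluster": str, "family": str})
    return df


SFFL_COLUMNS = ["cluster", "family", "tf", "gene", "class", "score", "p", "p_adj",
                "mirna_sites_lost_flag"]


def write_network_results(sffls: pd.DataFrame, mffls: list[dict],
                          out_dir: Path | str) -> tuple[Path, Path]:
    """Write the scored SFFL TSV and the MFFL JSON; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sffl_path = out_dir / "sffls.tsv"
    mffl_path = out_dir / "mffls.json"
    if len(sffls) == 0:
        df = pd.DataFrame(columns=SFFL_COLUMNS)
    else:
        df = sffls[SFFL_COLUMNS].sort_values(
            ["cluster", "family", "tf", "gene"]).reset_index(drop=True)
    df.to_csv(sffl_path, sep="\t", index=False)
    with open(mffl_path, "w") as fh:
        json.dump(mffls, fh, indent=1, sort_keys=True)
    return sffl_path, mffl_path


def read_mffls_json(path: Path | str) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# config


_CONFIG_KEYS = {
    "n_permutations", "alpha", "min_expr_frac", "count_mode",
    "smooth_permutation_p", "signed_edges", "seed", "out_dir", "paths",
}


def validate_config(path: Path | str) -> PipelineConfig:
    """Read a YAML config, apply defaults, and report all violations at once."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) if path.exists() else None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def write_config(config: PipelineConfig, path: Path | str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
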