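"""Core domain types shared by every analysis stage.

The pipeline operates on four kinds of tabular/matrix inputs:

* a genes × cells expression matrix,
* a polyA-site × cells APA matrix whose rows are cleavage isoforms of genes,
* a cell → cluster assignment,
* microRNA-family binding sites in 3'UTR-relative coordinates, and
* directed regulatory interaction tables (miRNA→gene, miRNA→TF, TF→gene, TF→miRNA).

Coordinate conventions: binding sites are 0-based half-open intervals relative
to the 3'UTR start on the mRNA sense strand; ``cleavage_pos`` is the number of
3'UTR bases retained by an isoform, so a site is physically present on that
isoform iff ``end <= cleavage_pos``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

ALLOWED_INTERACTION_KINDS = {
    ("miRNA", "TF"),
    ("miRNA", "gene"),
    ("TF", "gene"),
    ("TF", "miRNA"),
}

BINDING_SITE_COLUMNS = ["family_id", "gene_id", "start", "end"]
INTERACTION_COLUMNS = ["source_id", "source_type", "target_id", "target_type"]


class ValidationError(ValueError):
    """Raised when an input table or matrix violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        dupes = dupes[dupes > 1].index.tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class ExpressionMatrix:
    """Genes × cells expression values (raw counts or log-normalized)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression matrix must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        _check_unique(self.gene_ids, "gene IDs")
        _check_unique(self.cell_ids, "cell IDs")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def log_normalized(self, scale: float = 1e4) -> "ExpressionMatrix":
        """Library-size normalize to ``scale`` counts per cell and log1p.

        Returns self unchanged when already normalized.
        """
        if self.normalized:
            return self
        totals = self.values.sum(axis=0)
        totals[totals == 0] = 1.0
        vals = np.log1p(self.values / totals * scale)
        return replace(self, values=vals, normalized=True)


@dataclass
class ApaMatrix:
    """PolyA-site × cells expression with per-site cleavage metadata.

    ``site_meta`` has one row per matrix row with columns ``gene_id``,
    ``site_id`` and ``cleavage_pos`` (3'UTR bases retained by the isoform).
    """

    values: np.ndarray
    site_meta: pd.DataFrame
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        meta = self.site_meta.reset_index(drop=True)
        required = {"gene_id", "site_id", "cleavage_pos"}
        missing = required - set(meta.columns)
        if missing:
            raise ValidationError(f"site_meta missing columns {sorted(missing)}")
        if self.values.shape != (len(meta), len(self.cell_ids)):
            raise ValidationError(
                f"APA matrix shape {self.values.shape} does not match "
                f"{len(meta)} sites x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise ValidationError("APA values must be non-negative")
        if (meta["cleavage_pos"] < 0).any():
            raise ValidationError("cleavage_pos must be >= 0")
        pairs = meta[["gene_id", "site_id"]].apply(tuple, axis=1)
        _check_unique(pairs, "(gene_id, site_id) pairs")
        for gene, grp in meta.groupby("gene_id"):
            if grp["cleavage_pos"].nunique() != len(grp):
                raise ValidationError(
                    f"gene {gene!r} has duplicate cleavage positions"
                )
        _check_unique(self.cell_ids, "cell IDs")
        self.site_meta = meta

    @property
    def n_sites(self) -> int:
        return len(self.site_meta)

    def genes_with_multiple_sites(self) -> set[str]:
        counts = self.site_meta["gene_id"].value_counts()
        return set(counts[counts >= 2].index)


@dataclass
class ClusterAssignment:
    """Mapping cell_id → cluster label."""

    labels: pd.Series  # index: cell_id, values: cluster label (str)

    def __post_init__(self) -> None:
        s = pd.Series(self.labels)
        s.index = s.index.astype(str)
        self.labels = s.astype(str)
        _check_unique(self.labels.index, "cell IDs in cluster assignment")

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "ClusterAssignment":
        return cls(pd.Series(mapping))

    @property
    def clusters(self) -> list[str]:
        return sorted(self.labels.unique())

    def cells_of(self, cluster: str) -> list[str]:
        if cluster not in set(self.labels.values):
            raise ValidationError(f"unknown cluster label {cluster!r}")
        return list(self.labels.index[self.labels == cluster])

    def mask_for(self, cluster: str, cell_ids: list[str]) -> np.ndarray:
        """Boolean mask over ``cell_ids`` for membership in ``cluster``."""
        members = set(self.cells_of(cluster))
        return np.array([c in members for c in cell_ids], dtype=bool)

    def validate_against(self, cell_ids: list[str]) -> None:
        missing = [c for c in cell_ids if c not in self.labels.index]
        if missing:
            raise ValidationError(
                f"cells without cluster assignment: {missing[:5]}"
            )


def validate_binding_sites(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a binding-site table (family_id, gene_id, start, end).

    Coordinates are 0-based half-open, 3'UTR-relative. Returns the table with
    canonical column order and integer coordinates.
    """
    missing = set(BINDING_SITE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"binding-site table missing columns {sorted(missing)}")
    t = table[BINDING_SITE_COLUMNS].copy()
    t["start"] = t["start"].astype(int)
    t["end"] = t["end"].astype(int)
    if (t["start"] < 0).any() or (t["start"] >= t["end"]).any():
        bad = t[(t["start"] < 0) | (t["start"] >= t["end"])].head(3)
        raise ValidationError(f"binding sites must satisfy 0 <= start < end; bad rows:\n{bad}")
    if t.duplicated().any():
        raise ValidationError("duplicate binding-site rows")
    return t.reset_index(drop=True)


def validate_interactions(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and deduplicate a directed interaction table.

    Allowed (source_type, target_type) kinds: miRNA→TF, miRNA→gene, TF→gene,
    TF→miRNA. Self-edges are rejected.
    """
    missing = set(INTERACTION_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"interaction table missing columns {sorted(missing)}")
    t = table[INTERACTION_COLUMNS].astype(str).drop_duplicates().reset_index(drop=True)
    kinds = list(zip(t["source_type"], t["target_type"]))
    bad = [k for k in kinds if k not in ALLOWED_INTERACTION_KINDS]
    if bad:
        raise ValidationError(
            f"interaction kinds not allowed: {sorted(set(bad))}; "
            f"allowed kinds are {sorted(ALLOWED_INTERACTION_KINDS)}"
        )
    if (t["source_id"] == t["target_id"]).any():
        offenders = t.loc[t["source_id"] == t["target_id"], "source_id"].tolist()[:5]
        raise ValidationError(f"self-edges not allowed: {offenders}")
    return t


@dataclass
class PipelineConfig:
    """Run-level parameters shared by the permutation tests and filters.

    ``n_permutations`` defaults to 10,000 and ``alpha`` to 0.05; the prevalence
    filter keeps genes expressed in at least ``min_expr_frac`` of a cluster's
    cells (default 10%).
    """

    n_permutations: int = 10_000
    alpha: float = 0.05
    min_expr_frac: float = 0.10
    count_mode: str = "weighted"  # or "binary"
    smooth_permutation_p: bool = True
    signed_edges: bool = False
    seed: int = 0
    out_dir: Optional[str] = None
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        errors = []
        if self.n_permutations < 1:
            errors.append("n_permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            errors.append("alpha must be in (0, 1)")
        if not (0.0 <= self.min_expr_frac <= 1.0):
            errors.append("min_expr_frac must be in [0, 1]")
        if self.count_mode not in ("weighted", "binary"):
            errors.append("count_mode must be 'weighted' or 'binary'")
        if errors:
            raise ValidationError("; ".join(errors))
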