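"""Per-cell quality metrics and threshold-based filtering.

QC operates on raw UMI counts per cell: number of detected genes, total
counts, percentage of counts on mitochondrial- and ribosomal-flagged genes,
and an externally supplied doublet score. Thresholds are configurable per
tissue, mirroring atlas pipelines that tune cutoffs organ by organ.
Filtering is cell-only: genes are never dropped here, so the full gene
universe reaches normalization and classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import CountMatrix

QC_CRITERIA = ("min_genes", "max_genes", "max_pct_mito", "max_pct_ribo",
               "max_doublet_score")


@dataclass(frozen=True)
class QCThresholds:
    """Cell-filtering cutoffs, with optional per-tissue overrides.

    Unbounded criteria are expressed as ``None``. Defaults follow common
    droplet-data practice: at least 200 detected genes, at most 20% of
    counts on mitochondrial genes, doublet score at most 0.25; gene-count
    ceiling and ribosomal fraction unbounded.
    """

    min_genes: int = 200
    max_genes: int | None = None
    max_pct_mito: float | None = 20.0
    max_pct_ribo: float | None = None
    max_doublet_score: float | None = 0.25
    per_tissue: Mapping[str, "QCThresholds"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_genes is not None and self.min_genes > self.max_genes:
            raise ValueError("min_genes must not exceed max_genes")

    def resolve(self, tissue: str | None) -> "QCThresholds":
        """Thresholds applying to a tissue (override if present)."""
        if tissue is not None and tissue in self.per_tissue:
            return self.per_tissue[tissue]
        return self


def compute_cell_qc(
    counts: CountMatrix,
    mito_genes: Iterable[str],
    ribo_genes: Iterable[str],
    doublet_scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-cell QC metrics table, one row per barcode.

    Percentages are 100 x (counts on flagged genes) / (total counts), on
    raw counts. Cells with zero total counts get 0 for both percentages
    (they are always removable via ``min_genes >= 1``). Doublet scores
    default to 0 when not supplied.
    """
    if counts.n_genes == 0 or counts.n_cells == 0:
        raise ValueError("count matrix must be non-empty")
    gene_index = pd.Index(counts.genes)
    mito = gene_index.isin(set(mito_genes))
    ribo = gene_index.isin(set(ribo_genes))
    for name, mask, src in (("mito", mito, mito_genes), ("ribo", ribo, ribo_genes)):
        missing = set(src) - set(gene_index)
        if missing:
            raise ValueError(f"{name} gene set contains unknown genes: {sorted(missing)[:5]}")

    m = counts.matrix.tocsc()
    total = np.asarray(m.sum(axis=0)).ravel()
    detected = np.asarray((m > 0).sum(axis=0)).ravel()
    mito_counts = np.asarray(m[mito, :].sum(axis=0)).ravel() if mito.any() else np.zeros_like(total)
    ribo_counts = np.asarray(m[ribo, :].sum(axis=0)).ravel() if ribo.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(total > 0, 100.0 * mito_counts / total, 0.0)
        pct_ribo = np.where(total > 0, 100.0 * ribo_counts / total, 0.0)
    qc = pd.DataFrame(
        {
            "n_genes_detected": detected.astype(int),
            "total_counts": total.astype(int),
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
        },
        index=pd.Index(counts.barcodes, name="barcode"),
    )
    if doublet_scores is not None:
        qc["doublet_score"] = doublet_scores.reindex(qc.index).fillna(0.0)
    else:
        qc["doublet_score"] = 0.0
    return qc


def filter_cells(
    qc: pd.DataFrame,
    thresholds: QCThresholds,
    tissue: str | None = None,
) -> tuple[list[str], dict[str, int]]:
    """Apply thresholds; return kept barcodes and per-criterion removal counts.

    A cell is kept iff it passes every criterion; a removed cell is counted
    under each criterion it fails (so counts can exceed the number of
    removed cells). Order-independent.
    """
    t = thresholds.resolve(tissue)
    fails = {
        "min_genes": qc["n_genes_detected"] < t.min_genes,
        "max_genes": (qc["n_genes_detected"] > t.max_genes)
        if t.max_genes is not None
        else pd.Series(False, index=qc.index),
        "max_pct_mito": (qc["pct_mito"] > t.max_pct_mito)
        if t.max_pct_mito is not None
        else pd.Series(False, index=qc.index),
        "max_pct_ribo": (qc["pct_ribo"] > t.max_pct_ribo)
        if t.max_pct_ribo is not None
        else pd.Series(False, index=qc.index),
        "max_doublet_score": (qc["doublet_score"] > t.max_doublet_score)
        if t.max_doublet_score is not None
        else pd.Series(False, index=qc.index),
    }
    any_fail = pd.concat(fails, axis=1).any(axis=1)
    kept = qc.index[~any_fail].tolist()
    removal_counts = {c: int(f.sum()) for c, f in fails.items()}
    if not kept:
        warnings.warn("all cells removed by QC filtering")
    return kept, removal_counts
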