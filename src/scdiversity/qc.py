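"""Gene/cell quality filters and total-count normalization.

Genes are kept only if detected in at least three cells of some sample;
cells are kept only if they express at least 500 genes and have
mitochondrial content of at most 20% of total UMIs; each retained cell is
rescaled to 10,000 total transcripts.
Boundary conventions are strict readings of those rules: a cell with exactly
500 detected genes or exactly 20% mitochondrial UMIs is retained, a gene
detected in exactly 3 cells is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import NormalizedMatrix, RawCountMatrix

__all__ = [
    "QCConfig",
    "filter_genes",
    "filter_cells",
    "normalize_total",
    "cell_qc_table",
]


@dataclass
class QCConfig:
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 500
    max_mito_fraction: float = 0.20
    scale_total: float = 10_000.0
    mito_prefix: str = "MT-"
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.min_cells_per_gene <= 0 or self.min_genes_per_cell <= 0:
            raise ValueError("count thresholds must be strictly positive")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")
        if self.scale_total <= 0:
            raise ValueError("scale_total must be positive")


def gene_filter_mask(m: RawCountMatrix, cfg: QCConfig) -> np.ndarray:
    """Boolean keep-mask: gene detected in >= min_cells_per_gene cells of some sample."""
    detected = m.counts > 0
    keep = np.zeros(m.n_genes, dtype=bool)
    for sample in pd.unique(m.sample_of_cell):
        cols = np.flatnonzero(m.sample_of_cell == sample)
        n_det = np.asarray(detected[:, cols].sum(axis=1)).ravel()
        keep |= n_det >= cfg.min_cells_per_gene
    return keep


def filter_genes(m: RawCountMatrix, cfg: QCConfig | None = None) -> RawCountMatrix:
    """Drop genes detected in fewer than ``min_cells_per_gene`` cells in every sample.

    Retention in any single sample is sufficient, so genes private to one
    tumor survive. Gene order is preserved.
    """
    cfg = cfg or QCConfig()
    return m.subset_genes(gene_filter_mask(m, cfg))


def cell_qc_table(m: RawCountMatrix, cfg: QCConfig | None = None) -> pd.DataFrame:
    """Per-cell QC metrics and keep/remove decision with reasons."""
    cfg = cfg or QCConfig()
    n_genes = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    mito_mask = np.array([str(g).startswith(cfg.mito_prefix) for g in m.gene_ids])
    mito_counts = (
        np.asarray(m.counts[mito_mask].sum(axis=0)).ravel().astype(float)
        if mito_mask.any()
        else np.zeros(m.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)
    low_genes = n_genes < cfg.min_genes_per_cell
    high_mito = mito_fraction > cfg.max_mito_fraction
    reason = np.array(
        [
            ";".join(r for r, f in (("low_genes", lg), ("high_mito", hm)) if f)
            for lg, hm in zip(low_genes, high_mito)
        ],
        dtype=object,
    )
    return pd.DataFrame(
        {
            "barcode": m.barcodes,
            "sample": m.sample_of_cell,
            "n_genes": n_genes,
            "total_counts": totals,
            "mito_fraction": mito_fraction,
            "kept": ~(low_genes | high_mito),
            "reason": reason,
        }
    )


def filter_cells(
    m: RawCountMatrix, cfg: QCConfig | None = None
) -> tuple[RawCountMatrix, pd.DataFrame]:
    """Drop cells expressing fewer than ``min_genes_per_cell`` genes or with a
    mitochondrial UMI fraction strictly above ``max_mito_fraction``.

    Returns the filtered matrix and the full per-cell QC report (including
    removed cells and removal reasons).
    """
    cfg = cfg or QCConfig()
    report = cell_qc_table(m, cfg)
    return m.subset_cells(report["kept"].to_numpy()), report


def normalize_total(m: RawCountMatrix, cfg: QCConfig | None = None) -> NormalizedMatrix:
    """Rescale every cell to ``scale_total`` total counts, then log(1 + x).

    Cell filtering must precede: a zero-total cell cannot be normalized.
    """
    cfg = cfg or QCConfig()
    totals = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    if np.any(totals <= 0):
        raise ValueError(
            f"{int((totals <= 0).sum())} cells have zero total counts; "
            "run cell QC before normalization"
        )
    scaled = m.counts.multiply(cfg.scale_total / totals).toarray()
    values = np.log1p(scaled) if cfg.log_transform else scaled
    return NormalizedMatrix(
        values=values,
        gene_ids=m.gene_ids.copy(),
        barcodes=m.barcodes.copy(),
        sample_of_cell=m.sample_of_cell.copy(),
        library_sizes=totals,
        scale_total=cfg.scale_total,
        log_transformed=cfg.log_transform,
    )
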