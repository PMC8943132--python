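"""Expression-based copy-number inference and malignant-cell classification.

Large chromosomal dosage changes leave a footprint in expression: averaging
log-expression over long runs of genomically adjacent genes, relative to a
panel of confidently non-malignant reference cells (endothelia, fibroblasts,
macrophages), yields a per-cell "CNV profile". Two summaries classify cells:

* CNV signal — the mean of squares of a cell's CNV values across the genome,
  a proxy for total aneuploidy burden;
* CNV correlation — Pearson correlation of the cell's profile with its
  sample's putative-malignant consensus profile (mean over the top 5% of
  cells by signal).

A cell is called malignant when signal > 0.05 and correlation > 0.5, both
strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import NormalizedMatrix

__all__ = [
    "CNVProfile",
    "read_gene_annotation",
    "write_gene_annotation",
    "infer_cnv_profile",
    "cnv_signal",
    "cnv_correlation",
    "classify_malignant",
]


@dataclass
class CNVProfile:
    """Centered, genomically smoothed relative-expression values (cells x genes).

    Columns follow genomic order; the per-gene mean over reference cells is
    zero by construction, so 0 means "dosage like the reference".
    """

    values: np.ndarray  # cells x ordered genes
    gene_ids: np.ndarray
    chromosomes: np.ndarray
    barcodes: np.ndarray
    sample_of_cell: np.ndarray
    reference_mask: np.ndarray
    window: int

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a BED-like gene table: gene_id, chrom, start, end (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["gene_id", "chrom", "start", "end"],
        dtype={"gene_id": str, "chrom": str, "start": int, "end": int},
    )
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in annotation")
    return df


def write_gene_annotation(ann: pd.DataFrame, path) -> None:
    ann[["gene_id", "chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def _genomic_order(ann: pd.DataFrame) -> pd.DataFrame:
    """Sort by chromosome (order of first appearance) then start; reject ties."""
    chrom_rank = {c: i for i, c in enumerate(pd.unique(ann["chrom"]))}
    out = ann.assign(_rank=ann["chrom"].map(chrom_rank)).sort_values(
        ["_rank", "start"], kind="stable"
    )
    dup = out.duplicated(subset=["chrom", "start"])
    if dup.any():
        raise ValueError("gene starts are not strictly increasing within a chromosome")
    return out.drop(columns="_rank").reset_index(drop=True)


def _moving_average(X: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1, window shrinking symmetrically
    at the ends: position i averages over [i-h, i+h], h = min(w//2, i, n-1-i)."""
    n = X.shape[1]
    half = window // 2
    cs = np.cumsum(X, axis=1)
    cs = np.concatenate([np.zeros((X.shape[0], 1)), cs], axis=1)
    out = np.empty_like(X)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[:, i] = (cs[:, i + h + 1] - cs[:, i - h]) / (2 * h + 1)
    return out


def infer_cnv_profile(
    norm: NormalizedMatrix,
    gene_annotation: pd.DataFrame,
    reference_cells: np.ndarray,
    window: int = 101,
    clip: float = 3.0,
    min_genes_per_chromosome: int = 3,
    exclude_chroms: tuple[str, ...] = ("chrM", "MT"),
    expression_scale: float = 1e5,
) -> CNVProfile:
    """Infer per-cell relative copy-number values along the genome.

    Expression enters on the scale this classifier family conventionally
    uses, log2(x + 1) of counts rescaled to ``expression_scale`` per cell
    (1e5 corresponds to TPM/10); the 0.05 signal threshold is calibrated to
    these units. Procedure: per-gene log2-expression minus the
    reference-cell mean, clipped to +/- ``clip``; centered moving average
    over ``window`` genes within each chromosome (shrinking symmetrically at
    chromosome ends); per-cell median centering; final per-gene subtraction
    of the reference mean so reference cells average exactly zero.

    ``reference_cells`` is a boolean mask or index array over the cells of
    ``norm``; at least 10 reference cells are required. Genes without
    annotation, mitochondrial contigs, and chromosomes carrying fewer than
    ``min_genes_per_chromosome`` annotated genes are dropped with a warning.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    ref = np.zeros(norm.n_cells, dtype=bool)
    ref[np.asarray(reference_cells)] = True
    if ref.sum() == 0:
        raise ValueError("no reference cells given")
    if ref.sum() < 10:
        raise ValueError(f"need >= 10 reference cells, got {int(ref.sum())}")

    present = set(norm.gene_ids)
    n_unannotated = len(present - set(gene_annotation["gene_id"]))
    if n_unannotated:
        warnings.warn(f"{n_unannotated} genes lack annotation and are dropped from CNV")
    ann = gene_annotation[~gene_annotation["chrom"].isin(exclude_chroms)]
    ann = _genomic_order(ann[ann["gene_id"].isin(present)])

    sizes = ann.groupby("chrom", sort=False).size()
    small = sizes[sizes < min_genes_per_chromosome].index.tolist()
    if small:
        warnings.warn(f"chromosomes with < {min_genes_per_chromosome} genes excluded: {small}")
        ann = ann[~ann["chrom"].isin(small)]
    if ann.empty:
        raise ValueError("no annotated genes left for CNV inference")

    idx = norm.gene_index(ann["gene_id"].to_numpy())
    linear = norm.linear()[idx] * (expression_scale / norm.scale_total)
    E = np.log2(linear + 1.0).T  # cells x genes, genomic order
    rel = E - E[ref].mean(axis=0, keepdims=True)
    rel = np.clip(rel, -clip, clip)

    chroms = ann["chrom"].to_numpy()
    smoothed = np.empty_like(rel)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        smoothed[:, cols] = _moving_average(rel[:, cols], window)

    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    smoothed -= smoothed[ref].mean(axis=0, keepdims=True)

    return CNVProfile(
        values=smoothed,
        gene_ids=ann["gene_id"].to_numpy(dtype=object),
        chromosomes=chroms.astype(object),
        barcodes=norm.barcodes.copy(),
        sample_of_cell=norm.sample_of_cell.copy(),
        reference_mask=ref,
        window=window,
    )


def cnv_signal(profile: CNVProfile | np.ndarray) -> np.ndarray:
    """Per-cell CNV signal: mean of squares of CNV values across the genome."""
    values = profile.values if isinstance(profile, CNVProfile) else np.asarray(profile)
    return np.mean(values**2, axis=1)


def _pearson_to_profile(rows: np.ndarray, profile: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    pc = profile - profile.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (pc**2).sum())
    num = rc @ pc
    zero = denom == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance CNV rows; their correlation is set to 0"
        )
    return np.where(zero, 0.0, num / np.where(zero, 1.0, denom))


def cnv_correlation(profile: CNVProfile, top_fraction: float = 0.05) -> np.ndarray:
    """Per-cell Pearson correlation with the sample's putative-malignant consensus.

    Within each sample the consensus is the per-gene mean profile of the top
    ``top_fraction`` of cells by CNV signal (at least one cell). Cells that
    are themselves part of the top set are correlated against the consensus
    with themselves left out whenever the set has at least two members, so a
    cell never certifies itself.
    """
    signal = cnv_signal(profile)
    out = np.empty(profile.n_cells)
    for sample in pd.unique(profile.sample_of_cell):
        cells = np.flatnonzero(profile.sample_of_cell == sample)
        n_top = max(1, int(np.ceil(top_fraction * len(cells))))
        order = cells[np.argsort(-signal[cells], kind="stable")]
        top = order[:n_top]
        top_rows = profile.values[top]
        consensus = top_rows.mean(axis=0)
        out[cells] = _pearson_to_profile(profile.values[cells], consensus)
        if n_top >= 2:
            total = top_rows.sum(axis=0)
            for rank, cell in enumerate(top):
                loo = (total - top_rows[rank]) / (n_top - 1)
                out[cell] = _pearson_to_profile(profile.values[[cell]], loo)[0]
    return out


def classify_malignant(
    signal: np.ndarray,
    correlation: np.ndarray,
    signal_min: float = 0.05,
    corr_min: float = 0.5,
) -> pd.DataFrame:
    """Malignancy call: CNV signal strictly above ``signal_min`` AND CNV
    correlation strictly above ``corr_min``."""
    signal = np.asarray(signal, dtype=float)
    correlation = np.asarray(correlation, dtype=float)
    return pd.DataFrame(
        {
            "cnv_signal": signal,
            "cnv_correlation": correlation,
            "is_malignant": (signal > signal_min) & (correlation > corr_min),
        }
    )
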