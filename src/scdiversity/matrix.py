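"""Count-matrix containers and 10x-convention Matrix Market I/O.

Matrices are stored gene-major (genes x cells) throughout the package,
mirroring the on-disk 10x layout (matrix.mtx rows = features).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["RawCountMatrix", "NormalizedMatrix", "read_counts", "write_counts"]


class FormatError(ValueError):
    """Raised when an input file is structurally inconsistent."""


@dataclass
class RawCountMatrix:
    """Sparse UMI count matrix (genes x cells) with labels.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes in rows, cells in columns.
    gene_ids, barcodes
        Unique row / column labels.
    sample_of_cell
        Sample label per cell; defaults to a single sample.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    sample_of_cell: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.sample_of_cell is None:
            self.sample_of_cell = np.full(self.n_cells, "sample1", dtype=object)
        self.sample_of_cell = np.asarray(self.sample_of_cell, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if len(self.sample_of_cell) != self.n_cells:
            raise FormatError("sample_of_cell length does not match cell count")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, mask: np.ndarray) -> "RawCountMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            counts=sp.csr_matrix(self.counts[mask]),
            gene_ids=self.gene_ids[mask],
        )

    def subset_cells(self, mask: np.ndarray) -> "RawCountMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            counts=sp.csr_matrix(self.counts[:, mask]),
            barcodes=self.barcodes[mask],
            sample_of_cell=self.sample_of_cell[mask],
        )

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclass
class NormalizedMatrix:
    """Library-size-normalized expression (genes x cells).

    ``values`` holds log(1 + x) of counts rescaled so each cell sums to
    ``scale_total``; ``linear()`` recovers the pre-log scale on which the
    HVG mean-expression window (0.05-3) is defined.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    barcodes: np.ndarray
    sample_of_cell: np.ndarray
    library_sizes: np.ndarray
    scale_total: float = 10_000.0
    log_transformed: bool = True

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def linear(self) -> np.ndarray:
        """Normalized expression on the pre-log (counts-per-scale_total) scale."""
        if self.log_transformed:
            return np.expm1(self.values)
        return self.values

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            values=self.values[:, mask],
            barcodes=self.barcodes[mask],
            sample_of_cell=self.sample_of_cell[mask],
            library_sizes=self.library_sizes[mask],
        )


def _read_tsv_column(path, column: int = 0) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if column >= df.shape[1]:
        raise FormatError(f"{path}: expected at least {column + 1} columns")
    return df.iloc[:, column].to_numpy(dtype=object)


def read_counts(
    mtx_path,
    features_path,
    barcodes_path,
    samples=None,
) -> RawCountMatrix:
    """Read a 10x-convention triplet (matrix.mtx, features.tsv, barcodes.tsv).

    ``samples`` may be a per-cell array, a path to a two-column TSV
    (barcode, sample), or None for a single anonymous sample.
    MTX indices are 1-based on disk and converted to 0-based internally.
    """
    for p in (mtx_path, features_path, barcodes_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
    gene_ids = _read_tsv_column(features_path, 0)
    barcodes = _read_tsv_column(barcodes_path, 0)
    if counts.shape[0] != len(gene_ids):
        raise FormatError(
            f"MTX declares {counts.shape[0]} genes but features file has "
            f"{len(gene_ids)} lines"
        )
    if counts.shape[1] != len(barcodes):
        raise FormatError(
            f"MTX declares {counts.shape[1]} cells but barcodes file has "
            f"{len(barcodes)} lines"
        )
    sample_of_cell = None
    if samples is not None:
        if isinstance(samples, (str, Path)):
            tab = pd.read_csv(samples, sep="\t", header=None, dtype=str)
            mapping = dict(zip(tab.iloc[:, 0], tab.iloc[:, 1]))
            missing = [b for b in barcodes if b not in mapping]
            if missing:
                raise FormatError(f"{len(missing)} barcodes missing from sample table")
            sample_of_cell = np.array([mapping[b] for b in barcodes], dtype=object)
        else:
            sample_of_cell = np.asarray(samples, dtype=object)
    return RawCountMatrix(counts, gene_ids, barcodes, sample_of_cell)


def write_counts(m: RawCountMatrix, outdir) -> None:
    """Write matrix.mtx / features.tsv / barcodes.tsv / samples.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(_as_integer(m.counts)))
    pd.Series(m.gene_ids).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(m.barcodes).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.DataFrame({"barcode": m.barcodes, "sample": m.sample_of_cell}).to_csv(
        outdir / "samples.tsv", sep="\t", index=False, header=False
    )


def _as_integer(counts: sp.spmatrix) -> sp.spmatrix:
    """Cast to integer dtype if the values are integral (MTX round-trip hygiene)."""
    if np.issubdtype(counts.dtype, np.integer):
        return counts
    data = counts.tocoo()
    if np.allclose(data.data, np.round(data.data)):
        return data.astype(np.int64)
    return data
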