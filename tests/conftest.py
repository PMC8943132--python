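import numpy as np
import pytest
import scipy.sparse as sp

from scdiversity.matrix import NormalizedMatrix, RawCountMatrix


def make_norm(values, gene_ids=None, samples=None, scale_total=10_000.0, log=True):
    """Build a NormalizedMatrix directly from a dense genes x cells array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_ids = np.array(
        gene_ids if gene_ids is not None else [f"g{i}" for i in range(n_genes)],
        dtype=object,
    )
    barcodes = np.array([f"c{i}" for i in range(n_cells)], dtype=object)
    samples = np.array(
        samples if samples is not None else ["s1"] * n_cells, dtype=object
    )
    return NormalizedMatrix(
        values=values,
        gene_ids=gene_ids,
        barcodes=barcodes,
        sample_of_cell=samples,
        library_sizes=np.ones(n_cells),
        scale_total=scale_total,
        log_transformed=log,
    )


def make_raw(counts, gene_ids=None, samples=None):
    counts = sp.csr_matrix(np.asarray(counts))
    n_genes, n_cells = counts.shape
    return RawCountMatrix(
        counts=counts,
        gene_ids=np.array(
            gene_ids if gene_ids is not None else [f"g{i}" for i in range(n_genes)],
            dtype=object,
        ),
        barcodes=np.array([f"c{i}" for i in range(n_cells)], dtype=object),
        sample_of_cell=None if samples is None else np.asarray(samples, dtype=object),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One-sample synthetic cohort shared by annotation/CNV tests."""
    from scdiversity.synthetic import SimConfig, simulate_dataset

    cfg = SimConfig(
        n_samples=1,
        cells_per_type={
            "T": 100, "B": 50, "TEC": 70, "CAF": 70, "TAM": 60,
            "HPC-like": 50, "malignant": 200,
        },
        seed=2,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    from scdiversity.qc import QCConfig, filter_cells, filter_genes, normalize_total

    raw, ann, truth = small_dataset
    cfg = QCConfig()
    filtered, report = filter_cells(filter_genes(raw, cfg), cfg)
    norm = normalize_total(filtered, cfg)
    kept = report["kept"].to_numpy()
    return norm, ann, truth, kept
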