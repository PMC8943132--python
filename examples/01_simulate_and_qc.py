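"""Simulate a small liver-tumor scRNA-seq cohort and apply quality control.

Generates a two-sample cohort with known ground truth, filters genes
detected in fewer than 3 cells per sample and cells with <500 genes or >20%
mitochondrial UMIs, then normalizes every cell to 10,000 transcripts.
"""

import numpy as np

import scdiversity as sd
from scdiversity.qc import QCConfig, filter_cells, filter_genes, normalize_total

cfg = sd.SimConfig(
    n_samples=2,
    cells_per_type={"T": 60, "CAF": 50, "TAM": 40, "malignant": 100},
    seed=0,
)
raw, annotation, truth = sd.simulate_dataset(cfg)
print(f"simulated {raw.n_genes} genes x {raw.n_cells} cells "
      f"({int(np.median(np.asarray(raw.counts.sum(axis=0))))} median UMIs/cell)")

qc = QCConfig()
after_genes = filter_genes(raw, qc)
after_cells, report = filter_cells(after_genes, qc)
norm = normalize_total(after_cells, qc)

print(f"genes kept: {after_genes.n_genes}/{raw.n_genes} "
      f"(removed: detected in <{qc.min_cells_per_gene} cells in every sample)")
print(f"cells kept: {after_cells.n_cells}/{raw.n_cells} "
      f"(removed: <{qc.min_genes_per_cell} genes or >{qc.max_mito_fraction:.0%} mito)")

totals = np.expm1(norm.values).sum(axis=0)
print(f"normalization check: every cell sums to {totals.min():.4f}..{totals.max():.4f} "
      f"(target {qc.scale_total:g}) before the log transform")
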