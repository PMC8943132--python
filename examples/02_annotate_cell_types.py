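"""Cluster non-malignant cells and label lineages from canonical markers.

Selects variable genes by the mean/dispersion rule, runs exact PCA, clusters
the cells on a shared-nearest-neighbor graph, and assigns each cluster the
marker panel (T/B/TEC/CAF/TAM/HPC-like) with the highest mean z-scored
expression. The printed cross-table compares assignments with the
generator's ground truth; malignant cells carry no lineage markers and stay
"unassigned" here — the CNV classifier (example 03) is what identifies them.
"""

import pandas as pd

import scdiversity as sd
from scdiversity.qc import QCConfig, filter_cells, filter_genes, normalize_total

cfg = sd.SimConfig(
    n_samples=1,
    cells_per_type={
        "T": 80, "B": 40, "TEC": 50, "CAF": 50, "TAM": 40,
        "HPC-like": 40, "malignant": 120,
    },
    seed=1,
)
raw, annotation, truth = sd.simulate_dataset(cfg)
qc = QCConfig()
filtered, report = filter_cells(filter_genes(raw, qc), qc)
norm = normalize_total(filtered, qc)
kept = report["kept"].to_numpy()

hvg_genes, hvg_stats = sd.select_hvg(norm)
print(f"{len(hvg_genes)} highly variable genes "
      f"(mean in (0.05, 3), normalized dispersion > 0.5)")

scaled, _ = sd.scale_matrix(norm, hvg_genes)
pcs = sd.run_pca(scaled, 20)
table = sd.annotate_cells(norm, pcs, resolution=0.5, seed=0)

print(pd.crosstab(
    pd.Series(truth.cell_type[kept], name="truth"),
    pd.Series(table["type"].to_numpy(), name="assigned"),
))
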