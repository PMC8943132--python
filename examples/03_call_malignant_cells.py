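"""Identify malignant cells from inferred copy-number profiles.

Endothelial, fibroblast and macrophage cells serve as the diploid
reference. Log2 expression relative to that reference, smoothed along each
chromosome, gives a per-cell CNV profile; cells with CNV signal (mean of
squares) above 0.05 and correlation with the sample's top-signal consensus
above 0.5 are called malignant.
"""

import numpy as np

import scdiversity as sd
from scdiversity.qc import QCConfig, filter_cells, filter_genes, normalize_total

cfg = sd.SimConfig(
    n_samples=1,
    cells_per_type={
        "CAF": 70, "TEC": 70, "TAM": 60, "T": 100, "B": 50,
        "HPC-like": 50, "malignant": 200,
    },
    seed=2,
)
raw, annotation, truth = sd.simulate_dataset(cfg)
qc = QCConfig()
filtered, report = filter_cells(filter_genes(raw, qc), qc)
norm = normalize_total(filtered, qc)
kept = report["kept"].to_numpy()

reference = np.isin(truth.cell_type[kept], ["TEC", "CAF", "TAM"])
profile = sd.infer_cnv_profile(norm, annotation, np.flatnonzero(reference))
signal = sd.cnv_signal(profile)
corr = sd.cnv_correlation(profile)
calls = sd.classify_malignant(signal, corr)

is_mal = truth.is_malignant[kept]
print(f"CNV signal: malignant median {np.median(signal[is_mal]):.3f}, "
      f"non-malignant median {np.median(signal[~is_mal]):.3f} (threshold 0.05)")
print(f"CNV correlation: malignant median {np.median(corr[is_mal]):.3f}, "
      f"non-malignant median {np.median(corr[~is_mal]):.3f} (threshold 0.5)")

pred = calls["is_malignant"].to_numpy()
tp = int((pred & is_mal).sum())
print(f"called {pred.sum()} of {is_mal.sum()} planted malignant cells: "
      f"precision {tp / max(pred.sum(), 1):.3f}, recall {tp / is_mal.sum():.3f}")
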