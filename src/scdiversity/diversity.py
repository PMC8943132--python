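"""Per-tumor transcriptional (and CNV) diversity scoring.

A tumor's diversity score is the mean Euclidean distance of its malignant
cells to their centroid in a per-sample PC space: PCA projects the cells'
profiles onto the leading components (smallest set reaching a cumulative
variance target, default 80%), the centroid is the arithmetic mean of the
retained coordinates, and cells whose distance falls outside
mean +/- 3*SD are excluded once before the final score. Samples are split
into diversity-high / diversity-low groups at the median score. The same
machinery applied to inferred CNV profiles gives the genetic twin of the
score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiversityConfig",
    "project_sample",
    "diversity_score",
    "assign_groups",
    "sample_diversity",
]


@dataclass
class DiversityConfig:
    variance_kept: float = 0.80
    outlier_k: float = 3.0
    split_rule: str = "median"
    min_cells: int = 3  # below this a sample cannot be scored
    min_tumor_cells: int = 20  # inclusion rule: strictly more required

    def __post_init__(self) -> None:
        if not 0 < self.variance_kept <= 1:
            raise ValueError("variance_kept must be in (0, 1]")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")
        if self.split_rule != "median":
            raise ValueError(f"unknown split rule {self.split_rule!r}")


def project_sample(X: np.ndarray, variance_kept: float = 0.80) -> np.ndarray:
    """Per-sample PCA projection keeping the smallest k with cumulative
    variance >= ``variance_kept``.

    ``X`` is cells x features for one sample's tumor cells. Returns cells x k
    PC coordinates. Degenerate inputs (zero total variance) yield a single
    all-zero coordinate.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("per-sample PCA needs at least 3 cells")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    eig = S**2 / (X.shape[0] - 1)
    total = eig.sum()
    if total <= 0:
        return np.zeros((X.shape[0], 1))
    k = int(np.searchsorted(np.cumsum(eig) / total, variance_kept - 1e-12) + 1)
    k = min(k, len(eig))
    return U[:, :k] * S[:k]


def diversity_score(
    coords: np.ndarray, outlier_k: float = 3.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean distance to centroid after one pass of mean +/- k*SD exclusion.

    Distances are Euclidean in the supplied coordinate space. Cells whose
    distance lies outside mean(d) +/- k*SD(d) (sample SD) are flagged; the
    centroid and score are then recomputed once on the remaining cells.
    Returns (score, first-pass distances, outlier flags). With k = 3 no cell
    can be flagged when n <= 10 (Samuelson's inequality caps |d - mean|/SD at
    (n-1)/sqrt(n)).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = coords.shape[0]
    if n < 2:
        raise ValueError("diversity score needs at least 2 cells")
    centroid = coords.mean(axis=0)
    d = np.linalg.norm(coords - centroid, axis=1)
    sd = d.std(ddof=1)
    outlier = np.abs(d - d.mean()) > outlier_k * sd if sd > 0 else np.zeros(n, bool)
    kept = ~outlier
    if not kept.any():
        warnings.warn("all cells flagged as outliers; scoring the full set")
        kept = np.ones(n, bool)
        outlier = np.zeros(n, bool)
    centroid2 = coords[kept].mean(axis=0)
    d2 = np.linalg.norm(coords[kept] - centroid2, axis=1)
    return float(d2.mean()), d, outlier


def assign_groups(scores: pd.Series, split_rule: str = "median") -> pd.Series:
    """Median split: score >= median -> "high", below -> "low".

    When every score is identical the split is degenerate and all samples
    are placed in the high group with a warning.
    """
    if split_rule != "median":
        raise ValueError(f"unknown split rule {split_rule!r}")
    scores = pd.Series(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("group assignment needs at least 2 samples")
    if scores.nunique() == 1:
        warnings.warn("all diversity scores equal; assigning every sample to 'high'")
        return pd.Series("high", index=scores.index, dtype=object)
    med = float(np.median(scores.to_numpy()))
    return pd.Series(
        np.where(scores.to_numpy() >= med, "high", "low"), index=scores.index, dtype=object
    )


def sample_diversity(
    features: np.ndarray,
    sample_of_cell: np.ndarray,
    tumor_mask: np.ndarray,
    cfg: DiversityConfig | None = None,
    assign: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every sample with enough tumor cells and split at the median.

    ``features`` is cells x features (e.g. scaled HVG expression or a CNV
    profile); scoring runs on the rows where ``tumor_mask`` is True,
    per sample. Samples with more than ``cfg.min_tumor_cells`` tumor cells
    are scored and grouped; samples at or below the rule (but with at least
    ``cfg.min_cells``) are still scored and reported with ``included=False``;
    smaller samples are skipped with a warning.

    Returns (per-sample table, per-cell table with distances/outlier flags).
    """
    cfg = cfg or DiversityConfig()
    features = np.asarray(features, dtype=float)
    sample_of_cell = np.asarray(sample_of_cell)
    tumor_mask = np.asarray(tumor_mask, dtype=bool)

    rows, cell_rows = [], []
    for sample in pd.unique(sample_of_cell):
        cells = np.flatnonzero((sample_of_cell == sample) & tumor_mask)
        n = len(cells)
        if n < max(cfg.min_cells, 2):
            warnings.warn(f"sample {sample!r}: only {n} tumor cells; skipped")
            continue
        coords = project_sample(features[cells], cfg.variance_kept)
        score, dists, outliers = diversity_score(coords, cfg.outlier_k)
        rows.append(
            {
                "sample": sample,
                "n_tumor_cells": n,
                "n_outliers": int(outliers.sum()),
                "score": score,
                "included": n > cfg.min_tumor_cells,
            }
        )
        cell_rows.append(
            pd.DataFrame(
                {
                    "cell_index": cells,
                    "sample": sample,
                    "distance": dists,
                    "outlier": outliers,
                }
            )
        )
    per_sample = pd.DataFrame(
        rows, columns=["sample", "n_tumor_cells", "n_outliers", "score", "included"]
    )
    per_cell = (
        pd.concat(cell_rows, ignore_index=True)
        if cell_rows
        else pd.DataFrame(columns=["cell_index", "sample", "distance", "outlier"])
    )
    if assign and per_sample["included"].sum() >= 2:
        inc = per_sample["included"]
        groups = assign_groups(per_sample.loc[inc, "score"], cfg.split_rule)
        per_sample["group"] = pd.Series(pd.NA, index=per_sample.index, dtype=object)
        per_sample.loc[inc, "group"] = groups
    else:
        per_sample["group"] = pd.Series(pd.NA, index=per_sample.index, dtype=object)
    return per_sample, per_cell
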