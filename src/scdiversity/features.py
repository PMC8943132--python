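"""Variable-gene selection, scaling, PCA, and t-SNE embedding.

Highly variable genes are chosen by the classical mean/dispersion procedure:
per-gene mean of normalized (pre-log) expression inside an open window
(0.05, 3) and variance/mean dispersion z-scored within equal-frequency mean
bins, kept when strictly above 0.5. PCA uses an exact SVD with a fixed sign
convention so results are platform-deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .matrix import NormalizedMatrix

__all__ = ["HVGConfig", "PCResult", "select_hvg", "scale_matrix", "run_pca", "run_tsne"]


@dataclass
class HVGConfig:
    mean_low: float = 0.05
    mean_high: float = 3.0
    dispersion_min: float = 0.5
    n_bins: int = 20

    def __post_init__(self) -> None:
        if not self.mean_low < self.mean_high:
            raise ValueError("mean_low must be below mean_high")


@dataclass
class PCResult:
    """Exact PCA decomposition: cell coordinates, covariance eigenvalues
    (non-increasing), and gene loadings."""

    coordinates: np.ndarray  # cells x k
    eigenvalues: np.ndarray  # k, non-increasing
    loadings: np.ndarray  # genes x k
    total_variance: float = float("nan")

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def hvg_stats(norm: NormalizedMatrix, cfg: HVGConfig | None = None) -> pd.DataFrame:
    """Per-gene mean, raw dispersion (variance/mean), and bin-normalized dispersion."""
    cfg = cfg or HVGConfig()
    if norm.n_cells < 2:
        raise ValueError("dispersion is undefined with fewer than 2 cells")
    linear = norm.linear()
    mean = linear.mean(axis=1)
    var = linear.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-300), np.nan)

    disp_norm = np.full(norm.n_genes, np.nan)
    expressed = mean > 0
    if expressed.sum() >= 2:
        n_bins = min(cfg.n_bins, max(1, expressed.sum()))
        bins = pd.qcut(
            pd.Series(mean[expressed]).rank(method="first"), n_bins, duplicates="drop"
        )
        df = pd.DataFrame({"d": dispersion[expressed], "bin": bins.to_numpy()})
        grouped = df.groupby("bin", observed=True)["d"]
        mu = grouped.transform("mean").to_numpy()
        sd = grouped.transform("std").to_numpy()
        z = np.where(sd > 0, (df["d"].to_numpy() - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        disp_norm[expressed] = z

    stats = pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "mean": mean,
            "dispersion": dispersion,
            "dispersion_norm": disp_norm,
        }
    )
    stats["selected"] = (
        (stats["mean"] > cfg.mean_low)
        & (stats["mean"] < cfg.mean_high)
        & (stats["dispersion_norm"] > cfg.dispersion_min)
    )
    return stats


def select_hvg(
    norm: NormalizedMatrix, cfg: HVGConfig | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Highly variable genes: open mean window and strict dispersion threshold.

    Returns (selected gene ids, per-gene stats table).
    """
    stats = hvg_stats(norm, cfg)
    genes = stats.loc[stats["selected"], "gene"].to_numpy(dtype=object)
    return genes, stats


def scale_matrix(
    norm: NormalizedMatrix, genes, clip: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Center and unit-scale the selected genes (rows), clipping at +/- ``clip``.

    Genes with zero variance carry no cell-to-cell signal and are dropped
    with a warning. Returns (scaled genes x cells matrix, retained gene ids).
    """
    genes = np.asarray(list(genes), dtype=object)
    if genes.size == 0:
        raise ValueError("empty gene set")
    idx = norm.gene_index(genes)
    X = np.asarray(norm.values[idx], dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    nonconstant = sd.ravel() > 0
    if not nonconstant.all():
        warnings.warn(
            f"dropping {int((~nonconstant).sum())} zero-variance genes before scaling"
        )
    X = (X[nonconstant] - mu[nonconstant]) / sd[nonconstant]
    return np.clip(X, -clip, clip), genes[nonconstant]


def run_pca(scaled: np.ndarray, k: int) -> PCResult:
    """Exact PCA of a scaled genes x cells matrix via full SVD.

    Eigenvalues are those of the (cells-1)-denominator covariance of the
    column-centered cells x genes matrix. Sign convention: within each
    component the largest-magnitude gene loading is positive.
    """
    X = np.asarray(scaled, dtype=float).T  # cells x genes
    n_cells, n_genes = X.shape
    if not 1 <= k <= min(n_genes, n_cells - 1):
        raise ValueError(
            f"k={k} out of range [1, {min(n_genes, n_cells - 1)}] "
            f"for {n_cells} cells x {n_genes} genes"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = S**2 / (n_cells - 1)
    loadings = Vt.T[:, :k]
    coords = U[:, :k] * S[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            coords[:, j] = -coords[:, j]
    total_var = float(Xc.var(axis=0, ddof=1).sum())
    return PCResult(coords, eig[:k], loadings, total_var)


def run_tsne(
    pcs: PCResult,
    n_pcs: int = 20,
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """2-D t-SNE of the leading principal components (visualization only).

    Deterministic given ``seed``. The perplexity must be smaller than the
    number of cells; shrink it for small datasets.
    """
    if n_pcs > pcs.n_components:
        raise ValueError(f"n_pcs={n_pcs} exceeds available components ({pcs.n_components})")
    X = pcs.coordinates[:, :n_pcs]
    if X.shape[0] <= perplexity:
        raise ValueError(
            f"perplexity ({perplexity}) must be below the number of cells "
            f"({X.shape[0]}); pass a smaller perplexity"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="random",
    )
    return tsne.fit_transform(X)
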