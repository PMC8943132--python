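"""Graph-based clustering and marker-panel cell-type assignment.

Non-malignant liver TME populations are identified at the cluster level:
cells are clustered on a shared-nearest-neighbor graph built in PC space,
and each cluster is labeled with the lineage whose canonical markers are
most elevated (mean z-scored expression), or left "unassigned" when no
panel scores above the cell-population average.
"""

from __future__ import annotations

import warnings

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import yaml
from sklearn.neighbors import NearestNeighbors

from .features import PCResult
from .matrix import NormalizedMatrix

__all__ = [
    "DEFAULT_MARKER_PANEL",
    "read_marker_panel",
    "write_marker_panel",
    "cluster_cells",
    "score_and_assign",
    "annotate_cells",
]

# Canonical lineage markers for the liver-tumor microenvironment.
DEFAULT_MARKER_PANEL: dict[str, tuple[str, ...]] = {
    "T": ("CD4", "CD3E", "CD3D", "CD3G", "CD8A", "CD8B"),
    "B": ("CD79A", "SLAMF7", "BLNK", "FCRL5"),
    "TEC": ("PECAM1", "VWF", "ENG", "CDH5"),
    "CAF": ("COL1A2", "FAP", "ACTA1", "COL3A1", "COL6A1"),
    "TAM": ("CD14", "CD163", "CD68", "CSF1R"),
    "HPC-like": ("EPCAM", "KRT19", "PROM1", "ALDH1A1", "CD24"),
}


def read_marker_panel(path) -> dict[str, tuple[str, ...]]:
    """Load an editable marker panel from YAML (type -> gene list)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    panel = {str(t): tuple(genes) for t, genes in raw.items()}
    if any(not genes for genes in panel.values()):
        raise ValueError("marker panel has an empty gene list")
    return panel


def write_marker_panel(panel: dict[str, tuple[str, ...]], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({t: list(g) for t, g in panel.items()}, fh, sort_keys=True)


def _snn_graph(coords: np.ndarray, n_neighbors: int) -> ig.Graph:
    """Jaccard-weighted shared-nearest-neighbor graph over all cell pairs
    sharing at least one neighbor, pruned at the conventional 1/15 cutoff."""
    n = coords.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    A = nn.kneighbors_graph(coords, mode="connectivity")  # n x n, includes self
    shared = (A @ A.T).tocoo()  # |N(i) & N(j)|
    size = k + 1
    keep = shared.row < shared.col
    rows, cols, counts = shared.row[keep], shared.col[keep], shared.data[keep]
    jaccard = counts / (2 * size - counts)
    strong = jaccard >= 1 / 15
    g = ig.Graph(n=n, edges=list(zip(rows[strong], cols[strong])))
    g.es["weight"] = jaccard[strong].tolist()
    return g


def cluster_cells(
    pcs: PCResult,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
) -> np.ndarray:
    """Leiden community detection on a Jaccard-weighted SNN graph in PC space.

    Deterministic given ``seed``; returns one integer label per cell.
    """
    coords = pcs.coordinates
    if coords.shape[0] < 2:
        raise ValueError("clustering requires at least 2 cells")
    g = _snn_graph(coords, n_neighbors)
    partition = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=g.es["weight"] if g.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(partition.membership, dtype=int)


def score_and_assign(
    norm: NormalizedMatrix,
    clusters: np.ndarray,
    panel: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Assign each cluster the arg-max marker-panel type.

    A type's score for a cluster is the mean (over that type's present
    markers) of the cluster-mean z-scored expression. Clusters whose best
    score is not positive — no lineage markers above the population average —
    stay "unassigned". Exact ties resolve to the lexicographically first type.
    """
    panel = panel or DEFAULT_MARKER_PANEL
    clusters = np.asarray(clusters)
    present_genes = set(norm.gene_ids)
    usable: dict[str, list[str]] = {}
    for cell_type in sorted(panel):
        genes = [g for g in panel[cell_type] if g in present_genes]
        missing = [g for g in panel[cell_type] if g not in present_genes]
        if missing:
            warnings.warn(f"{cell_type}: markers absent from matrix: {missing}")
        if genes:
            usable[cell_type] = genes
    if not usable:
        raise ValueError("no marker-panel gene present in the matrix")

    all_marker_genes = sorted({g for genes in usable.values() for g in genes})
    idx = norm.gene_index(all_marker_genes)
    X = np.asarray(norm.values[idx], dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    row_of = {g: i for i, g in enumerate(all_marker_genes)}

    cluster_ids = np.unique(clusters)
    label_of: dict[int, tuple[str, float]] = {}
    for c in cluster_ids:
        cols = clusters == c
        scores = {
            t: float(Z[np.array([row_of[g] for g in genes])][:, cols].mean())
            for t, genes in usable.items()
        }
        best = min(scores, key=lambda t: (-scores[t], t))  # ties: lexicographic
        label_of[int(c)] = (best, scores[best]) if scores[best] > 0 else (
            "unassigned",
            scores[best],
        )

    types = np.array([label_of[int(c)][0] for c in clusters], dtype=object)
    scores = np.array([label_of[int(c)][1] for c in clusters], dtype=float)
    return pd.DataFrame(
        {
            "barcode": norm.barcodes,
            "cluster": clusters,
            "type": types,
            "score": scores,
        }
    )


def annotate_cells(
    norm: NormalizedMatrix,
    pcs: PCResult,
    panel: dict[str, tuple[str, ...]] | None = None,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
) -> pd.DataFrame:
    """Cluster in PC space and assign marker-panel types in one step."""
    clusters = cluster_cells(pcs, resolution=resolution, seed=seed, n_neighbors=n_neighbors)
    return score_and_assign(norm, clusters, panel)
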